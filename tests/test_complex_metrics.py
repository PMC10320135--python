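"""complex_metrics: contacts, chain mapping, oligo-lDDT, QS-score, DockQ."""

import itertools

import numpy as np
import pytest

from oligoqa import (
    all_metrics,
    dockq,
    dockq_multimer,
    fnat,
    inter_chain_contacts,
    interface_residues,
    make_idealized_multimer,
    map_chains,
    oligo_lddt,
    parse_stoichiometry,
    qs_score,
)
from oligoqa.complex_metrics import (
    FNAT_CONTACT_CUTOFF,
    LDDT_INCLUSION_RADIUS,
    LDDT_THRESHOLDS,
    QS_CONTACT_CUTOFF,
    MetricError,
    _qs_from_contact_dicts,
    dockq_from_components,
    qs_weight,
)
from oligoqa.synthetic import DecoySpec, perturb

from conftest import build_structure, random_isometry


def _identity(s):
    return {cid: cid for cid in s.chain_ids}


def _atoms(s):
    return [(ch.chain_id, r.index, a.name, a.coords)
            for ch in s.chains for r in ch.residues for a in r.atoms]


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def brute_contacts(s, scheme, cutoff):
    """Exhaustive double loop over all residue pairs."""
    out = {}
    residues = [(ch.chain_id, r) for ch in s.chains for r in ch.residues]
    for (ci, ri), (cj, rj) in itertools.combinations(residues, 2):
        if ci == cj:
            continue
        if scheme == "cb":
            d = np.linalg.norm(ri.cb_or_ca.coords - rj.cb_or_ca.coords)
        else:
            d = min(np.linalg.norm(a.coords - b.coords)
                    for a in ri.atoms for b in rj.atoms)
        if d <= cutoff:
            a, b = (ci, ri.index), (cj, rj.index)
            out[(a, b) if a < b else (b, a)] = float(d)
    return out


def brute_oligo_lddt(model, reference, mapping):
    """O(N^2) per-residue lDDT over all shared heavy-atom pairs."""
    inv = {v: k for k, v in mapping.items()}
    model_atoms = {(c, i, n): x for c, i, n, x in _atoms(model)}
    matched = []
    for c, i, n, x in _atoms(reference):
        mx = model_atoms.get((inv[c], i, n))
        if mx is not None:
            matched.append(((inv[c], i), x, mx))
    per_res_counts = {}
    per_res_ok = {}
    for (sa, ra, ma), (sb, rb, mb) in itertools.combinations(matched, 2):
        if sa == sb:
            continue
        dref = np.linalg.norm(ra - rb)
        if dref >= LDDT_INCLUSION_RADIUS:
            continue
        delta = abs(dref - np.linalg.norm(ma - mb))
        frac = sum(delta < t for t in LDDT_THRESHOLDS) / len(LDDT_THRESHOLDS)
        for slot in (sa, sb):
            per_res_counts[slot] = per_res_counts.get(slot, 0) + 1
            per_res_ok[slot] = per_res_ok.get(slot, 0.0) + frac
    per_res = {s: per_res_ok[s] / per_res_counts[s] for s in per_res_counts}
    return float(np.mean(list(per_res.values()))), per_res


def brute_qs(model, reference, mapping):
    mp = {}
    for k, v in brute_contacts(model, "cb", QS_CONTACT_CUTOFF).items():
        (ci, ri), (cj, rj) = k
        a, b = (mapping[ci], ri), (mapping[cj], rj)
        mp[(a, b) if a < b else (b, a)] = v
    rp = brute_contacts(reference, "cb", QS_CONTACT_CUTOFF)
    shared = mp.keys() & rp.keys()
    num = sum(max(0.0, 1.0 - abs(mp[k] - rp[k]) / QS_CONTACT_CUTOFF) for k in shared)
    return num / (len(mp) + len(rp) - len(shared))


def brute_fnat(model, reference, mapping, chain_pair):
    cp = tuple(sorted(chain_pair))
    rp = {k for k in brute_contacts(reference, "heavy", FNAT_CONTACT_CUTOFF)
          if tuple(sorted((k[0][0], k[1][0]))) == cp}
    mp = set()
    for k in brute_contacts(model, "heavy", FNAT_CONTACT_CUTOFF):
        (ci, ri), (cj, rj) = k
        a, b = (mapping[ci], ri), (mapping[cj], rj)
        mp.add((a, b) if a < b else (b, a))
    return len(rp & mp) / len(rp)


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

def test_contacts_empty_when_chains_far_apart():
    far = build_structure({
        "A": [{"CA": (0, 0, i * 3), "CB": (1, 0, i * 3)} for i in range(5)],
        "B": [{"CA": (100, 0, i * 3), "CB": (101, 0, i * 3)} for i in range(5)],
    })
    assert len(inter_chain_contacts(far, "cb", 12.0)) == 0


@pytest.mark.parametrize("scheme,cutoff", [("cb", 12.0), ("heavy", 5.0), ("heavy", 10.0)])
def test_contacts_match_brute_force(dimer, scheme, cutoff):
    got = inter_chain_contacts(dimer, scheme, cutoff)
    want = brute_contacts(dimer, scheme, cutoff)
    assert got.pairs.keys() == want.keys()
    for k in want:
        assert got.pairs[k] == pytest.approx(want[k], abs=1e-9)


def test_tighter_criterion_is_subset(dimer):
    heavy5 = inter_chain_contacts(dimer, "heavy", 5.0).pairs.keys()
    cb12 = inter_chain_contacts(dimer, "cb", 12.0).pairs.keys()
    # every 5 A heavy contact pair is also within the looser CB criterion
    assert heavy5 <= cb12


# ---------------------------------------------------------------------------
# chain mapping
# ---------------------------------------------------------------------------

def test_map_chains_identity_for_heterodimer(heterodimer):
    m = map_chains(heterodimer, heterodimer)
    assert m.pairs == {"A": "A", "B": "B"}
    assert m.score == pytest.approx(1.0)


def test_map_chains_handles_swapped_labels(dimer):
    swapped = perturb(dimer, DecoySpec(label_permutation={"A": "B", "B": "A"}, seed=0),
                      model_name="swapped")
    m = map_chains(swapped, dimer)
    # objective must equal the self-comparison optimum regardless of labels
    assert m.score == pytest.approx(1.0)
    assert qs_score(swapped, dimer, m).global_score == pytest.approx(1.0)


def test_map_chains_matches_exhaustive_oracle(tetramer):
    noisy = perturb(tetramer, DecoySpec(noise_sigma=0.5,
                                        label_permutation={"A": "B", "B": "A", "C": "D", "D": "C"},
                                        seed=9), model_name="decoy")
    got = map_chains(noisy, tetramer)
    # oracle: every group-respecting bijection, scored via qs_score directly
    groups = {}
    for ch in tetramer.chains:
        groups.setdefault(ch.sequence, []).append(ch.chain_id)
    model_groups = {}
    for ch in noisy.chains:
        model_groups.setdefault(ch.sequence, []).append(ch.chain_id)
    best, best_map = -1.0, None
    seqs = list(groups)
    for perms in itertools.product(*(itertools.permutations(model_groups[s]) for s in seqs)):
        mapping = {}
        for s, perm in zip(seqs, perms):
            mapping.update(dict(zip(perm, groups[s])))
        sc = qs_score(noisy, tetramer, mapping).global_score
        if sc > best + 1e-12:
            best, best_map = sc, mapping
    assert got.pairs == best_map
    assert got.score == pytest.approx(best, abs=1e-9)


def test_map_chains_rejects_stoichiometry_mismatch(dimer, heterodimer):
    with pytest.raises(MetricError):
        map_chains(dimer, heterodimer)


# ---------------------------------------------------------------------------
# oligo-lDDT
# ---------------------------------------------------------------------------

def test_oligo_lddt_self_is_one(dimer):
    res = oligo_lddt(dimer, dimer, _identity(dimer))
    assert res.global_score == 1.0
    assert all(v == 1.0 for v in res.per_residue.values())


def test_oligo_lddt_superposition_free(dimer):
    R, t = random_isometry(np.random.default_rng(5))
    moved = dimer.transformed(R, t)
    assert oligo_lddt(moved, dimer, _identity(dimer)).global_score == pytest.approx(1.0, abs=1e-9)


def test_oligo_lddt_matches_brute_force_enumeration(dimer):
    noisy = perturb(dimer, DecoySpec(noise_sigma=1.0, seed=4))
    got = oligo_lddt(noisy, dimer, _identity(dimer))
    want_global, want_per_res = brute_oligo_lddt(noisy, dimer, _identity(dimer))
    assert got.global_score == pytest.approx(want_global, abs=1e-9)
    assert got.per_residue.keys() == want_per_res.keys()
    for k in want_per_res:
        assert got.per_residue[k] == pytest.approx(want_per_res[k], abs=1e-9)


def test_oligo_lddt_displaced_atom_toy():
    """One CB displaced 3 A: its pairs fail the 0.5/1/2 A thresholds where the
    distance change exceeds them; values equal the hand-enumerable table."""
    toy = build_structure({
        "A": [{"CA": (0, 0, 0), "CB": (1.5, 0, 0)},
              {"CA": (0, 0, 3), "CB": (1.5, 0, 3)},
              {"CA": (0, 0, 6), "CB": (1.5, 0, 6)}],
        "B": [{"CA": (5, 0, 0), "CB": (3.5, 0, 0)},
              {"CA": (5, 0, 3), "CB": (3.5, 0, 3)},
              {"CA": (5, 0, 6), "CB": (3.5, 0, 6)}],
    })
    moved = build_structure({
        "A": [{"CA": (0, 0, 0), "CB": (1.5, 0, 0)},
              {"CA": (0, 0, 3), "CB": (1.5, 3, 3)},   # CB displaced exactly 3 A
              {"CA": (0, 0, 6), "CB": (1.5, 0, 6)}],
        "B": [{"CA": (5, 0, 0), "CB": (3.5, 0, 0)},
              {"CA": (5, 0, 3), "CB": (3.5, 0, 3)},
              {"CA": (5, 0, 6), "CB": (3.5, 0, 6)}],
    })
    got = oligo_lddt(moved, toy, _identity(toy))
    want_global, _ = brute_oligo_lddt(moved, toy, _identity(toy))
    assert got.global_score == pytest.approx(want_global, abs=1e-9)
    assert got.global_score < 1.0


def test_oligo_lddt_global_equals_mean_of_per_residue(dimer):
    noisy = perturb(dimer, DecoySpec(noise_sigma=2.0, seed=6))
    res = oligo_lddt(noisy, dimer, _identity(dimer))
    assert res.global_score == pytest.approx(np.mean(list(res.per_residue.values())), abs=1e-9)


# ---------------------------------------------------------------------------
# QS-score
# ---------------------------------------------------------------------------

def test_qs_identical_structures(dimer):
    assert qs_score(dimer, dimer, _identity(dimer)).global_score == 1.0


def test_qs_zero_when_no_shared_contacts(dimer):
    moved = perturb(dimer, DecoySpec(shift_chain="B", shift_translation=100.0, seed=0))
    assert qs_score(moved, dimer, _identity(dimer)).global_score == 0.0


def test_qs_direct_formula_on_constructed_contact_sets():
    # 6 shared contacts preserved exactly, 2 model-only, 4 reference-only
    shared = {((("A", i), ("B", i))): 6.0 for i in range(6)}
    model = dict(shared)
    model.update({((("A", 90 + i), ("B", 90 + i))): 5.0 for i in range(2)})
    ref = dict(shared)
    ref.update({((("A", 50 + i), ("B", 50 + i))): 7.0 for i in range(4)})
    assert _qs_from_contact_dicts(model, ref) == pytest.approx(6 / (6 + 2 + 4))


def test_qs_matches_brute_force(dimer):
    noisy = perturb(dimer, DecoySpec(noise_sigma=1.5, seed=10))
    got = qs_score(noisy, dimer, _identity(dimer)).global_score
    assert got == pytest.approx(brute_qs(noisy, dimer, _identity(dimer)), abs=1e-9)


def test_qs_undefined_without_contacts():
    far = build_structure({
        "A": [{"CA": (0, 0, i * 3), "CB": (1, 0, i * 3)} for i in range(5)],
        "B": [{"CA": (100, 0, i * 3), "CB": (101, 0, i * 3)} for i in range(5)],
    })
    with pytest.raises(MetricError):
        qs_score(far, far, _identity(far))


def test_qs_weight_kernel_shape():
    assert qs_weight(0.0) == 1.0
    assert qs_weight(6.0) == pytest.approx(0.5)
    assert qs_weight(12.0) == 0.0
    assert qs_weight(30.0) == 0.0


# ---------------------------------------------------------------------------
# interface residues and Fnat
# ---------------------------------------------------------------------------

def test_interface_residues_empty_for_distant_chains():
    far = build_structure({
        "A": [{"CA": (0, 0, i * 3), "CB": (1, 0, i * 3)} for i in range(5)],
        "B": [{"CA": (50, 0, i * 3), "CB": (51, 0, i * 3)} for i in range(5)],
    })
    assert interface_residues(far, ("A", "B"), 10.0) == set()


def test_interface_residues_match_brute_force(dimer):
    got = interface_residues(dimer, ("A", "B"), 10.0)
    want = set()
    for k, d in brute_contacts(dimer, "heavy", 10.0).items():
        want |= set(k)
    assert got == want


def test_interface_residues_monotone_in_cutoff(dimer):
    assert interface_residues(dimer, ("A", "B"), 5.0) <= interface_residues(dimer, ("A", "B"), 10.0)


def test_fnat_perfect_and_separated(dimer):
    assert fnat(dimer, dimer, _identity(dimer), ("A", "B")) == 1.0
    moved = perturb(dimer, DecoySpec(shift_chain="B", shift_translation=100.0, seed=0))
    assert fnat(moved, dimer, _identity(dimer), ("A", "B")) == 0.0


def test_fnat_matches_brute_force(dimer):
    noisy = perturb(dimer, DecoySpec(noise_sigma=1.2, seed=13))
    got = fnat(noisy, dimer, _identity(dimer), ("A", "B"))
    assert got == pytest.approx(brute_fnat(noisy, dimer, _identity(dimer), ("A", "B")), abs=1e-12)


def test_fnat_undefined_without_native_contacts():
    far = build_structure({
        "A": [{"CA": (0, 0, i * 3), "CB": (1, 0, i * 3)} for i in range(5)],
        "B": [{"CA": (50, 0, i * 3), "CB": (51, 0, i * 3)} for i in range(5)],
    })
    with pytest.raises(MetricError):
        fnat(far, far, _identity(far), ("A", "B"))


# ---------------------------------------------------------------------------
# DockQ
# ---------------------------------------------------------------------------

def test_dockq_perfect_model_is_one(dimer):
    assert dockq(dimer, dimer, _identity(dimer), ("A", "B")).global_score == pytest.approx(1.0)


def test_dockq_formula_direct_evaluation():
    want = (0.0 + 1.0 / (1.0 + (10.0 / 1.5) ** 2) + 1.0 / (1.0 + (20.0 / 8.5) ** 2)) / 3.0
    assert dockq_from_components(0.0, 10.0, 20.0) == pytest.approx(want, abs=1e-12)


def test_dockq_monotone_in_each_term():
    base = dockq_from_components(0.5, 2.0, 4.0)
    assert dockq_from_components(0.5, 4.0, 4.0) < base      # doubling iRMS
    assert dockq_from_components(0.5, 2.0, 8.0) < base
    assert dockq_from_components(0.25, 2.0, 4.0) < base


def test_dockq_multimer_is_mean_over_interfaces(tetramer):
    noisy = perturb(tetramer, DecoySpec(noise_sigma=1.0, seed=2))
    res = dockq_multimer(noisy, tetramer, _identity(tetramer))
    assert res.global_score == pytest.approx(np.mean(list(res.per_interface.values())), abs=1e-12)
    for cp, v in res.per_interface.items():
        assert v == pytest.approx(dockq(noisy, tetramer, _identity(tetramer), cp).global_score)


# ---------------------------------------------------------------------------
# cross-metric properties
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("stoich,length,seed", [
    ("A2", 10, 1), ("A3", 8, 2), ("A2B2", 8, 3), ("A1B1", 12, 4),
])
def test_all_metrics_maximal_on_self(stoich, length, seed):
    s = make_idealized_multimer(parse_stoichiometry(stoich), length, seed=seed)
    res = all_metrics(s, s)
    assert res["oligo_lddt"].global_score == 1.0
    assert res["qs"].global_score == 1.0
    assert res["dockq"].global_score == pytest.approx(1.0, abs=1e-12)


def test_metrics_invariant_to_consistent_relabeling(dimer):
    noisy = perturb(dimer, DecoySpec(noise_sigma=0.7, seed=3))
    relabeled = perturb(noisy, DecoySpec(label_permutation={"A": "B", "B": "A"}, seed=0),
                        model_name="relabeled")
    base = all_metrics(noisy, dimer)       # mapping re-solved internally
    swap = all_metrics(relabeled, dimer)
    for m in ("oligo_lddt", "qs", "dockq"):
        assert swap[m].global_score == pytest.approx(base[m].global_score, abs=1e-6)
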