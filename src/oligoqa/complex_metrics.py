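"""Quaternary-structure comparison metrics.

The pairwise kernel of the consensus method: inter-chain contact maps, the
chain-mapping search (which bijection between model and reference chains of
identical sequence to score under), and the three complex metrics —
oligo-lDDT (superposition-free preserved-distance score over all heavy-atom
pairs), QS-score (shared inter-chain contacts weighted by distance
agreement) and DockQ (Fnat + iRMS + LRMS composite per interface).

Conventions fixed here:

* the CB contact scheme uses the CB atom, falling back to CA for glycine;
* residue pairs in contact maps are unordered and stored once, canonically;
* the QS weight kernel is ``w(delta) = max(0, 1 - delta/12)`` — isolated in
  :func:`qs_weight` so an alternative kernel can be swapped in;
* DockQ over a multimer is the unweighted mean over reference interfaces.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from . import align3d
from .structure_io import OligoQAError, Structure

__all__ = [
    "ContactMap",
    "ChainMapping",
    "MetricResult",
    "MetricError",
    "qs_weight",
    "inter_chain_contacts",
    "map_chains",
    "oligo_lddt",
    "qs_score",
    "interface_residues",
    "fnat",
    "dockq",
    "dockq_multimer",
    "all_metrics",
    "LDDT_INCLUSION_RADIUS",
    "LDDT_THRESHOLDS",
    "QS_CONTACT_CUTOFF",
    "FNAT_CONTACT_CUTOFF",
    "INTERFACE_CUTOFF",
]

#: lDDT inclusion radius R0 (Å) and distance-difference thresholds (Å).
LDDT_INCLUSION_RADIUS = 15.0
LDDT_THRESHOLDS = (0.5, 1.0, 2.0, 4.0)
#: CB contact cutoff used by QS-score (Å).
QS_CONTACT_CUTOFF = 12.0
#: Heavy-atom contact cutoff defining native contacts for Fnat (Å).
FNAT_CONTACT_CUTOFF = 5.0
#: Heavy-atom cutoff defining interface residues (DockQ iRMS and local output).
INTERFACE_CUTOFF = 10.0
#: DockQ RMSD scaling constants (Å).
DOCKQ_IRMS_SCALE = 1.5
DOCKQ_LRMS_SCALE = 8.5


class MetricError(OligoQAError):
    """A metric is undefined for the given inputs (e.g. no contacts)."""


@dataclass
class ContactMap:
    """Inter-chain residue contacts of one structure.

    ``pairs`` maps the canonical (sorted) residue-slot pair
    ``((chain_i, res_i), (chain_j, res_j))`` with ``chain_i != chain_j`` to
    its distance in Å (CB distance for the cb scheme, minimum heavy-atom
    distance for the heavy scheme).
    """

    pairs: dict[tuple[tuple[str, int], tuple[str, int]], float]
    atom_scheme: str
    cutoff: float

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class ChainMapping:
    """A sequence-group-respecting bijection model chain -> reference chain."""

    pairs: dict[str, str]
    score: float = 0.0

    def __getitem__(self, model_chain_id: str) -> str:
        return self.pairs[model_chain_id]

    @property
    def inverse(self) -> dict[str, str]:
        return {v: k for k, v in self.pairs.items()}


@dataclass
class MetricResult:
    """One pairwise comparison outcome.

    ``global_score`` is in [0, 1] (GDT_TS is stored divided by 100).
    ``per_residue`` maps ``(model_chain_id, residue_index)`` to [0, 1];
    ``per_interface`` maps a reference chain pair to its score.
    """

    metric: str
    global_score: float
    per_residue: dict[tuple[str, int], float] | None = None
    per_interface: dict[tuple[str, str], float] | None = None


# ---------------------------------------------------------------------------
# Per-structure coordinate tables (cached on the Structure instance)
# ---------------------------------------------------------------------------

def _tables(s: Structure) -> dict:
    """Flat coordinate arrays for a structure, cached on the instance."""
    cache = getattr(s, "_oligoqa_tables", None)
    if cache is not None:
        return cache
    heavy_xyz, heavy_slot, heavy_key = [], [], []
    cb_xyz, cb_slot = [], []
    slot_ids: list[tuple[str, int]] = []
    slot_of: dict[tuple[str, int], int] = {}
    for ch in s.chains:
        for res in ch.residues:
            slot = (ch.chain_id, res.index)
            slot_of[slot] = len(slot_ids)
            slot_ids.append(slot)
            k = slot_of[slot]
            for a in res.atoms:
                heavy_xyz.append(a.coords)
                heavy_slot.append(k)
                heavy_key.append((ch.chain_id, res.index, a.name))
            cb = res.cb_or_ca
            if cb is not None:
                cb_xyz.append(cb.coords)
                cb_slot.append(k)
    cache = {
        "slot_ids": slot_ids,
        "slot_of": slot_of,
        "heavy_xyz": np.asarray(heavy_xyz, float).reshape(-1, 3),
        "heavy_slot": np.asarray(heavy_slot, int),
        "heavy_key": heavy_key,
        "cb_xyz": np.asarray(cb_xyz, float).reshape(-1, 3),
        "cb_slot": np.asarray(cb_slot, int),
    }
    chain_code = {cid: i for i, cid in enumerate(s.chain_ids)}
    cache["slot_chain_code"] = np.array([chain_code[cid] for cid, _ in slot_ids])
    object.__setattr__(s, "_oligoqa_tables", cache)
    return cache


def qs_weight(delta: np.ndarray | float) -> np.ndarray | float:
    """Distance-agreement weight for QS-score: ``max(0, 1 - |delta| / 12)``."""
    return np.maximum(0.0, 1.0 - np.abs(delta) / QS_CONTACT_CUTOFF)


# ---------------------------------------------------------------------------
# Contacts
# ---------------------------------------------------------------------------

def inter_chain_contacts(s: Structure, scheme: str = "cb",
                         cutoff: float = QS_CONTACT_CUTOFF) -> ContactMap:
    """All inter-chain residue pairs within ``cutoff`` Å.

    ``scheme="cb"`` measures CB–CB distance (CA for glycine); ``"heavy"``
    measures the minimum heavy-atom distance between the two residues.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    t = _tables(s)
    if scheme == "cb":
        xyz, slot = t["cb_xyz"], t["cb_slot"]
    elif scheme == "heavy":
        xyz, slot = t["heavy_xyz"], t["heavy_slot"]
    else:
        raise ValueError(f"unknown contact scheme {scheme!r}")
    pairs: dict[tuple[tuple[str, int], tuple[str, int]], float] = {}
    if len(xyz) == 0:
        return ContactMap(pairs, scheme, cutoff)
    idx = cKDTree(xyz).query_pairs(cutoff, output_type="ndarray")
    if len(idx):
        si, sj = slot[idx[:, 0]], slot[idx[:, 1]]
        code = t["slot_chain_code"]
        inter = code[si] != code[sj]
        d = np.linalg.norm(xyz[idx[inter, 0]] - xyz[idx[inter, 1]], axis=1)
        ids = t["slot_ids"]
        for a, b, dist in zip(si[inter], sj[inter], d):
            key = (ids[a], ids[b]) if ids[a] < ids[b] else (ids[b], ids[a])
            old = pairs.get(key)
            if old is None or dist < old:
                pairs[key] = float(dist)
    return ContactMap(pairs, scheme, cutoff)


def _relabel_contacts(contacts: ContactMap, mapping: Mapping[str, str]) -> dict:
    """Re-key a model contact map into reference chain labels."""
    out = {}
    for ((ci, ri), (cj, rj)), d in contacts.pairs.items():
        a, b = (mapping[ci], ri), (mapping[cj], rj)
        out[(a, b) if a < b else (b, a)] = d
    return out


def _qs_from_contact_dicts(model_pairs: Mapping, ref_pairs: Mapping) -> float:
    shared = model_pairs.keys() & ref_pairs.keys()
    denom = len(model_pairs) + len(ref_pairs) - len(shared)
    if denom == 0:
        raise MetricError("no inter-chain contacts in either structure")
    num = sum(float(qs_weight(model_pairs[k] - ref_pairs[k])) for k in shared)
    return num / denom


# ---------------------------------------------------------------------------
# Chain mapping
# ---------------------------------------------------------------------------

#: Largest same-sequence group for which mapping is exhaustive (6! = 720).
EXHAUSTIVE_GROUP_LIMIT = 6


def _grouped_chain_ids(model: Structure, reference: Structure) -> list[tuple[list[str], list[str]]]:
    """Pair up model and reference chain ids by exact sequence identity."""
    ref_groups: dict[str, list[str]] = {}
    for ch in reference.chains:
        ref_groups.setdefault(ch.sequence, []).append(ch.chain_id)
    model_groups: dict[str, list[str]] = {}
    for ch in model.chains:
        model_groups.setdefault(ch.sequence, []).append(ch.chain_id)
    if set(ref_groups) != set(model_groups) or any(
            len(ref_groups[s]) != len(model_groups[s]) for s in ref_groups):
        raise MetricError("model and reference stoichiometries differ")
    # deterministic order: by reference chain id
    return [(sorted(model_groups[s]), sorted(ref_groups[s]))
            for s in sorted(ref_groups, key=lambda s: ref_groups[s][0])]


def _contact_profile(contacts: ContactMap, chain_id: str) -> dict[int, int]:
    prof: dict[int, int] = {}
    for (a, b) in contacts.pairs:
        for (cid, ri) in (a, b):
            if cid == chain_id:
                prof[ri] = prof.get(ri, 0) + 1
    return prof


def map_chains(model: Structure, reference: Structure,
               groups: Sequence[tuple[list[str], list[str]]] | None = None) -> ChainMapping:
    """Find the bijection model chain -> reference chain to score under.

    Chains map only within identical-sequence groups. The objective is the
    QS-style shared-contact score evaluated under the candidate mapping.
    Groups of up to six copies are searched exhaustively over permutations;
    larger groups fall back to a greedy assignment by contact-profile
    similarity followed by one round of pairwise-swap hill climbing.
    """
    if groups is None:
        groups = _grouped_chain_ids(model, reference)
    model_contacts = inter_chain_contacts(model, "cb", QS_CONTACT_CUTOFF)
    ref_contacts = inter_chain_contacts(reference, "cb", QS_CONTACT_CUTOFF)
    ref_pairs = {k: v for k, v in ref_contacts.pairs.items()}

    def objective(mapping: dict[str, str]) -> float:
        try:
            return _qs_from_contact_dicts(_relabel_contacts(model_contacts, mapping), ref_pairs)
        except MetricError:
            return 0.0

    if max(len(m) for m, _ in groups) <= EXHAUSTIVE_GROUP_LIMIT:
        best_map, best_score = None, -1.0
        per_group_perms = [list(itertools.permutations(mids)) for mids, _ in groups]
        for combo in itertools.product(*per_group_perms):
            mapping = {}
            for (_, rids), perm in zip(groups, combo):
                mapping.update(dict(zip(perm, rids)))
            sc = objective(mapping)
            if sc > best_score + 1e-12:
                best_map, best_score = mapping, sc
        assert best_map is not None
        return ChainMapping(best_map, best_score)

    # greedy: rank candidate (model, ref) chain pairs by contact-profile similarity
    mapping: dict[str, str] = {}
    for mids, rids in groups:
        m_prof = {m: _contact_profile(model_contacts, m) for m in mids}
        r_prof = {r: _contact_profile(ref_contacts, r) for r in rids}

        def similarity(m: str, r: str) -> float:
            pm, pr = m_prof[m], r_prof[r]
            keys = pm.keys() | pr.keys()
            return -sum(abs(pm.get(k, 0) - pr.get(k, 0)) for k in keys)

        cands = sorted(((similarity(m, r), m, r) for m in mids for r in rids),
                       key=lambda t: (-t[0], t[1], t[2]))
        used_m, used_r = set(), set()
        for _, m, r in cands:
            if m not in used_m and r not in used_r:
                mapping[m] = r
                used_m.add(m)
                used_r.add(r)
    # one round of pairwise-swap hill climbing within each group
    score = objective(mapping)
    for mids, _ in groups:
        for a, b in itertools.combinations(sorted(mids), 2):
            trial = dict(mapping)
            trial[a], trial[b] = mapping[b], mapping[a]
            sc = objective(trial)
            if sc > score + 1e-12:
                mapping, score = trial, sc
    return ChainMapping(mapping, score)


# ---------------------------------------------------------------------------
# oligo-lDDT
# ---------------------------------------------------------------------------

def _matched_heavy(model: Structure, reference: Structure,
                   mapping: Mapping[str, str]) -> tuple[np.ndarray, np.ndarray, np.ndarray, list]:
    """Heavy atoms present in both structures, in reference order.

    Returns reference coords, model coords, residue-slot index per atom, and
    the slot key list ``[(model_chain_id, residue_index), ...]``.
    """
    tm, tr = _tables(model), _tables(reference)
    inv = {v: k for k, v in mapping.items()}
    model_lookup = {key: i for i, key in enumerate(tm["heavy_key"])}
    ref_sel, mod_sel, slot_per_atom = [], [], []
    slot_index: dict[tuple[str, int], int] = {}
    slot_keys: list[tuple[str, int]] = []
    for i, (rcid, ridx, name) in enumerate(tr["heavy_key"]):
        mcid = inv.get(rcid)
        if mcid is None:
            continue
        j = model_lookup.get((mcid, ridx, name))
        if j is None:
            continue
        slot = (mcid, ridx)
        if slot not in slot_index:
            slot_index[slot] = len(slot_keys)
            slot_keys.append(slot)
        ref_sel.append(i)
        mod_sel.append(j)
        slot_per_atom.append(slot_index[slot])
    ref_xyz = tr["heavy_xyz"][np.array(ref_sel, int)] if ref_sel else np.empty((0, 3))
    mod_xyz = tm["heavy_xyz"][np.array(mod_sel, int)] if mod_sel else np.empty((0, 3))
    return ref_xyz, mod_xyz, np.asarray(slot_per_atom, int), slot_keys


def oligo_lddt(model: Structure, reference: Structure,
               mapping: ChainMapping | Mapping[str, str] | None = None,
               inclusion_radius: float = LDDT_INCLUSION_RADIUS,
               thresholds: Sequence[float] = LDDT_THRESHOLDS) -> MetricResult:
    """Superposition-free all-atom distance-preservation score of a complex.

    For every reference heavy-atom pair in different residues (inter- and
    intra-chain alike, under the chain mapping) within ``inclusion_radius``,
    the model distance is compared with the reference distance at each
    threshold. A residue's score is the mean over thresholds of the fraction
    of its pairs preserved; the global score is the mean over scored residues.
    """
    mapping = _as_mapping(model, reference, mapping)
    ref_xyz, mod_xyz, slot, slot_keys = _matched_heavy(model, reference, mapping)
    if len(ref_xyz) == 0:
        raise MetricError("no atoms shared between model and reference")
    idx = cKDTree(ref_xyz).query_pairs(inclusion_radius, output_type="ndarray")
    if len(idx):
        idx = idx[slot[idx[:, 0]] != slot[idx[:, 1]]]
    if len(idx) == 0:
        raise MetricError("no scorable atom pairs within the inclusion radius")
    dref = np.linalg.norm(ref_xyz[idx[:, 0]] - ref_xyz[idx[:, 1]], axis=1)
    dmod = np.linalg.norm(mod_xyz[idx[:, 0]] - mod_xyz[idx[:, 1]], axis=1)
    delta = np.abs(dref - dmod)
    preserved = np.zeros(len(idx))
    for t in thresholds:
        preserved += (delta < t)
    preserved /= len(thresholds)
    n_slots = len(slot_keys)
    si, sj = slot[idx[:, 0]], slot[idx[:, 1]]
    pair_count = (np.bincount(si, minlength=n_slots)
                  + np.bincount(sj, minlength=n_slots)).astype(float)
    pair_score = (np.bincount(si, weights=preserved, minlength=n_slots)
                  + np.bincount(sj, weights=preserved, minlength=n_slots))
    scored = pair_count > 0
    per_residue = {slot_keys[k]: float(pair_score[k] / pair_count[k])
                   for k in np.nonzero(scored)[0]}
    global_score = float(np.mean([v for v in per_residue.values()]))
    return MetricResult("oligo_lddt", global_score, per_residue=per_residue)


# ---------------------------------------------------------------------------
# QS-score
# ---------------------------------------------------------------------------

def _as_mapping(model: Structure, reference: Structure,
                mapping: ChainMapping | Mapping[str, str] | None) -> dict[str, str]:
    if mapping is None:
        return map_chains(model, reference).pairs
    if isinstance(mapping, ChainMapping):
        return mapping.pairs
    return dict(mapping)


def qs_score(model: Structure, reference: Structure,
             mapping: ChainMapping | Mapping[str, str] | None = None) -> MetricResult:
    """Quaternary similarity from shared inter-chain CB contacts (12 Å).

    ``QS = sum over shared contacts of w(|d_model - d_ref|) divided by
    (N_shared + N_model_only + N_ref_only)`` with ``w(delta) = max(0, 1 -
    delta/12)``. A contact is shared when the residue pair (under the chain
    mapping) is within 12 Å in both structures. Also reports the same ratio
    restricted to each reference chain pair.
    """
    mapping = _as_mapping(model, reference, mapping)
    model_pairs = _relabel_contacts(
        inter_chain_contacts(model, "cb", QS_CONTACT_CUTOFF), mapping)
    ref_pairs = inter_chain_contacts(reference, "cb", QS_CONTACT_CUTOFF).pairs
    global_score = _qs_from_contact_dicts(model_pairs, ref_pairs)
    per_interface: dict[tuple[str, str], float] = {}
    chain_pairs = {tuple(sorted((a[0], b[0]))) for (a, b) in
                   set(model_pairs) | set(ref_pairs)}
    for cp in sorted(chain_pairs):
        mp = {k: v for k, v in model_pairs.items()
              if tuple(sorted((k[0][0], k[1][0]))) == cp}
        rp = {k: v for k, v in ref_pairs.items()
              if tuple(sorted((k[0][0], k[1][0]))) == cp}
        try:
            per_interface[cp] = _qs_from_contact_dicts(mp, rp)
        except MetricError:
            continue
    return MetricResult("qs", global_score, per_interface=per_interface)


# ---------------------------------------------------------------------------
# DockQ
# ---------------------------------------------------------------------------

def interface_residues(reference: Structure, chain_pair: tuple[str, str],
                       cutoff: float = INTERFACE_CUTOFF) -> set[tuple[str, int]]:
    """Residues of either chain with any heavy atom within ``cutoff`` of the
    other chain, as ``(chain_id, residue_index)`` pairs."""
    c1, c2 = chain_pair
    t = _tables(reference)
    code = {cid: i for i, cid in enumerate(reference.chain_ids)}
    if c1 not in code or c2 not in code:
        raise KeyError(f"chain pair {chain_pair} not in structure")
    keys = t["heavy_key"]
    xyz = t["heavy_xyz"]
    sel1 = [i for i, (cid, _, _) in enumerate(keys) if cid == c1]
    sel2 = [i for i, (cid, _, _) in enumerate(keys) if cid == c2]
    out: set[tuple[str, int]] = set()
    if not sel1 or not sel2:
        return out
    t1, t2 = cKDTree(xyz[sel1]), cKDTree(xyz[sel2])
    for i_loc, nbrs in enumerate(t1.query_ball_tree(t2, cutoff)):
        if nbrs:
            cid, ridx, _ = keys[sel1[i_loc]]
            out.add((cid, ridx))
            for j_loc in nbrs:
                cjd, rjdx, _ = keys[sel2[j_loc]]
                out.add((cjd, rjdx))
    return out


def _chain_pair_contacts(contacts: Mapping, chain_pair: tuple[str, str]) -> set:
    cp = tuple(sorted(chain_pair))
    return {k for k in contacts
            if tuple(sorted((k[0][0], k[1][0]))) == cp}


def fnat(model: Structure, reference: Structure,
         mapping: ChainMapping | Mapping[str, str] | None,
         chain_pair: tuple[str, str]) -> float:
    """Fraction of the reference's heavy-atom contacts (5 Å) across the chain
    pair that are present in the model (under the chain mapping)."""
    mapping = _as_mapping(model, reference, mapping)
    ref_pairs = inter_chain_contacts(reference, "heavy", FNAT_CONTACT_CUTOFF).pairs
    native = _chain_pair_contacts(ref_pairs, chain_pair)
    if not native:
        raise MetricError(f"no native contacts across chains {chain_pair}")
    model_pairs = _relabel_contacts(
        inter_chain_contacts(model, "heavy", FNAT_CONTACT_CUTOFF), mapping)
    return len(native & model_pairs.keys()) / len(native)


def dockq_from_components(fnat_value: float, irms_value: float, lrms_value: float) -> float:
    """The DockQ composite: ``(Fnat + 1/(1+(iRMS/1.5)^2) + 1/(1+(LRMS/8.5)^2)) / 3``."""
    return (fnat_value
            + 1.0 / (1.0 + (irms_value / DOCKQ_IRMS_SCALE) ** 2)
            + 1.0 / (1.0 + (lrms_value / DOCKQ_LRMS_SCALE) ** 2)) / 3.0


def _receptor_ligand(reference: Structure, chain_pair: tuple[str, str]) -> tuple[str, str]:
    """Receptor = the side with more residues; tie -> lexicographically first."""
    c1, c2 = chain_pair
    n1, n2 = len(reference.chain(c1)), len(reference.chain(c2))
    if n1 > n2 or (n1 == n2 and c1 < c2):
        return c1, c2
    return c2, c1


def dockq(model: Structure, reference: Structure,
          mapping: ChainMapping | Mapping[str, str] | None,
          chain_pair: tuple[str, str]) -> MetricResult:
    """DockQ of one interface (a reference chain pair with native contacts)."""
    mapping = _as_mapping(model, reference, mapping)
    f = fnat(model, reference, mapping, chain_pair)
    receptor, ligand = _receptor_ligand(reference, chain_pair)
    iface = interface_residues(reference, chain_pair, INTERFACE_CUTOFF)
    i = align3d.irms(model, reference, mapping, iface)
    l = align3d.lrms(model, reference, mapping, [receptor], [ligand])
    value = dockq_from_components(f, i, l)
    cp = tuple(sorted(chain_pair))
    return MetricResult("dockq", value, per_interface={cp: value})


def dockq_multimer(model: Structure, reference: Structure,
                   mapping: ChainMapping | Mapping[str, str] | None = None) -> MetricResult:
    """Unweighted mean DockQ over all reference interfaces.

    An interface is any reference chain pair with at least one heavy-atom
    contact at 5 Å.
    """
    mapping = _as_mapping(model, reference, mapping)
    ref_pairs = inter_chain_contacts(reference, "heavy", FNAT_CONTACT_CUTOFF).pairs
    chain_pairs = sorted({tuple(sorted((a[0], b[0]))) for (a, b) in ref_pairs})
    if not chain_pairs:
        raise MetricError("reference has no inter-chain interface")
    per_interface: dict[tuple[str, str], float] = {}
    for cp in chain_pairs:
        per_interface[cp] = dockq(model, reference, mapping, cp).global_score
    return MetricResult("dockq", float(np.mean(list(per_interface.values()))),
                        per_interface=per_interface)


def all_metrics(model: Structure, reference: Structure,
                mapping: ChainMapping | Mapping[str, str] | None = None) -> dict[str, MetricResult]:
    """oligo-lDDT, QS-score and multimer DockQ under one solved chain mapping."""
    mapping = _as_mapping(model, reference, mapping)
    return {
        "oligo_lddt": oligo_lddt(model, reference, mapping),
        "qs": qs_score(model, reference, mapping),
        "dockq": dockq_multimer(model, reference, mapping),
    }
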