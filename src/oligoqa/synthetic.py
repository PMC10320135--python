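"""Synthetic multimer fixtures: idealized assemblies and graded decoy sets.

Generates fully deterministic test inputs so every stage of the method can be
exercised without any experimental data: each chain is a parametric
alpha-helix (1.5 Å rise, 100 degree twist per residue, backbone N/CA/C/O plus
CB except for glycine) and chains are placed on a ring so that adjacent
chains form interfaces. Decoys are produced by seeded Gaussian coordinate
noise, optional rigid displacement of one chain, and optional relabelling of
same-sequence chains; a labelled ensemble carries the true metric scores of
every decoy against its unperturbed reference, computed with this package's
own metrics.

The geometry is deliberately minimal: poly-alanine chemistry, no side chains
beyond CB, no clash relief. Metrics need contacts and correspondence, not
physical realism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import complex_metrics as cm
from .structure_io import (
    Atom,
    Chain,
    Ensemble,
    OligoQAError,
    Residue,
    Stoichiometry,
    Structure,
    derive_stoichiometry,
    validate_ensemble,
)

__all__ = [
    "DecoySpec",
    "LabeledEnsemble",
    "make_idealized_multimer",
    "perturb",
    "make_labeled_ensemble",
]

#: Helix parameters: rise per residue (Å) and twist per residue (degrees).
HELIX_RISE = 1.5
HELIX_TWIST_DEG = 100.0
#: Distance between the axes of adjacent chains on the ring (Å).
RING_NEIGHBOUR_DISTANCE = 9.5

MAX_TOTAL_CHAINS = 12
CHAIN_LENGTH_RANGE = (5, 200)
#: Seeded per-atom jitter (Å) baked into every reference so that generated
#: assemblies are generic: without it an n-fold ring is exactly symmetric,
#: every same-sequence chain mapping ties exactly, and degenerate tie-breaks
#: rather than structure decide the winner. Real complexes carry no such
#: exact coincidences.
GENERIC_JITTER_SIGMA = 0.05


class FixtureConfigError(OligoQAError):
    """Fixture parameters outside the supported ranges."""


@dataclass
class DecoySpec:
    """Recipe for one decoy: noise, an optional one-chain rigid shift, and an
    optional relabelling of same-sequence chains. ``seed`` fixes everything."""

    noise_sigma: float = 0.0
    shift_chain: str | None = None
    shift_translation: float = 0.0
    shift_rotation_deg: float = 0.0
    label_permutation: Mapping[str, str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise FixtureConfigError("noise_sigma must be >= 0")


@dataclass
class LabeledEnsemble:
    """A decoy ensemble together with its reference and true quality scores.

    ``true_scores[model_name]`` holds oligo_lddt / qs / dockq of that decoy
    against the unperturbed reference, computed on construction.
    """

    ensemble: Ensemble
    reference: Structure
    true_scores: dict[str, dict[str, float]]


def _rotation_z(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    # QR of a Gaussian matrix, sign-fixed to a proper rotation
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def _helix_residue(i: int, aa: str) -> list[Atom]:
    """Backbone + CB atoms of residue ``i`` (0-based) of an ideal helix at
    the origin, axis along z."""
    def on_helix(radius: float, phase_deg: float, dz: float) -> np.ndarray:
        ang = math.radians(HELIX_TWIST_DEG * i + phase_deg)
        return np.array([radius * math.cos(ang), radius * math.sin(ang),
                         HELIX_RISE * i + dz])

    atoms = [
        Atom("N", "N", on_helix(1.6, -28.0, -0.9)),
        Atom("CA", "C", on_helix(2.3, 0.0, 0.0)),
        Atom("C", "C", on_helix(2.0, 27.0, 0.9)),
        Atom("O", "O", on_helix(2.6, 32.0, 1.4)),
    ]
    if aa != "G":
        atoms.append(Atom("CB", "C", on_helix(3.3, -14.0, 0.2)))
    return atoms


def make_idealized_multimer(stoich: Stoichiometry, chain_length: int,
                            seed: int = 0, model_name: str = "reference") -> Structure:
    """Build an idealized multimer matching ``stoich``.

    Each chain is an alpha-helix of ``chain_length`` residues; chains sit on
    a ring with adjacent axes ``RING_NEIGHBOUR_DISTANCE`` apart, guaranteeing
    inter-chain CB contacts without any physics. Sequences are poly-alanine
    with one glycine placed at a group-specific position, so each sequence
    group is distinct and the glycine CB fallback is exercised. A small
    seeded per-atom jitter (``GENERIC_JITTER_SIGMA``) breaks the exact ring
    symmetry so chain mappings are uniquely determined; the whole assembly
    is given a seed-dependent rigid orientation; coordinates are
    bit-identical for equal seeds.
    """
    lo, hi = CHAIN_LENGTH_RANGE
    if not (lo <= chain_length <= hi):
        raise FixtureConfigError(f"chain_length must be in [{lo}, {hi}]")
    total = stoich.total_chains
    if not (1 <= total <= MAX_TOTAL_CHAINS):
        raise FixtureConfigError(f"total chain count must be in [1, {MAX_TOTAL_CHAINS}]")

    sequences: list[str] = []
    for gi, (label, copies) in enumerate(stoich.groups):
        seq = list("A" * chain_length)
        seq[gi % chain_length] = "G"
        sequences.extend(["".join(seq)] * copies)

    if total == 1:
        ring_radius = 0.0
    else:
        ring_radius = RING_NEIGHBOUR_DISTANCE / (2.0 * math.sin(math.pi / total))
    rng = np.random.default_rng(seed)
    R_global = _random_rotation(rng)
    t_global = rng.normal(scale=5.0, size=3)

    structure = Structure(model_name, [])
    for k, seq in enumerate(sequences):
        cid = chr(ord("A") + k)
        theta = 360.0 * k / total
        Rz = _rotation_z(theta)
        center = ring_radius * np.array([math.cos(math.radians(theta)),
                                         math.sin(math.radians(theta)), 0.0])
        chain = Chain(cid, [])
        for i, aa in enumerate(seq):
            res = Residue(index=i + 1, seq_id=i + 1, aa=aa)
            for a in _helix_residue(i, aa):
                xyz = Rz @ a.coords + center
                xyz = xyz + rng.normal(scale=GENERIC_JITTER_SIGMA, size=3)
                res.atoms.append(Atom(a.name, a.element, R_global @ xyz + t_global))
            chain.residues.append(res)
        structure.chains.append(chain)
    return structure


def perturb(reference: Structure, spec: DecoySpec,
            model_name: str | None = None) -> Structure:
    """Produce a decoy from a reference according to a :class:`DecoySpec`.

    In order: i.i.d. Gaussian noise (sigma = ``noise_sigma``) on every atom;
    a rigid shift of the designated chain (translation along a seeded random
    direction, rotation about a seeded random axis through the chain
    centroid); relabelling of chains by ``label_permutation``, which must not
    cross sequence groups.
    """
    rng = np.random.default_rng(spec.seed)
    out = Structure(model_name or f"{reference.model_name}_decoy", [])
    for ch in reference.chains:
        new_ch = Chain(ch.chain_id, [])
        for res in ch.residues:
            new_res = Residue(res.index, res.seq_id, res.aa, [], res.icode)
            for a in res.atoms:
                noise = rng.normal(scale=spec.noise_sigma, size=3) if spec.noise_sigma > 0 else 0.0
                new_res.atoms.append(Atom(a.name, a.element, a.coords + noise))
            new_ch.residues.append(new_res)
        out.chains.append(new_ch)

    if spec.shift_chain is not None and (spec.shift_translation or spec.shift_rotation_deg):
        ch = out.chain(spec.shift_chain)
        coords = np.array([a.coords for r in ch.residues for a in r.atoms])
        centroid = coords.mean(axis=0)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        ang = math.radians(spec.shift_rotation_deg)
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        R = np.eye(3) + math.sin(ang) * K + (1 - math.cos(ang)) * (K @ K)
        t = spec.shift_translation * direction
        for res in ch.residues:
            for a in res.atoms:
                a.coords = R @ (a.coords - centroid) + centroid + t

    if spec.label_permutation:
        seq_of = {ch.chain_id: ch.sequence for ch in out.chains}
        for old, new in spec.label_permutation.items():
            if seq_of[old] != seq_of[new]:
                raise FixtureConfigError(
                    f"label permutation {old}->{new} crosses sequence groups")
        for ch in out.chains:
            ch.chain_id = spec.label_permutation.get(ch.chain_id, ch.chain_id)
    return out


def make_labeled_ensemble(reference: Structure, n: int,
                          sigma_range: tuple[float, float] = (0.1, 4.0),
                          seed: int = 0, target_id: str = "synthetic") -> LabeledEnsemble:
    """Build ``n`` noise-graded decoys of ``reference`` with true scores.

    Noise levels are evenly spaced across ``sigma_range``; each decoy's
    randomness is derived deterministically from ``seed``. True oligo-lDDT,
    QS and DockQ scores of every decoy against the reference are computed
    with the package's own metrics and attached.
    """
    if n < 2:
        raise FixtureConfigError("a labelled ensemble needs n >= 2 decoys")
    sigmas = np.linspace(sigma_range[0], sigma_range[1], n)
    child_seeds = np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)
    decoys, true_scores = [], {}
    for i, (sigma, s) in enumerate(zip(sigmas, child_seeds)):
        name = f"model_{i + 1:03d}"
        decoy = perturb(reference, DecoySpec(noise_sigma=float(sigma), seed=int(s)),
                        model_name=name)
        decoys.append(decoy)
        res = cm.all_metrics(decoy, reference)
        true_scores[name] = {m: res[m].global_score
                             for m in ("oligo_lddt", "qs", "dockq")}
    stoich = derive_stoichiometry(reference)
    ensemble = validate_ensemble(decoys, stoich, target_id=target_id)
    return LabeledEnsemble(ensemble, reference, true_scores)
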