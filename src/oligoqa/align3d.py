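"""Rigid-body superposition and per-chain (tertiary) comparison scores.

Provides the Kabsch least-squares superposition, the GDT_TS score over the
standard 1/2/4/8 Å thresholds, and the two RMSD terms of DockQ: the ligand
RMSD after receptor superposition (LRMS) and the interface backbone RMSD
(iRMS). Correspondence between model and reference residues is by ordinal
index within mapped chains (model and reference share sequences).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .structure_io import Chain, OligoQAError, Structure

__all__ = [
    "Superposition",
    "TertiaryScore",
    "AlignmentError",
    "kabsch_superpose",
    "gdt_ts",
    "lrms",
    "irms",
    "BACKBONE_ATOMS",
    "GDT_THRESHOLDS",
]

#: Backbone atom set used by the RMSD terms; missing O is tolerated.
BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: GDT_TS distance thresholds in Å.
GDT_THRESHOLDS = (1.0, 2.0, 4.0, 8.0)


class AlignmentError(OligoQAError):
    """Superposition or score undefined for the given inputs."""


@dataclass
class Superposition:
    """A proper rigid transform ``x -> R x + t`` of one point set onto another."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_points: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


@dataclass
class TertiaryScore:
    """GDT_TS (0..100), CA RMSD, and the four per-threshold fractions."""

    gdt_ts: float
    rmsd_ca: float
    per_threshold_fractions: tuple[float, float, float, float]


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> Superposition:
    """Least-squares proper rigid transform of ``coords_a`` onto ``coords_b``.

    Point sets must be in correspondence, n >= 3 and non-degenerate
    (non-collinear). Reflections are never returned.
    """
    a = np.asarray(coords_a, float)
    b = np.asarray(coords_b, float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise AlignmentError("point sets must be matching n x 3 arrays")
    n = a.shape[0]
    if n < 3:
        raise AlignmentError(f"need at least 3 points, got {n}")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    # degenerate (collinear) sets leave the rotation about the line free
    sv = np.linalg.svd(a - ca, compute_uv=False)
    if sv[1] < 1e-9 * max(1.0, sv[0]):
        raise AlignmentError("degenerate (collinear) point set")
    rot, _ = Rotation.align_vectors(b - cb, a - ca)
    R = rot.as_matrix()
    t = cb - R @ ca
    rmsd = float(np.sqrt(np.mean(np.sum((a @ R.T + t - b) ** 2, axis=1))))
    return Superposition(R, t, rmsd, n)


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def _ca_arrays(model_chain: Chain, ref_chain: Chain,
               correspondence: Iterable[tuple[int, int]] | None) -> tuple[np.ndarray, np.ndarray]:
    if correspondence is None:
        n = min(len(model_chain), len(ref_chain))
        correspondence = [(i, i) for i in range(1, n + 1)]
    m_by_idx = {r.index: r for r in model_chain.residues}
    r_by_idx = {r.index: r for r in ref_chain.residues}
    mc, rc = [], []
    for mi, ri in correspondence:
        mres, rres = m_by_idx.get(mi), r_by_idx.get(ri)
        if mres is None or rres is None:
            continue
        ma, ra = mres.ca, rres.ca
        if ma is None or ra is None:
            continue
        mc.append(ma.coords)
        rc.append(ra.coords)
    if len(mc) < 3:
        raise AlignmentError(f"fewer than 3 paired CA atoms ({len(mc)})")
    return np.array(mc), np.array(rc)


def _gdt_fraction(model: np.ndarray, ref: np.ndarray, threshold: float,
                  seed_lengths: Sequence[int] = (3, 5, 7), max_iter: int = 10) -> float:
    """Maximal fraction of CAs placeable within ``threshold`` (seed-and-extend).

    Every contiguous window of the given lengths seeds a superposition which
    is iteratively re-fit on its within-threshold subset until a fixed point.
    The search is deterministic; it is a lower bound on the exact maximum but
    reproduces reference behaviour on small cases.
    """
    n = len(model)
    best = 0
    seen: set[bytes] = set()
    for w in seed_lengths:
        if w > n:
            continue
        for start in range(0, n - w + 1):
            subset = np.zeros(n, dtype=bool)
            subset[start:start + w] = True
            for _ in range(max_iter):
                key = subset.tobytes()
                if key in seen:
                    break
                seen.add(key)
                try:
                    sup = kabsch_superpose(model[subset], ref[subset])
                except AlignmentError:
                    break
                d = np.linalg.norm(sup.apply(model) - ref, axis=1)
                within = d <= threshold
                best = max(best, int(within.sum()))
                if within.sum() < 3:
                    # too few within threshold: re-fit on the 3 closest pairs
                    within = np.zeros(n, dtype=bool)
                    within[np.argsort(d)[:3]] = True
                if np.array_equal(within, subset):
                    break
                subset = within
    return best / n


def gdt_ts(model_chain: Chain, ref_chain: Chain,
           correspondence: Iterable[tuple[int, int]] | None = None) -> TertiaryScore:
    """GDT_TS of a model chain against a reference chain over paired CAs.

    ``correspondence`` pairs model residue indices with reference residue
    indices; by default residues are paired by equal ordinal index.
    GDT_TS = 25 x sum over thresholds {1, 2, 4, 8} Å of the maximal fraction
    of paired CA atoms within threshold under a rigid transform.
    """
    mc, rc = _ca_arrays(model_chain, ref_chain, correspondence)
    fractions = tuple(_gdt_fraction(mc, rc, t) for t in GDT_THRESHOLDS)
    sup = kabsch_superpose(mc, rc)
    return TertiaryScore(
        gdt_ts=25.0 * sum(fractions),
        rmsd_ca=sup.rmsd,
        per_threshold_fractions=fractions,  # type: ignore[arg-type]
    )


def _backbone_coords(structure: Structure, chain_residues: Mapping[str, Iterable[int]],
                     atom_names: Sequence[str]) -> list[tuple[str, int, str, np.ndarray]]:
    out = []
    for cid, indices in chain_residues.items():
        ch = structure.chain(cid)
        by_idx = {r.index: r for r in ch.residues}
        for idx in indices:
            res = by_idx.get(idx)
            if res is None:
                continue
            for name in atom_names:
                a = res.atom(name)
                if a is not None:
                    out.append((cid, idx, name, a.coords))
    return out


def _paired_backbone(model: Structure, reference: Structure,
                     mapping: Mapping[str, str],
                     ref_chain_residues: Mapping[str, Iterable[int]]) -> tuple[np.ndarray, np.ndarray]:
    """Matched model/reference backbone coordinates over reference residues."""
    inv = {v: k for k, v in mapping.items()}
    ref_atoms = _backbone_coords(reference, ref_chain_residues, BACKBONE_ATOMS)
    model_lookup: dict[tuple[str, int, str], np.ndarray] = {}
    model_chain_residues = {inv[cid]: idx for cid, idx in ref_chain_residues.items()}
    for cid, idx, name, xyz in _backbone_coords(model, model_chain_residues, BACKBONE_ATOMS):
        model_lookup[(mapping[cid], idx, name)] = xyz
    m, r = [], []
    for cid, idx, name, xyz in ref_atoms:
        mx = model_lookup.get((cid, idx, name))
        if mx is not None:
            m.append(mx)
            r.append(xyz)
    return np.array(m), np.array(r)


def lrms(model: Structure, reference: Structure, mapping: Mapping[str, str],
         receptor: Iterable[str], ligand: Iterable[str]) -> float:
    """Ligand backbone RMSD after superposing on the receptor backbone.

    ``receptor`` and ``ligand`` are reference chain id sets partitioning the
    interface's two sides; ``mapping`` maps model chain ids to reference
    chain ids. The superposition is fit on receptor backbone atoms and the
    RMSD is reported over ligand backbone atoms without re-fitting.
    """
    receptor, ligand = list(receptor), list(ligand)
    if not receptor or not ligand:
        raise AlignmentError("receptor and ligand sides must both be non-empty")
    all_res = lambda cids: {cid: [r.index for r in reference.chain(cid).residues]
                            for cid in cids}
    m_rec, r_rec = _paired_backbone(model, reference, mapping, all_res(receptor))
    m_lig, r_lig = _paired_backbone(model, reference, mapping, all_res(ligand))
    if len(m_rec) < 3 or len(m_lig) == 0:
        raise AlignmentError("too few paired backbone atoms for LRMS")
    sup = kabsch_superpose(m_rec, r_rec)
    return _rmsd(sup.apply(m_lig), r_lig)


def irms(model: Structure, reference: Structure, mapping: Mapping[str, str],
         interface_residues: Iterable[tuple[str, int]]) -> float:
    """Backbone RMSD over interface residues after superposing on them.

    ``interface_residues`` are ``(reference_chain_id, residue_index)`` pairs,
    typically from :func:`oligoqa.complex_metrics.interface_residues` at the
    DockQ 10 Å definition.
    """
    per_chain: dict[str, list[int]] = {}
    for cid, idx in interface_residues:
        per_chain.setdefault(cid, []).append(idx)
    if sum(len(v) for v in per_chain.values()) < 3:
        raise AlignmentError("fewer than 3 interface residues")
    m, r = _paired_backbone(model, reference, mapping, per_chain)
    if len(m) < 3:
        raise AlignmentError("fewer than 3 paired interface backbone atoms")
    sup = kabsch_superpose(m, r)
    return _rmsd(sup.apply(m), r)
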