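"""Structure and QA file I/O for multimer quality assessment.

Reads protein-complex models from PDB files (including the CASP TS dialect,
whose ``PFRMAT``/``TARGET``/``MODEL`` header lines are tolerated), validates
model ensembles against a target stoichiometry, and writes the two QA output
formats: PDB with per-residue quality in the B-factor column, and the CASP
QMODE2 QA format (global score plus per-residue local scores per model).

Parsing is delegated to :mod:`gemmi`; this module applies the filtering rules
of the method on top: only the first MODEL block, only standard amino-acid
polymer residues, one atom per name (highest occupancy wins among altlocs),
hydrogens discarded, and residues lacking a CA atom dropped.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "Stoichiometry",
    "Ensemble",
    "OligoQAError",
    "ParseError",
    "StoichiometryFormatError",
    "ValidationError",
    "EmissionError",
    "read_structure",
    "write_structure",
    "write_structure_with_bfactor",
    "parse_stoichiometry",
    "validate_ensemble",
    "sequence_groups",
    "derive_stoichiometry",
    "write_qa_qmode2",
    "read_qa",
]


class OligoQAError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(OligoQAError):
    """A structure or QA file could not be parsed."""


class StoichiometryFormatError(OligoQAError):
    """A stoichiometry string does not match ``<letter><count>`` repeats."""


class ValidationError(OligoQAError):
    """A model does not match the target stoichiometry or sequences."""


class EmissionError(OligoQAError):
    """An output file cannot be produced from the given results."""


#: Three-letter -> one-letter codes for the 20 standard amino acids.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
ONE_TO_THREE["X"] = "UNK"

#: Number of local scores per continuation line in QMODE2 output.
QA_SCORES_PER_LINE = 20


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Atom:
    """A heavy atom with Cartesian coordinates in Å."""

    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    bfactor: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")


@dataclass
class Residue:
    """One amino-acid residue: ordinal index, author numbering, and atoms.

    ``index`` is the 1-based ordinal position in the chain and is the key used
    throughout for residue correspondence (model and reference share
    sequences, so index pairing is exact).
    """

    index: int
    seq_id: int
    aa: str
    atoms: list[Atom] = field(default_factory=list)
    icode: str = ""

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Atom | None:
        return self.atom("CA")

    @property
    def cb_or_ca(self) -> Atom:
        """CB coordinates, falling back to CA for glycine (or missing CB)."""
        a = self.atom("CB")
        return a if a is not None else self.atom("CA")  # type: ignore[return-value]


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Structure:
    """A parsed multimer model: ordered chains of residues of heavy atoms."""

    model_name: str
    chains: list[Chain] = field(default_factory=list)

    def chain(self, chain_id: str) -> Chain:
        for ch in self.chains:
            if ch.chain_id == chain_id:
                return ch
        raise KeyError(f"no chain {chain_id!r} in {self.model_name}")

    @property
    def chain_ids(self) -> list[str]:
        return [ch.chain_id for ch in self.chains]

    def n_residues(self) -> int:
        return sum(len(ch) for ch in self.chains)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a copy with ``x -> R x + t`` applied to every atom."""
        rotation = np.asarray(rotation, float)
        translation = np.asarray(translation, float)
        out = Structure(self.model_name, [])
        for ch in self.chains:
            new_ch = Chain(ch.chain_id, [])
            for res in ch.residues:
                new_res = Residue(res.index, res.seq_id, res.aa, [], res.icode)
                for a in res.atoms:
                    new_res.atoms.append(
                        Atom(a.name, a.element, rotation @ a.coords + translation,
                             a.occupancy, a.altloc, a.bfactor)
                    )
                new_ch.residues.append(new_res)
            out.chains.append(new_ch)
        return out


@dataclass
class Stoichiometry:
    """Copy-number composition of the target complex, e.g. A2B2."""

    groups: list[tuple[str, int]]
    sequences: dict[str, str] | None = None

    @property
    def total_chains(self) -> int:
        return sum(n for _, n in self.groups)

    def __str__(self) -> str:
        return "".join(f"{label}{n}" for label, n in self.groups)


@dataclass
class Ensemble:
    """A validated set of models of one target.

    ``sequence_groups`` maps each stoichiometry label to the chain sequence
    bound to it (taken from the first accepted model).
    """

    target_id: str
    structures: list[Structure]
    stoichiometry: Stoichiometry
    sequence_groups: dict[str, str]

    def __len__(self) -> int:
        return len(self.structures)


# ---------------------------------------------------------------------------
# Reading structures
# ---------------------------------------------------------------------------

def _select_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties broken by file order
    best = atoms[0]
    for a in atoms[1:]:
        if a.occ > best.occ:
            best = a
    return best


def read_structure(path: str | Path, dialect: str = "pdb") -> Structure:
    """Read a multimer model from a PDB or CASP TS file.

    Only the first MODEL block is used. HETATM records, waters, non-polymer
    residues and hydrogens are excluded; among altloc duplicates the highest
    occupancy atom is kept; residues without a CA atom are dropped.

    Parameters
    ----------
    path:
        PDB file. CASP TS header lines (PFRMAT, TARGET, PARENT, ...) are
        tolerated by the reader, so ``dialect`` only documents intent.
    dialect:
        ``"pdb"`` or ``"casp_ts"``.
    """
    if dialect not in ("pdb", "casp_ts"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, OSError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{path}: no MODEL block / no ATOM records")

    out = Structure(model_name=path.stem, chains=[])
    model = st[0]  # first MODEL block only
    for ch in model:
        chain = Chain(ch.name, [])
        for res in ch:
            aa = THREE_TO_ONE.get(res.name.upper())
            if res.het_flag != "A":
                # HETATM: waters, ligands, ions, modified residues
                continue
            if aa is None:
                aa = "X" if res.name.upper() == "UNK" else None
            if aa is None:
                continue  # non-standard polymer residue
            by_name: dict[str, list[gemmi.Atom]] = {}
            for a in res:
                if a.is_hydrogen():
                    continue
                by_name.setdefault(a.name, []).append(a)
            if "CA" not in by_name:
                continue  # backbone-incomplete residue: drop
            residue = Residue(
                index=len(chain.residues) + 1,
                seq_id=res.seqid.num,
                aa=aa,
                icode=(res.seqid.icode or "").strip(),
            )
            for name, cands in by_name.items():
                a = _select_altloc(cands)
                residue.atoms.append(
                    Atom(name, a.element.name, [a.pos.x, a.pos.y, a.pos.z],
                         a.occ, (a.altloc or "").strip("\x00"), a.b_iso)
                )
            chain.residues.append(residue)
        if chain.residues:
            out.chains.append(chain)
    if not out.chains:
        raise ParseError(f"{path}: no residues with CA atoms")
    return out


# ---------------------------------------------------------------------------
# Writing structures
# ---------------------------------------------------------------------------

def _to_gemmi(structure: Structure,
              bfactors: Mapping[tuple[str, int], float] | None = None) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.model_name
    model = gemmi.Model("1")
    serial = 0
    for ch in structure.chains:
        gch = gemmi.Chain(ch.chain_id)
        for res in ch.residues:
            gres = gemmi.Residue()
            gres.name = ONE_TO_THREE.get(res.aa, "UNK")
            gres.seqid = gemmi.SeqId(res.seq_id, res.icode or " ")
            gres.het_flag = "A"
            for a in res.atoms:
                serial += 1
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.coords)
                ga.occ = a.occupancy
                ga.serial = serial
                if bfactors is not None:
                    ga.b_iso = bfactors.get((ch.chain_id, res.index), 0.0)
                else:
                    ga.b_iso = a.bfactor
                gres.add_atom(ga)
            gch.add_residue(gres)
        model.add_chain(gch)
    st.add_model(model)
    st.setup_entities()
    return st


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a Structure as standard PDB text."""
    _to_gemmi(structure).write_pdb(str(path))


def write_structure_with_bfactor(
    structure: Structure,
    per_residue_scores: Mapping[tuple[str, int], float],
    path: str | Path,
) -> None:
    """Write a PDB with local quality scores in the B-factor column.

    Scores are fractions in [0, 1] keyed by ``(chain_id, residue_index)``;
    every atom of residue *r* carries ``round(score(r) * 100, 2)``. Residues
    without a score take the sentinel 0.00.
    """
    for key, s in per_residue_scores.items():
        if not (0.0 <= s <= 1.0):
            raise ValueError(f"score for residue {key} outside [0, 1]: {s}")
    bf = {k: round(v * 100.0, 2) for k, v in per_residue_scores.items()}
    _to_gemmi(structure, bfactors=bf).write_pdb(str(path))


# ---------------------------------------------------------------------------
# Stoichiometry and ensemble validation
# ---------------------------------------------------------------------------

_STOICH_TOKEN = re.compile(r"([A-Za-z])(\d*)")


def parse_stoichiometry(spec: str) -> Stoichiometry:
    """Parse a stoichiometry string such as ``"A2"``, ``"A2B2"`` or ``"A6"``.

    A missing count means one copy. Labels must be unique.
    """
    spec = spec.strip()
    if not spec:
        raise StoichiometryFormatError("empty stoichiometry string")
    groups: list[tuple[str, int]] = []
    pos = 0
    while pos < len(spec):
        m = _STOICH_TOKEN.match(spec, pos)
        if m is None:
            raise StoichiometryFormatError(
                f"malformed stoichiometry at {spec[pos:]!r} in {spec!r}")
        label = m.group(1).upper()
        count = int(m.group(2)) if m.group(2) else 1
        if count < 1:
            raise StoichiometryFormatError(
                f"copy number must be >= 1 in token {m.group(0)!r}")
        if any(label == l for l, _ in groups):
            raise StoichiometryFormatError(f"duplicate group label {label!r} in {spec!r}")
        groups.append((label, count))
        pos = m.end()
    return Stoichiometry(groups)


def sequence_groups(structure: Structure) -> dict[str, list[str]]:
    """Group chain ids of a structure by exact sequence identity.

    Returns ``{sequence: [chain_id, ...]}`` in order of first occurrence.
    """
    groups: dict[str, list[str]] = {}
    for ch in structure.chains:
        groups.setdefault(ch.sequence, []).append(ch.chain_id)
    return groups


def derive_stoichiometry(structure: Structure) -> Stoichiometry:
    """Infer a stoichiometry from a structure's own sequence groups.

    Groups are labelled A, B, ... in order of decreasing copy number (ties by
    first occurrence), with the sequences bound.
    """
    found = sorted(sequence_groups(structure).items(), key=lambda kv: -len(kv[1]))
    groups, seqs = [], {}
    for i, (seq, ids) in enumerate(found):
        label = chr(ord("A") + i)
        groups.append((label, len(ids)))
        seqs[label] = seq
    return Stoichiometry(groups, seqs)


def _match_counts(structure: Structure, stoich: Stoichiometry) -> dict[str, str] | str:
    """Assign stoichiometry labels to this structure's sequence groups.

    Returns ``{label: sequence}`` on success or an error message. Labels with
    equal copy numbers are interchangeable; assignment is by decreasing count,
    ties resolved in stoichiometry order against sequences in chain order.
    """
    found = sequence_groups(structure)
    if len(found) != len(stoich.groups):
        return (f"expected {len(stoich.groups)} distinct chain sequences, "
                f"found {len(found)}")
    want = sorted((n for _, n in stoich.groups), reverse=True)
    have = sorted((len(ids) for ids in found.values()), reverse=True)
    if want != have:
        return f"expected copy numbers {want}, found {have}"
    if stoich.sequences:
        assignment: dict[str, str] = {}
        for label, n in stoich.groups:
            seq = stoich.sequences.get(label)
            if seq is None or seq not in found or len(found[seq]) != n:
                return f"group {label}: bound sequence not found with {n} copies"
            assignment[label] = seq
        return assignment
    # stable assignment: labels and sequences each ordered by (-count, first seen)
    labels = sorted(stoich.groups, key=lambda g: -g[1])
    seqs = sorted(found.items(), key=lambda kv: -len(kv[1]))
    return {label: seq for (label, _), (seq, _) in zip(labels, seqs)}


def validate_ensemble(
    structures: Sequence[Structure],
    stoichiometry: Stoichiometry,
    target_id: str = "target",
) -> Ensemble:
    """Check every model against the stoichiometry and build an Ensemble.

    Each model's multiset of chain sequences must match the stoichiometry's
    copy numbers, and all models must share the same sequences (they model the
    same target). Chain order within a file is irrelevant.

    Raises
    ------
    ValidationError
        Listing, per rejected model, expected vs found copy numbers.
    """
    if not structures:
        raise ValidationError("no structures given")
    problems: list[str] = []
    bound: dict[str, str] | None = None
    for s in structures:
        res = _match_counts(s, stoichiometry)
        if isinstance(res, str):
            problems.append(f"{s.model_name}: {res}")
            continue
        if bound is None:
            bound = res
        elif set(bound.values()) != set(res.values()):
            problems.append(f"{s.model_name}: chain sequences differ from "
                            f"previous models of this target")
    if problems:
        raise ValidationError("stoichiometry validation failed:\n  " +
                              "\n  ".join(problems))
    assert bound is not None
    return Ensemble(target_id, list(structures), stoichiometry, bound)


# ---------------------------------------------------------------------------
# CASP QA (QMODE2) format
# ---------------------------------------------------------------------------

def write_qa_qmode2(
    model_names: Sequence[str],
    global_scores: Sequence[float],
    local_scores: Sequence[Sequence[float]],
    target_id: str,
    path: str | Path,
) -> None:
    """Write per-model global + per-residue local scores in QMODE2 layout.

    The file carries ``PFRMAT QA`` / ``TARGET <id>`` / ``MODEL <n>`` /
    ``QMODE 2`` header lines, then one block per model: the model name and its
    global score on the first line, local scores (3 decimals) wrapped at
    ``QA_SCORES_PER_LINE`` per continuation line; the file ends with ``END``.
    """
    if not model_names:
        raise EmissionError("no models to write")
    if not (len(model_names) == len(global_scores) == len(local_scores)):
        raise EmissionError("model names, global and local scores must align")
    lines = [
        "PFRMAT QA",
        f"TARGET {target_id}",
        f"MODEL {len(model_names)}",
        "QMODE 2",
    ]
    for name, g, locs in zip(model_names, global_scores, local_scores):
        locs = list(locs)
        if not locs:
            raise EmissionError(f"{name}: QMODE2 requires per-residue local scores")
        lines.append(f"{name} {g:.3f}")
        for i in range(0, len(locs), QA_SCORES_PER_LINE):
            chunk = locs[i:i + QA_SCORES_PER_LINE]
            lines.append(" ".join(f"{v:.3f}" for v in chunk))
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_qa(path: str | Path) -> tuple[str, list[tuple[str, float, list[float]]]]:
    """Parse a QMODE2 QA file written by :func:`write_qa_qmode2`.

    Returns ``(target_id, [(model_name, global, [local, ...]), ...])``.
    """
    target_id = ""
    records: list[tuple[str, float, list[float]]] = []
    current: tuple[str, float, list[float]] | None = None
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        tok = line.split()
        if tok[0] in ("PFRMAT", "MODEL", "QMODE", "AUTHOR", "METHOD", "REMARK"):
            continue
        if tok[0] == "TARGET":
            target_id = tok[1] if len(tok) > 1 else ""
            continue
        if tok[0] == "END":
            break
        try:
            values = [float(t) for t in tok]
            is_scores = True
        except ValueError:
            is_scores = False
        if is_scores and current is not None:
            current[2].extend(values)
            continue
        if is_scores:
            raise ParseError(f"{path}:{lineno}: local scores before any model line")
        # model line: <name> <global>
        if len(tok) != 2:
            raise ParseError(f"{path}:{lineno}: expected '<model> <global>'")
        if current is not None:
            records.append(current)
        current = (tok[0], float(tok[1]), [])
    if current is not None:
        records.append(current)
    if not records:
        raise ParseError(f"{path}: no model records found")
    return target_id, records
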