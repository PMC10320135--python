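"""Consensus ("jury") quality estimation from all-vs-all model comparisons.

Each model of an ensemble is scored against every other model of the same
target: entry (i, j) of a pairwise matrix holds metric(model_i scored against
model_j as reference). A model's component jury score is the mean of its row
(the mean similarity of that model to all others) — models resembling the
consensus score high, outliers score low. Three combination variants are
provided:

* linear (``jury``): equal/configurable-weight arithmetic mean of the
  component jury scores, aimed at linear correlation with observed quality;
* ranking (``jury_rank``): Borda aggregation of the within-ensemble ranks of
  each component, aimed at putting the best model first;
* single-model (``single``): one model scored against a user-supplied
  reference set instead of against co-models.

Local (per-residue) estimates are the mean per-residue oligo-lDDT of each
residue over all comparisons, with interface residues flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from . import complex_metrics as cm
from .structure_io import Ensemble, OligoQAError, Structure

__all__ = [
    "PairwiseMatrix",
    "JuryResult",
    "ConsensusError",
    "JURY_COMPONENTS",
    "pairwise_matrix",
    "jury_global",
    "combine_linear",
    "combine_for_ranking",
    "jury_scores",
    "score_single_model",
    "local_scores",
    "rank_models",
]

#: The component scoring methods of the jury, in canonical order.
JURY_COMPONENTS = ("dockq_jury", "qs_jury", "lddt_jury")

_METRIC_OF_COMPONENT = {"dockq_jury": "dockq", "qs_jury": "qs",
                        "lddt_jury": "oligo_lddt"}


class ConsensusError(OligoQAError):
    """Jury scores undefined (too few models, or a model with no comparisons)."""


@dataclass
class PairwiseMatrix:
    """All-vs-all pairwise scores for one metric.

    ``values[i, j]`` = metric(model_i against model_j as reference); the
    diagonal is NaN, as is any pair for which the metric was undefined.
    No symmetrization is applied (lDDT and DockQ are direction-sensitive).
    """

    metric: str
    model_names: list[str]
    values: np.ndarray

    @property
    def n(self) -> int:
        return len(self.model_names)


@dataclass
class JuryResult:
    """Per-model jury scores, combined scores, ranks and local estimates."""

    model_names: list[str]
    components: dict[str, np.ndarray]
    combined_linear: np.ndarray
    combined_rank_score: np.ndarray
    ranks_linear: np.ndarray
    ranks_ranking: np.ndarray
    local: list[dict[tuple[str, int], float]]
    interface_flags: list[set[tuple[str, int]]]
    provenance: dict = field(default_factory=dict)

    def governing_score(self, variant: str) -> np.ndarray:
        if variant == "linear":
            return self.combined_linear
        if variant == "rank":
            return self.combined_rank_score
        raise ValueError(f"unknown variant {variant!r}")


# ---------------------------------------------------------------------------
# Pairwise comparison layer
# ---------------------------------------------------------------------------

def _pairwise_all(ensemble: Ensemble) -> dict:
    """Compute all pairwise metrics for an ensemble (cached on the instance).

    The chain mapping is solved once per unordered pair (the shared-contact
    objective is symmetric) and inverted for the reverse direction; each
    ordered pair then yields oligo-lDDT (with its per-residue vector),
    QS-score and multimer DockQ.
    """
    cache = getattr(ensemble, "_oligoqa_pairwise", None)
    if cache is not None:
        return cache
    n = len(ensemble)
    if n < 2:
        raise ConsensusError("jury modes require at least 2 models")
    structures = ensemble.structures
    values = {m: np.full((n, n), np.nan) for m in ("oligo_lddt", "qs", "dockq")}
    per_residue: dict[tuple[int, int], dict] = {}
    for i in range(n):
        for j in range(i + 1, n):
            mapping_ij = cm.map_chains(structures[i], structures[j]).pairs
            for (a, b), mp in (((i, j), mapping_ij),
                               ((j, i), {v: k for k, v in mapping_ij.items()})):
                try:
                    r = cm.all_metrics(structures[a], structures[b], mp)
                except cm.MetricError:
                    continue
                values["oligo_lddt"][a, b] = r["oligo_lddt"].global_score
                values["qs"][a, b] = r["qs"].global_score
                values["dockq"][a, b] = r["dockq"].global_score
                per_residue[(a, b)] = r["oligo_lddt"].per_residue
    cache = {"values": values, "per_residue": per_residue,
             "names": [s.model_name for s in structures]}
    object.__setattr__(ensemble, "_oligoqa_pairwise", cache)
    return cache


def pairwise_matrix(ensemble: Ensemble, metric: str) -> PairwiseMatrix:
    """The all-vs-all matrix of one metric over the ensemble.

    ``metric`` is one of ``oligo_lddt``, ``qs``, ``dockq``. Undefined pairs
    are NaN; a model with an all-NaN row raises downstream in
    :func:`jury_global`.
    """
    if metric not in ("oligo_lddt", "qs", "dockq"):
        raise ValueError(f"unknown metric {metric!r}")
    c = _pairwise_all(ensemble)
    return PairwiseMatrix(metric, list(c["names"]), c["values"][metric].copy())


def jury_global(matrix: PairwiseMatrix) -> np.ndarray:
    """Per-model jury score: mean over j != i of value(i, j), skipping NaN."""
    vals = matrix.values.copy()
    np.fill_diagonal(vals, np.nan)
    defined = np.sum(~np.isnan(vals), axis=1)
    if np.any(defined == 0):
        bad = [matrix.model_names[i] for i in np.nonzero(defined == 0)[0]]
        raise ConsensusError(f"no defined pairwise comparisons for: {bad}")
    with np.errstate(invalid="ignore"):
        return np.nanmean(vals, axis=1)


# ---------------------------------------------------------------------------
# Score combination variants
# ---------------------------------------------------------------------------

def _normalize_weights(components: Mapping[str, np.ndarray],
                       weights: Mapping[str, float] | None) -> dict[str, float]:
    names = list(components)
    if weights is None:
        return {k: 1.0 / len(names) for k in names}
    w = {k: float(weights.get(k, 0.0)) for k in names}
    total = sum(w.values())
    if total <= 0:
        raise ValueError("component weights must have a positive sum")
    return {k: v / total for k, v in w.items()}  # silent normalization


def combine_linear(components: Mapping[str, np.ndarray],
                   weights: Mapping[str, float] | None = None) -> np.ndarray:
    """Weighted arithmetic mean of component jury scores (equal by default)."""
    w = _normalize_weights(components, weights)
    out = np.zeros_like(next(iter(components.values())), dtype=float)
    for k, vec in components.items():
        out += w[k] * np.asarray(vec, float)
    return out


def combine_for_ranking(components: Mapping[str, np.ndarray]) -> np.ndarray:
    """Borda aggregation of within-ensemble component ranks.

    Each component contributes the rank of every model (1 = best, ties share
    the mean of their ranks); ``rank_score = 1 - (mean_rank - 1) / (n - 1)``,
    so the model every component puts first scores 1 and the model every
    component puts last scores 0.
    """
    mats = [np.asarray(v, float) for v in components.values()]
    n = len(mats[0])
    if n < 2:
        raise ConsensusError("ranking undefined for fewer than 2 models")
    ranks = np.array([rankdata(-v, method="average") for v in mats])
    mean_rank = ranks.mean(axis=0)
    return 1.0 - (mean_rank - 1.0) / (n - 1.0)


def _order(scores: np.ndarray, tiebreak: np.ndarray, names: Sequence[str]) -> np.ndarray:
    keyed = sorted(range(len(names)),
                   key=lambda i: (-scores[i], -tiebreak[i], names[i]))
    ranks = np.empty(len(names), dtype=int)
    for pos, i in enumerate(keyed, start=1):
        ranks[i] = pos
    return ranks


# ---------------------------------------------------------------------------
# Local (per-residue) consensus
# ---------------------------------------------------------------------------

def local_scores(ensemble: Ensemble) -> tuple[list[dict[tuple[str, int], float]],
                                              list[set[tuple[str, int]]]]:
    """Per-model per-residue consensus scores and interface flags.

    For model i and residue r, the score is the mean over j != i of the
    per-residue oligo-lDDT of r in comparison (i, j). Every residue receives
    a score; a residue unscored in every comparison takes the sentinel 0.0.
    Interface membership (any heavy atom within 10 Å of another chain, on
    model i itself) is returned alongside.
    """
    c = _pairwise_all(ensemble)
    n = len(ensemble)
    out: list[dict[tuple[str, int], float]] = []
    flags: list[set[tuple[str, int]]] = []
    for i, s in enumerate(ensemble.structures):
        sums: dict[tuple[str, int], float] = {}
        counts: dict[tuple[str, int], int] = {}
        for j in range(n):
            if j == i or (i, j) not in c["per_residue"]:
                continue
            for key, v in c["per_residue"][(i, j)].items():
                sums[key] = sums.get(key, 0.0) + v
                counts[key] = counts.get(key, 0) + 1
        scores = {}
        for ch in s.chains:
            for res in ch.residues:
                key = (ch.chain_id, res.index)
                scores[key] = sums[key] / counts[key] if key in counts else 0.0
        out.append(scores)
        iface: set[tuple[str, int]] = set()
        for a in range(len(s.chains)):
            for b in range(a + 1, len(s.chains)):
                iface |= cm.interface_residues(
                    s, (s.chains[a].chain_id, s.chains[b].chain_id),
                    cm.INTERFACE_CUTOFF)
        flags.append(iface)
    return out, flags


# ---------------------------------------------------------------------------
# Full jury computation and ranking
# ---------------------------------------------------------------------------

def jury_scores(ensemble: Ensemble,
                weights: Mapping[str, float] | None = None) -> JuryResult:
    """Run the full jury: components, both combined variants, ranks, locals."""
    components = {
        name: jury_global(pairwise_matrix(ensemble, _METRIC_OF_COMPONENT[name]))
        for name in JURY_COMPONENTS
    }
    combined_linear = combine_linear(components, weights)
    combined_rank = combine_for_ranking(components)
    names = [s.model_name for s in ensemble.structures]
    locals_, flags = local_scores(ensemble)
    return JuryResult(
        model_names=names,
        components=components,
        combined_linear=combined_linear,
        combined_rank_score=combined_rank,
        ranks_linear=_order(combined_linear, combined_linear, names),
        ranks_ranking=_order(combined_rank, combined_linear, names),
        local=locals_,
        interface_flags=flags,
        provenance={
            "components": list(JURY_COMPONENTS),
            "weights": dict(_normalize_weights(components, weights)),
        },
    )


def score_single_model(model: Structure,
                       references: Sequence[Structure] | Ensemble,
                       weights: Mapping[str, float] | None = None) -> dict:
    """Single-model mode: score one model against a reference model set.

    Component scores are the mean of each metric over the references;
    combination and local scoring follow the linear jury. Returns a dict with
    ``components``, ``combined``, ``local`` and ``interface`` keys.
    """
    refs = list(references.structures) if isinstance(references, Ensemble) else list(references)
    if not refs:
        raise ConsensusError("single-model mode needs at least one reference")
    per_metric: dict[str, list[float]] = {m: [] for m in ("dockq", "qs", "oligo_lddt")}
    sums: dict[tuple[str, int], float] = {}
    counts: dict[tuple[str, int], int] = {}
    for ref in refs:
        res = cm.all_metrics(model, ref)
        for m in per_metric:
            per_metric[m].append(res[m].global_score)
        for key, v in res["oligo_lddt"].per_residue.items():
            sums[key] = sums.get(key, 0.0) + v
            counts[key] = counts.get(key, 0) + 1
    components = {name: np.array([np.mean(per_metric[_METRIC_OF_COMPONENT[name]])])
                  for name in JURY_COMPONENTS}
    combined = float(combine_linear(components, weights)[0])
    local = {}
    for ch in model.chains:
        for res in ch.residues:
            key = (ch.chain_id, res.index)
            local[key] = sums[key] / counts[key] if key in counts else 0.0
    iface: set[tuple[str, int]] = set()
    for a in range(len(model.chains)):
        for b in range(a + 1, len(model.chains)):
            iface |= cm.interface_residues(
                model, (model.chains[a].chain_id, model.chains[b].chain_id),
                cm.INTERFACE_CUTOFF)
    return {
        "components": {k: float(v[0]) for k, v in components.items()},
        "combined": combined,
        "local": local,
        "interface": iface,
    }


def rank_models(jury: JuryResult, variant: str = "rank",
                top_k: int | None = None) -> list[str]:
    """Model names in decreasing order of the variant's governing score.

    Ties are broken by the linear combined score and then by model name.
    """
    ranks = jury.ranks_linear if variant == "linear" else jury.ranks_ranking
    if variant not in ("linear", "rank"):
        raise ValueError(f"unknown variant {variant!r}")
    ordered = [name for _, name in sorted(zip(ranks, jury.model_names))]
    return ordered[:top_k] if top_k is not None else ordered
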