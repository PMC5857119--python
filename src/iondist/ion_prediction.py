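"""Naive-Bayes ion-type scoring at a query position in a structure.

The physicochemical environment of a position is summarized by the set
of residues whose geometry centers lie within the pairing cutoff.  For
a candidate ion type the score multiplies, over those neighbors, the
ratio of the observed pair probability to the independence baseline
p(aa) p(ion); an ion that co-occurs with the neighborhood's amino acids
more often than chance scores above 1.  The octant-resolved variant
replaces the pair probability with the probability of observing the ion
in the specific octant the query occupies in each neighbor's local
frame, exploiting the anisotropy of the ion clouds.  All scoring is
done in the log domain, so the product becomes a sum and cannot
underflow; rankings are unchanged by the monotone transform.

Candidate probabilities come from a :class:`ProbabilityModel` with
add-alpha smoothing, so unseen (amino acid, ion) combinations penalize
a candidate without annihilating it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import local_geometry as lg
from .pair_statistics import DEFAULT_CUTOFF, ProbabilityModel, StatsDB
from .structure_io import Residue, Structure

#: Default candidate set: the most abundant monoatomic ions in protein
#: structures.
DEFAULT_CANDIDATES: tuple[str, ...] = (
    "Br-", "Ca2+", "Cl-", "Cu2+", "Fe2+/3+", "K+", "Mg2+", "Mn2+", "Na+",
    "Ni2+", "Zn2+",
)


@dataclass
class NeighborContext:
    """Residues around a query position, each with the query's local
    coordinates in that residue's frame."""

    position: np.ndarray
    neighbors: list[tuple[Residue, lg.LocalCoord]] = field(
        default_factory=list)

    def __len__(self) -> int:
        return len(self.neighbors)


@dataclass
class PredictionResult:
    """Scores, descending ranking, and (optionally) the truth's rank."""

    scores: dict[str, float]
    ranking: list[str]
    ranks: dict[str, float]
    rank_of_truth: float | None = None


@dataclass
class EvaluationReport:
    """Per-ion rank summary over a labelled site collection."""

    per_ion: pd.DataFrame       # ion, n_sites, mean_rank, std_rank
    rank_cdf: pd.DataFrame      # index: rank threshold; columns: ions
    n_candidates: int


def neighbor_context(structure: Structure, position: Sequence[float],
                     cutoff: float = DEFAULT_CUTOFF) -> NeighborContext:
    """Residues whose geometry center is within ``cutoff`` of the query.

    Residues without a buildable frame are skipped.  An empty context is
    returned as-is; prediction then degenerates to the prior (all
    candidates tie).
    """
    position = np.asarray(position, dtype=float)
    if not np.all(np.isfinite(position)):
        raise ValueError("query position must be finite")
    ctx = NeighborContext(position=position)
    for res in structure.residues:
        try:
            frame = lg.build_frame(res)
        except (lg.FrameUndefined, lg.FrameDegenerate):
            continue
        if np.linalg.norm(position - frame.origin) <= cutoff:
            ctx.neighbors.append((res, lg.to_local(frame, position)))
    return ctx


def score_ion(model: ProbabilityModel | StatsDB, context: NeighborContext,
              ion: str, mode: str = "pair") -> float:
    """Log-domain score of one candidate ion for a neighbor context.

    ``mode`` is ``"pair"`` (amino-acid co-occurrence only) or
    ``"octant"`` (octant-resolved).  An empty context scores 0 for every
    candidate.
    """
    if isinstance(model, StatsDB):
        model = ProbabilityModel.from_statsdb(model)
    if mode not in ("pair", "octant"):
        raise ValueError(f"unknown mode {mode!r}")
    ii = model.ion_index(ion)
    score = 0.0
    for res, local in context.neighbors:
        ai = model.aa_index(res.aa_type)
        if mode == "pair":
            num = model.p_pair[ai, ii]
        else:
            num = model.p_octant[ai, ii, local.octant]
        score += float(np.log(num) - np.log(model.p_aa[ai])
                       - np.log(model.p_ion[ii]))
    return score


def score_all(model: ProbabilityModel, context: NeighborContext,
              candidates: Sequence[str], mode: str = "pair"
              ) -> dict[str, float]:
    return {ion: score_ion(model, context, ion, mode) for ion in candidates}


def rank_ions(scores: Mapping[str, float],
              truth: str | None = None) -> PredictionResult:
    """Rank candidates by descending score; tied scores share the
    average of the ranks they cover (best possible rank is 1)."""
    if not scores:
        raise ValueError("at least one candidate required")
    ions = sorted(scores)
    values = np.array([scores[i] for i in ions])
    ranks = rankdata(-values, method="average")
    by_rank = dict(zip(ions, ranks))
    ranking = [ion for _, ion in sorted(zip(ranks, ions))]
    rank_of_truth = None
    if truth is not None:
        if truth not in by_rank:
            raise KeyError(f"truth {truth!r} not among candidates {ions}")
        rank_of_truth = float(by_rank[truth])
    return PredictionResult(scores=dict(scores), ranking=ranking,
                            ranks={i: float(r) for i, r in by_rank.items()},
                            rank_of_truth=rank_of_truth)


def predict(model: ProbabilityModel | StatsDB, structure: Structure,
            position: Sequence[float], mode: str = "pair",
            candidates: Sequence[str] = DEFAULT_CANDIDATES,
            cutoff: float = DEFAULT_CUTOFF) -> PredictionResult:
    """Score and rank all candidate ion types at a position."""
    if isinstance(model, StatsDB):
        model = ProbabilityModel.from_statsdb(model, ions=candidates)
    ctx = neighbor_context(structure, position, cutoff)
    return rank_ions(score_all(model, ctx, candidates, mode))


def evaluate(model: ProbabilityModel | StatsDB,
             sites: Iterable[tuple[Structure, Sequence[float], str]],
             mode: str = "pair",
             candidates: Sequence[str] = DEFAULT_CANDIDATES,
             cutoff: float = DEFAULT_CUTOFF) -> EvaluationReport:
    """Rank the true ion type at each labelled site and summarize.

    Each site is (structure with the ion removed, the ion's position,
    the true ion label).  The report carries per-ion mean rank and
    population standard deviation plus the cumulative distribution of
    ranks (fraction of sites with rank <= k).
    """
    if isinstance(model, StatsDB):
        model = ProbabilityModel.from_statsdb(model, ions=candidates)
    import logging

    logger = logging.getLogger(__name__)
    ranks_by_ion: dict[str, list[float]] = {}
    for structure, position, truth in sites:
        if truth not in candidates:
            logger.warning("site with ion %r skipped: not a candidate",
                           truth)
            continue
        ctx = neighbor_context(structure, position, cutoff)
        result = rank_ions(score_all(model, ctx, candidates, mode),
                           truth=truth)
        ranks_by_ion.setdefault(truth, []).append(result.rank_of_truth)
    rows = []
    cdf_cols = {}
    thresholds = np.arange(1, len(candidates) + 1)
    for ion in sorted(ranks_by_ion):
        arr = np.array(ranks_by_ion[ion])
        rows.append({
            "ion": ion,
            "n_sites": arr.size,
            "mean_rank": float(arr.mean()),
            "std_rank": float(arr.std()),
        })
        cdf_cols[ion] = [(arr <= k).mean() for k in thresholds]
    per_ion = pd.DataFrame(
        rows, columns=["ion", "n_sites", "mean_rank", "std_rank"])
    rank_cdf = pd.DataFrame(cdf_cols, index=thresholds)
    rank_cdf.index.name = "rank"
    return EvaluationReport(per_ion=per_ion, rank_cdf=rank_cdf,
                            n_candidates=len(candidates))
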