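"""Evaluation of ranked gene lists against a ground-truth gene set.

Two summaries of how far up a ranked list the known cancer genes sit:

* the top-p% protocol: how many truth genes appear within the top p% of
  the ranking, and the mean rank of those that do appear;
* the mean rank of all truth genes over the full list (no cutoff), the
  quantity used in the teleportation and mixture-weight sweeps.

Both are kept distinct on purpose: the first rewards concentrating a few
truth genes at the very top, the second penalizes burying any of them.
Plus standard precision/recall curves over every rank threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .construction import GeneUniverse, load_gene_list
from .models import AdditiveWeights, scores_to_ranks
from .pipeline import Cohort, normalize_model_id, rank
from .transitions import DEFAULT_ALPHA

logger = logging.getLogger(__name__)

__all__ = [
    "GroundTruthSet",
    "OVARIAN_TRUTH_GENES",
    "TopPercentReport",
    "PRCurve",
    "top_percent_report",
    "precision_recall_curve",
    "mean_truth_rank",
    "alpha_sweep",
    "additive_weight_grid",
    "WeightGridResult",
]

#: curated ovarian-cancer genes used as the reference ground-truth fixture
OVARIAN_TRUTH_GENES = (
    "BRCA1", "BRCA2", "BMPR1A", "BRIP1", "MLH1", "FHIT", "TFRC", "FGFR2",
    "GATA3", "MYST4", "PTEN", "FAS", "RB1", "SEPT9", "YWHAE", "TP53",
    "PIK3CA", "BRAF", "KRAS", "AIB1", "MSH2", "BMP4", "TRIP1", "MYC", "EP300",
)


@dataclass(frozen=True)
class GroundTruthSet:
    """Set of known driver genes to score rankings against."""

    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("ground-truth set must be nonempty")

    @classmethod
    def from_iterable(cls, genes: Iterable[str]) -> "GroundTruthSet":
        return cls(frozenset(genes))

    @classmethod
    def ovarian(cls) -> "GroundTruthSet":
        """The bundled curated ovarian-cancer gene set."""
        return cls(frozenset(OVARIAN_TRUTH_GENES))

    @classmethod
    def from_file(cls, path) -> "GroundTruthSet":
        return cls(frozenset(load_gene_list(path)))


@dataclass(frozen=True)
class TopPercentReport:
    """Truth-gene count and mean rank within the top-p% cutoff of a ranking."""

    model_id: str
    appearances: int
    average_rank: float | None
    cutoff: int
    percent: float


@dataclass(frozen=True)
class PRCurve:
    """Precision/recall at every rank threshold k = 1..n."""

    points: tuple[tuple[int, float, float], ...]  # (k, precision, recall)


Ranking = Sequence[tuple[str, float, int]]


def _truth_ranks(ranks: Ranking, truth: GroundTruthSet) -> list[int]:
    in_universe = {g for g, _, _ in ranks} & truth.genes
    missing = truth.genes - in_universe
    if missing:
        logger.info("evaluation: %d truth genes absent from the universe", len(missing))
    if not in_universe:
        raise ValueError("no ground-truth gene is present in the ranked universe")
    return sorted(r for g, _, r in ranks if g in in_universe)


def top_percent_report(
    ranks: Ranking,
    truth: GroundTruthSet,
    percent: float = 1.0,
    model_id: str = "",
) -> TopPercentReport:
    """Count truth genes within the top ``percent`` of the ranking.

    The cutoff is ceil(percent/100 * n) genes; ``average_rank`` is the mean
    1-based rank of the truth genes found at or above the cutoff, or None
    when none appear.
    """
    if not 0 < percent <= 100:
        raise ValueError("percent must lie in (0, 100]")
    n = len(ranks)
    cutoff = math.ceil(percent / 100.0 * n)
    tranks = _truth_ranks(ranks, truth)
    found = [r for r in tranks if r <= cutoff]
    avg = float(np.mean(found)) if found else None
    return TopPercentReport(model_id, len(found), avg, cutoff, percent)


def precision_recall_curve(ranks: Ranking, truth: GroundTruthSet) -> PRCurve:
    """Precision and recall at every rank threshold.

    precision(k) = hits(k)/k; recall(k) = hits(k)/|truth in universe|,
    where hits(k) counts truth genes at rank <= k.
    """
    tranks = set(_truth_ranks(ranks, truth))
    denom = len(tranks)
    points = []
    hits = 0
    for k in range(1, len(ranks) + 1):
        if k in tranks:
            hits += 1
        points.append((k, hits / k, hits / denom))
    return PRCurve(tuple(points))


def mean_truth_rank(ranks: Ranking, truth: GroundTruthSet) -> float:
    """Mean 1-based rank of the truth genes over the full list (no cutoff)."""
    return float(np.mean(_truth_ranks(ranks, truth)))


def alpha_sweep(
    cohort: Cohort,
    model_id: str,
    truth: GroundTruthSet,
    grid: Sequence[float] | None = None,
    **rank_kwargs,
) -> list[tuple[float, float]]:
    """Mean truth rank as a function of the teleportation parameter.

    Rebuilds Cr/Cc for each alpha in the grid (default 0.0, 0.05, ..., 0.95)
    and reruns the model; deterministic and side-effect free.
    """
    if grid is None:
        grid = [round(0.05 * i, 2) for i in range(20)]
    out = []
    for alpha in grid:
        result = rank(cohort, model_id, alpha=alpha, **rank_kwargs)
        ranking = scores_to_ranks(result.mu, cohort.universe)
        out.append((float(alpha), mean_truth_rank(ranking, truth)))
    return out


@dataclass(frozen=True)
class WeightGridResult:
    """Mean truth rank over the additive-weight simplex grid.

    ``points`` maps each (w_pm, w_ppi, w_corr) triple to its mean truth
    rank; ``best_per_fixed[name]`` holds, for the named weight held at
    each grid value, (fixed_value, best_mean_rank, best_triple) — the
    minimum over the free pair and the triple achieving it.
    """

    points: tuple[tuple[tuple[float, float, float], float], ...]
    best_per_fixed: dict[
        str, tuple[tuple[float, float, tuple[float, float, float]], ...]
    ]


def additive_weight_grid(
    cohort: Cohort,
    truth: GroundTruthSet,
    step: float = 0.1,
    alpha: float = DEFAULT_ALPHA,
    **rank_kwargs,
) -> WeightGridResult:
    """Evaluate RW-AM over the simplex grid of mixture weights.

    Enumerates all (w_pm, w_ppi, w_corr) with each weight a multiple of
    ``step`` and the three summing to 1, and records the mean truth rank of
    each run.  For each weight fixed at each grid value the best result
    over the free pair is reported, mirroring a one-at-a-time sensitivity
    scan of the mixture.
    """
    s = round(1.0 / step)
    if abs(s * step - 1.0) > 1e-9 or s < 1:
        raise ValueError("step must evenly divide 1.0")
    points = []
    for i in range(s + 1):
        for j in range(s + 1 - i):
            k = s - i - j
            triple = (i / s, j / s, k / s)
            result = rank(
                cohort,
                "RW-AM",
                alpha=alpha,
                weights=AdditiveWeights(*triple),
                **rank_kwargs,
            )
            ranking = scores_to_ranks(result.mu, cohort.universe)
            points.append((triple, mean_truth_rank(ranking, truth)))

    best_per_fixed: dict[str, tuple] = {}
    for axis, name in enumerate(("w_pm", "w_ppi", "w_corr")):
        rows = []
        for v in range(s + 1):
            fixed = v / s
            cands = [(t, mr) for t, mr in points if abs(t[axis] - fixed) < 1e-12]
            best_triple, best_rank = min(cands, key=lambda tm: tm[1])
            rows.append((fixed, best_rank, best_triple))
        best_per_fixed[name] = tuple(rows)
    return WeightGridResult(tuple(points), best_per_fixed)
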