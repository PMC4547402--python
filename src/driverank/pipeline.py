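"""High-level pipeline: files -> aligned cohort -> ranked genes.

`Cohort` bundles the aligned mutation profile, PPI network, expression
matrix and the derived co-expression network; :func:`rank` dispatches any
model id, building the transition operators for the requested
teleportation parameter on the fly (cheap at the dense scales this package
targets, and what the alpha sweep needs anyway).
"""

from __future__ import annotations

from dataclasses import dataclass

from .construction import (
    CorrelationNetwork,
    ExpressionMatrix,
    GeneNetwork,
    MutationProfile,
    align,
    compute_correlation_network,
    load_expression,
    load_mutation_profile,
    load_ppi,
)
from .models import (
    DEFAULT_MAX_ITER,
    DEFAULT_TOL,
    DEFAULT_WEIGHTS,
    AdditiveWeights,
    MMASchedule,
    MODEL_IDS,
    RankResult,
    benchmark_frequency,
    benchmark_rw_gc,
    benchmark_rw_pm,
    rank_rw_am,
    rank_rw_mma,
    rank_rw_mmgcs,
    rank_rw_mmgis,
    rank_rw_mmp,
    rank_rw_mmpfs,
)
from .transitions import (
    DEFAULT_ALPHA,
    build_penalized_transition,
    build_transition_set,
)

__all__ = ["Cohort", "prepare", "rank", "normalize_model_id"]


@dataclass
class Cohort:
    """Aligned data bundle shared by every model and evaluation sweep."""

    profile: MutationProfile
    network: GeneNetwork
    expression: ExpressionMatrix
    corr: CorrelationNetwork

    @property
    def universe(self):
        return self.profile.universe

    @property
    def cohort_ids(self):
        return self.profile.cohort


def prepare(
    profile: MutationProfile, network: GeneNetwork, expression: ExpressionMatrix
) -> Cohort:
    """Align the three sources and derive the co-expression network."""
    profile, network, expression = align(profile, network, expression)
    corr = compute_correlation_network(expression)
    return Cohort(profile, network, expression, corr)


def load_cohort(ppi_path, expression_path, mutations_path) -> Cohort:
    """Load the three TSV inputs and prepare an aligned cohort."""
    return prepare(
        load_mutation_profile(mutations_path),
        load_ppi(ppi_path),
        load_expression(expression_path),
    )


def normalize_model_id(model_id: str) -> str:
    """Accept case-insensitive ids with '-' or '_' separators."""
    canon = model_id.strip().upper().replace("_", "-")
    if canon not in MODEL_IDS:
        raise ValueError(f"unknown model {model_id!r}; choose from {', '.join(MODEL_IDS)}")
    return canon


def rank(
    cohort: Cohort,
    model_id: str,
    alpha: float = DEFAULT_ALPHA,
    weights: AdditiveWeights = DEFAULT_WEIGHTS,
    schedule: MMASchedule | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> RankResult:
    """Run one model on an aligned cohort and return its stationary scores."""
    model_id = normalize_model_id(model_id)
    if model_id == "FREQ":
        return benchmark_frequency(cohort.profile)
    ts = build_transition_set(cohort.profile, cohort.network, cohort.corr, alpha=alpha)
    if model_id == "RW-MMGCS":
        return rank_rw_mmgcs(ts, tol=tol, max_iter=max_iter)
    if model_id == "RW-MMGIS":
        return rank_rw_mmgis(ts, tol=tol, max_iter=max_iter)
    if model_id == "RW-AM":
        return rank_rw_am(ts, weights=weights, tol=tol, max_iter=max_iter)
    if model_id == "RW-MMP":
        _, Cg_pen = build_penalized_transition(cohort.network, cohort.corr)
        return rank_rw_mmp(ts, Cg_pen, tol=tol, max_iter=max_iter)
    if model_id == "RW-MMA":
        return rank_rw_mma(ts, schedule=schedule, tol=tol, max_iter=max_iter)
    if model_id == "RW-MMPFS":
        return rank_rw_mmpfs(ts, tol=tol, max_iter=max_iter)
    if model_id == "RW-GC":
        return benchmark_rw_gc(ts, tol=tol, max_iter=max_iter)
    if model_id == "RW-PM":
        return benchmark_rw_pm(ts, tol=tol, max_iter=max_iter)
    raise AssertionError(model_id)  # unreachable
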