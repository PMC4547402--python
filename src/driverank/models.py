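"""Stationary-distribution ranking models.

Each model defines a Markov chain on genes (and, for most, a companion
chain on patients) as a product or mixture of the four transition
operators, then ranks genes by their mass in the chain's stationary
distribution.  With teleportation ``alpha < 1`` every chain operator is a
strictly positive column-stochastic map of the probability simplex, so a
unique strictly positive stationary vector exists and power iteration
converges to it from any start.

Integrated models
-----------------
==========  ==========================================================
RW-MMGCS    mu = Cr^T Cc Cg^T Ch^T mu   (walk starts on co-expression)
RW-MMGIS    mu = Cr^T Cc Ch^T Cg^T mu   (walk starts on PPI)
RW-AM       mu = (w_pm Cr^T Cc + w_ppi Cg^T + w_corr Ch^T) mu
RW-MMP      mu = Cr^T Cc Cgpen^T mu     (correlation-penalized PPI)
RW-MMA      per-iteration average of the three component updates
RW-MMPFS    mu = Ch^T Cg^T Cr^T Cc mu   (walk starts on the bipartite graph)
==========  ==========================================================

Benchmarks: FREQ (normalized mutation counts), RW-GC (damped
co-expression walk only) and RW-PM (bipartite walk only).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .construction import GeneUniverse, MutationProfile
from .transitions import TransitionSet

__all__ = [
    "RankResult",
    "AdditiveWeights",
    "MMASchedule",
    "ConvergenceError",
    "stationary",
    "rank_rw_mmgcs",
    "rank_rw_mmgis",
    "rank_rw_am",
    "rank_rw_mmp",
    "rank_rw_mma",
    "rank_rw_mmpfs",
    "benchmark_frequency",
    "benchmark_rw_gc",
    "benchmark_rw_pm",
    "scores_to_ranks",
    "MODEL_IDS",
    "INTEGRATED_MODELS",
    "BENCHMARK_MODELS",
    "DEFAULT_TOL",
    "DEFAULT_MAX_ITER",
    "DEFAULT_WEIGHTS",
]

DEFAULT_TOL = 1e-10
DEFAULT_MAX_ITER = 10000

INTEGRATED_MODELS = ("RW-MMGCS", "RW-MMGIS", "RW-AM", "RW-MMP", "RW-MMA", "RW-MMPFS")
BENCHMARK_MODELS = ("RW-GC", "RW-PM", "FREQ")
MODEL_IDS = INTEGRATED_MODELS + BENCHMARK_MODELS


class ConvergenceError(RuntimeError):
    """Power iteration failed to reach tolerance within max_iter steps."""

    def __init__(self, iterations: int, residual: float, tol: float):
        self.iterations = iterations
        self.residual = residual
        self.tol = tol
        super().__init__(
            f"no convergence after {iterations} iterations "
            f"(L1 residual {residual:.3e}, tol {tol:.1e})"
        )


@dataclass
class RankResult:
    """Stationary scores: gene vector mu, optional patient vector pi, diagnostics."""

    model_id: str
    mu: np.ndarray
    pi: np.ndarray | None
    iterations: int
    residual: float
    pi_iterations: int | None = None
    pi_residual: float | None = None


@dataclass(frozen=True)
class AdditiveWeights:
    """Mixture weights of the additive model: bipartite, PPI and co-expression shares.

    (These are the additive model's own three weights, kept distinct from
    the teleportation parameter alpha of Cr/Cc.)
    """

    w_pm: float = 0.3
    w_ppi: float = 0.3
    w_corr: float = 0.4

    def __post_init__(self) -> None:
        for w in (self.w_pm, self.w_ppi, self.w_corr):
            if w < 0:
                raise ValueError("additive weights must be nonnegative")
        if abs(self.w_pm + self.w_ppi + self.w_corr - 1.0) > 1e-12:
            raise ValueError(
                f"additive weights must sum to 1, got {self.w_pm + self.w_ppi + self.w_corr!r}"
            )


DEFAULT_WEIGHTS = AdditiveWeights()


@dataclass(frozen=True)
class MMASchedule:
    """Iteration caps (l, m, r) of the finite multiplicative-average schedule."""

    l: int
    m: int
    r: int

    def __post_init__(self) -> None:
        if min(self.l, self.m, self.r) < 1:
            raise ValueError("schedule caps l, m, r must all be >= 1")


def stationary(
    apply_chain: Callable[[np.ndarray], np.ndarray],
    k: int,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    start: np.ndarray | None = None,
) -> tuple[np.ndarray, int, float]:
    """Power iteration for the stationary vector of a simplex-preserving map.

    Starts from the uniform distribution (or ``start``), renormalizes
    defensively each step, and stops when the L1 change drops below ``tol``.
    Raises :class:`ConvergenceError` carrying the last residual otherwise
    (e.g. for a periodic chain without teleportation).
    """
    if start is None:
        v = np.full(k, 1.0 / k)
    else:
        v = np.asarray(start, dtype=float)
        if v.shape != (k,) or (v < 0).any() or v.sum() <= 0:
            raise ValueError("start must be a length-k nonnegative vector with positive mass")
        v = v / v.sum()
    residual = np.inf
    for it in range(1, max_iter + 1):
        w = np.asarray(apply_chain(v), dtype=float)
        w = w / w.sum()
        residual = float(np.abs(w - v).sum())
        v = w
        if residual < tol:
            return v, it, residual
    raise ConvergenceError(max_iter, residual, tol)


def _solve(
    model_id: str,
    mu_chain: Callable[[np.ndarray], np.ndarray],
    n: int,
    pi_chain: Callable[[np.ndarray], np.ndarray] | None,
    m: int | None,
    tol: float,
    max_iter: int,
    start: np.ndarray | None = None,
) -> RankResult:
    mu, it, res = stationary(mu_chain, n, tol=tol, max_iter=max_iter, start=start)
    if pi_chain is None:
        return RankResult(model_id, mu, None, it, res)
    pi, itp, resp = stationary(pi_chain, m, tol=tol, max_iter=max_iter)
    return RankResult(model_id, mu, pi, it, res, itp, resp)


def rank_rw_mmgcs(
    ts: TransitionSet,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    start: np.ndarray | None = None,
) -> RankResult:
    """Multiplicative chain starting on the co-expression network.

    mu = Cr^T Cc Cg^T Ch^T mu;  pi = Cc Cg^T Ch^T Cr^T pi.
    """
    f = lambda v: ts.Cr.T @ (ts.Cc @ (ts.Cg.T @ (ts.Ch.T @ v)))
    g = lambda p: ts.Cc @ (ts.Cg.T @ (ts.Ch.T @ (ts.Cr.T @ p)))
    return _solve("RW-MMGCS", f, ts.n_genes, g, ts.n_patients, tol, max_iter, start)


def rank_rw_mmgis(
    ts: TransitionSet,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    start: np.ndarray | None = None,
) -> RankResult:
    """Multiplicative chain starting on the PPI network.

    mu = Cr^T Cc Ch^T Cg^T mu;  pi = Cc Ch^T Cg^T Cr^T pi.
    """
    f = lambda v: ts.Cr.T @ (ts.Cc @ (ts.Ch.T @ (ts.Cg.T @ v)))
    g = lambda p: ts.Cc @ (ts.Ch.T @ (ts.Cg.T @ (ts.Cr.T @ p)))
    return _solve("RW-MMGIS", f, ts.n_genes, g, ts.n_patients, tol, max_iter, start)


def rank_rw_am(
    ts: TransitionSet,
    weights: AdditiveWeights = DEFAULT_WEIGHTS,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    start: np.ndarray | None = None,
) -> RankResult:
    """Additive mixture of the three gene-level transition operators.

    mu = (w_pm Cr^T Cc + w_ppi Cg^T + w_corr Ch^T) mu;
    pi = Cc Cg^T Ch^T Cr^T pi.
    """
    f = lambda v: (
        weights.w_pm * (ts.Cr.T @ (ts.Cc @ v))
        + weights.w_ppi * (ts.Cg.T @ v)
        + weights.w_corr * (ts.Ch.T @ v)
    )
    g = lambda p: ts.Cc @ (ts.Cg.T @ (ts.Ch.T @ (ts.Cr.T @ p)))
    return _solve("RW-AM", f, ts.n_genes, g, ts.n_patients, tol, max_iter, start)


def rank_rw_mmp(
    ts: TransitionSet,
    Cg_pen: np.ndarray,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    start: np.ndarray | None = None,
) -> RankResult:
    """Multiplicative chain on the correlation-penalized PPI walk.

    mu = Cr^T Cc Cgpen^T mu;  pi = Cc Cgpen^T Cr^T pi.
    """
    f = lambda v: ts.Cr.T @ (ts.Cc @ (Cg_pen.T @ v))
    g = lambda p: ts.Cc @ (Cg_pen.T @ (ts.Cr.T @ p))
    return _solve("RW-MMP", f, ts.n_genes, g, ts.n_patients, tol, max_iter, start)


def rank_rw_mma(
    ts: TransitionSet,
    schedule: MMASchedule | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    start: np.ndarray | None = None,
) -> RankResult:
    """Average of the three component updates each iteration.

    Default mode runs all three components every iteration until the L1
    change drops below ``tol``.  Passing an explicit ``schedule`` instead
    runs the literal finite schedule: component x contributes at iteration
    t only while t <= its cap, and the update is the mean of the active
    components.  No patient chain is defined for this model.
    """
    comps = (
        lambda v: ts.Cr.T @ (ts.Cc @ v),
        lambda v: ts.Cg.T @ v,
        lambda v: ts.Ch.T @ v,
    )
    if schedule is None:
        f = lambda v: (comps[0](v) + comps[1](v) + comps[2](v)) / 3.0
        mu, it, res = stationary(f, ts.n_genes, tol=tol, max_iter=max_iter, start=start)
        return RankResult("RW-MMA", mu, None, it, res)

    caps = (schedule.l, schedule.m, schedule.r)
    n = ts.n_genes
    v = np.full(n, 1.0 / n) if start is None else np.asarray(start, float) / np.sum(start)
    residual = 0.0
    total = max(caps)
    for t in range(1, total + 1):
        active = [comp(v) for comp, cap in zip(comps, caps) if t <= cap]
        w = sum(active) / len(active)
        w = w / w.sum()
        residual = float(np.abs(w - v).sum())
        v = w
    return RankResult("RW-MMA", v, None, total, residual)


def rank_rw_mmpfs(
    ts: TransitionSet,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    start: np.ndarray | None = None,
) -> RankResult:
    """Multiplicative chain starting on the patient--gene bipartite graph.

    mu = Ch^T Cg^T Cr^T Cc mu;  pi = Cc Cg^T Ch^T Cr^T pi.
    """
    f = lambda v: ts.Ch.T @ (ts.Cg.T @ (ts.Cr.T @ (ts.Cc @ v)))
    g = lambda p: ts.Cc @ (ts.Cg.T @ (ts.Ch.T @ (ts.Cr.T @ p)))
    return _solve("RW-MMPFS", f, ts.n_genes, g, ts.n_patients, tol, max_iter, start)


def benchmark_frequency(profile: MutationProfile) -> RankResult:
    """Mutation-frequency baseline: mu proportional to per-gene mutation counts."""
    counts = profile.B.sum(axis=0).astype(float)
    if (counts == 0).any():
        raise ValueError("profile has a never-mutated gene; run align first")
    mu = counts / counts.sum()
    return RankResult("FREQ", mu, None, 0, 0.0)


def benchmark_rw_gc(
    ts: TransitionSet,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    start: np.ndarray | None = None,
) -> RankResult:
    """Damped walk on the co-expression network alone.

    mu = (alpha Ch^T + (1-alpha)/n) mu.  The same teleportation damping as
    the integrated models is applied so the chain is irreducible even when
    the correlation graph is disconnected.  No patient chain.
    """
    n = ts.n_genes
    f = lambda v: ts.alpha * (ts.Ch.T @ v) + (1.0 - ts.alpha) / n
    mu, it, res = stationary(f, n, tol=tol, max_iter=max_iter, start=start)
    return RankResult("RW-GC", mu, None, it, res)


def benchmark_rw_pm(
    ts: TransitionSet,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    start: np.ndarray | None = None,
) -> RankResult:
    """Bipartite patient-mutation walk alone.

    mu = Cr^T Cc mu;  pi = Cc Cr^T pi.
    """
    f = lambda v: ts.Cr.T @ (ts.Cc @ v)
    g = lambda p: ts.Cc @ (ts.Cr.T @ p)
    return _solve("RW-PM", f, ts.n_genes, g, ts.n_patients, tol, max_iter, start)


def scores_to_ranks(
    mu: np.ndarray, universe: GeneUniverse
) -> list[tuple[str, float, int]]:
    """Order genes by descending score; ties break lexicographically; ranks are 1-based."""
    mu = np.asarray(mu, dtype=float)
    if mu.shape != (len(universe),):
        raise ValueError("score vector length does not match the gene universe")
    order = sorted(zip(universe.genes, mu), key=lambda gs: (-gs[1], gs[0]))
    return [(g, float(s), r) for r, (g, s) in enumerate(order, start=1)]
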