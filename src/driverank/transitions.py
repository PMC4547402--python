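"""Stochastic transition operators of the patient--gene random walk.

Four operators drive every model:

* ``Cr`` (m x n, row-stochastic): patient -> gene moves.  With probability
  ``alpha`` the patient follows the bipartite edge distribution ``Br``
  (uniform over their mutated genes); with probability ``1 - alpha`` they
  teleport to a uniformly random gene.
* ``Cc`` (m x n, column-stochastic): gene -> patient moves, the analogous
  damping of ``Bc`` (uniform over the patients carrying the gene).
* ``Cg`` (n x n, row-stochastic): one step of the degree-normalized PPI walk
  D^-1 W.
* ``Ch`` (n x n, row-stochastic): one step of the co-expression walk, the
  row normalization of |H| (absolute correlation; see the methods note for
  why signed correlations cannot be used as transition probabilities).

Teleportation with ``alpha < 1`` makes every entry of ``Cr`` and ``Cc``
strictly positive, which is what guarantees a unique, strictly positive
stationary distribution for every product chain (Perron-Frobenius).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .construction import (
    CorrelationNetwork,
    GeneNetwork,
    GeneUniverse,
    MutationProfile,
    PatientCohort,
)

__all__ = [
    "TransitionSet",
    "PenaltyContext",
    "build_bipartite_stochastics",
    "apply_teleportation",
    "build_gene_transition",
    "build_correlation_transition",
    "build_penalized_transition",
    "build_transition_set",
    "DEFAULT_ALPHA",
]

#: teleportation parameter used throughout unless overridden
DEFAULT_ALPHA = 0.75

SIGMA_FLOOR = 1e-6


@dataclass
class TransitionSet:
    """The four stochastic operators on one aligned gene/patient universe."""

    alpha: float
    Cr: np.ndarray  # m x n, row-stochastic   (patient -> gene)
    Cc: np.ndarray  # m x n, column-stochastic (gene -> patient)
    Cg: np.ndarray  # n x n, row-stochastic   (PPI walk)
    Ch: np.ndarray  # n x n, row-stochastic   (co-expression walk)
    universe: GeneUniverse | None = None
    cohort: PatientCohort | None = None

    @property
    def n_genes(self) -> int:
        return self.Cr.shape[1]

    @property
    def n_patients(self) -> int:
        return self.Cr.shape[0]


@dataclass(frozen=True)
class PenaltyContext:
    """Correlation-penalty scale sigma = mean(H) and the penalized weights."""

    sigma: float
    Wpen: np.ndarray


def build_bipartite_stochastics(profile: MutationProfile) -> tuple[np.ndarray, np.ndarray]:
    """Row- and column-normalize the binary mutation matrix B.

    ``Br[i, j] = B[i, j] / sum_k B[i, k]`` (patient i hops uniformly to one
    of their mutated genes) and ``Bc[i, j] = B[i, j] / sum_k B[k, j]`` (gene
    j hops uniformly to one of its carriers).  Requires an aligned profile:
    every row and column of B must be nonzero.
    """
    B = profile.B.astype(float)
    row_sums = B.sum(axis=1)
    col_sums = B.sum(axis=0)
    if (row_sums == 0).any():
        raise ValueError("mutation profile has a patient with no mutations; run align first")
    if (col_sums == 0).any():
        raise ValueError("mutation profile has a never-mutated gene; run align first")
    return B / row_sums[:, None], B / col_sums[None, :]


def _check_alpha(alpha: float) -> None:
    if not 0.0 <= alpha < 1.0:
        raise ValueError(
            f"alpha must lie in [0, 1); got {alpha} "
            "(alpha = 1 loses the strict positivity that guarantees a unique stationary vector)"
        )


def apply_teleportation(Br: np.ndarray, Bc: np.ndarray, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    """Damp the bipartite operators with uniform teleportation.

    Cr = alpha*Br + (1-alpha)/n, Cc = alpha*Bc + (1-alpha)/m.  All entries
    become strictly positive for alpha < 1.
    """
    _check_alpha(alpha)
    m, n = Br.shape
    Cr = alpha * Br + (1.0 - alpha) / n
    Cc = alpha * Bc + (1.0 - alpha) / m
    return Cr, Cc


def _row_normalize(M: np.ndarray) -> np.ndarray:
    """D^-1 M with the PageRank dangling-row convention: zero rows become uniform."""
    n = M.shape[0]
    d = M.sum(axis=1)
    out = np.empty_like(M, dtype=float)
    dangling = d == 0
    if (~dangling).any():
        out[~dangling] = M[~dangling] / d[~dangling, None]
    if dangling.any():
        out[dangling] = 1.0 / n
    return out


def build_gene_transition(network: GeneNetwork) -> np.ndarray:
    """PPI walk Cg = D^-1 W; isolated genes get a uniform row."""
    return _row_normalize(network.W)


def build_correlation_transition(corr: CorrelationNetwork) -> np.ndarray:
    """Co-expression walk Ch = D^-1 |H|; zero-correlation rows get a uniform row."""
    return _row_normalize(np.abs(corr.H))


def build_penalized_transition(
    network: GeneNetwork, corr: CorrelationNetwork
) -> tuple[PenaltyContext, np.ndarray]:
    """Merge PPI and co-expression into one walk: Wpen = W * exp(H / sigma).

    ``sigma`` is the mean over all n^2 entries of H (the zero diagonal
    included).  Each PPI edge is up- or down-weighted by how far its
    endpoints' co-expression sits above or below the network-wide average.
    A near-zero sigma would blow up the exponent, so it is rejected.
    """
    if network.W.shape != corr.H.shape:
        raise ValueError("W and H must share one gene universe")
    sigma = float(corr.H.mean())
    if abs(sigma) < SIGMA_FLOOR:
        raise ValueError(
            f"penalty scale degenerate: |mean(H)| = {abs(sigma):.2e} < {SIGMA_FLOOR}"
        )
    # Row-normalizing cancels any common factor, so the stochastic operator is
    # computed in log space (softmax-style) to survive large |H|/sigma ratios.
    with np.errstate(divide="ignore"):
        logWpen = np.where(network.W > 0, np.log(network.W), -np.inf) + corr.H / sigma
    n = logWpen.shape[0]
    Cg_pen = np.empty_like(logWpen)
    rowmax = logWpen.max(axis=1)
    dangling = np.isneginf(rowmax)
    Cg_pen[dangling] = 1.0 / n
    if (~dangling).any():
        shifted = np.exp(logWpen[~dangling] - rowmax[~dangling, None])
        Cg_pen[~dangling] = shifted / shifted.sum(axis=1, keepdims=True)
    with np.errstate(over="ignore", invalid="ignore"):
        Wpen = np.where(network.W > 0, network.W * np.exp(corr.H / sigma), 0.0)
    return PenaltyContext(sigma, Wpen), Cg_pen


def build_transition_set(
    profile: MutationProfile,
    network: GeneNetwork,
    corr: CorrelationNetwork,
    alpha: float = DEFAULT_ALPHA,
) -> TransitionSet:
    """Assemble all four operators from aligned inputs."""
    if not (profile.universe.genes == network.universe.genes == corr.universe.genes):
        raise ValueError("inputs are not on a shared gene universe; run align first")
    Br, Bc = build_bipartite_stochastics(profile)
    Cr, Cc = apply_teleportation(Br, Bc, alpha)
    return TransitionSet(
        alpha=alpha,
        Cr=Cr,
        Cc=Cc,
        Cg=build_gene_transition(network),
        Ch=build_correlation_transition(corr),
        universe=profile.universe,
        cohort=profile.cohort,
    )
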