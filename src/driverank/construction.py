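"""Ingestion and alignment of the three heterogeneous data sources.

The prioritization framework combines three views of a tumor cohort:

* a weighted, undirected gene--gene interaction network ``W`` (PPI /
  functional interactions),
* a gene co-expression network ``H`` of pairwise Pearson correlations
  computed from an expression matrix, and
* a binary patient x gene somatic-mutation profile ``B``.

All downstream transition operators require a single gene universe shared
by the three sources and strictly positive row/column normalizers, so the
loaders here are followed by :func:`align`, which intersects the gene sets
and prunes to a fixed point where every gene is mutated in at least one
patient and every patient carries at least one mutated gene.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneUniverse",
    "PatientCohort",
    "MutationProfile",
    "ExpressionMatrix",
    "GeneNetwork",
    "CorrelationNetwork",
    "load_ppi",
    "load_expression",
    "load_mutation_profile",
    "load_gene_list",
    "align",
    "compute_correlation_network",
]


@dataclass(frozen=True)
class GeneUniverse:
    """Ordered set of gene symbols defining matrix axes.

    Order is significant: every matrix in the framework is indexed by
    position in this tuple. After :func:`align` the order is lexicographic,
    which makes every downstream matrix and ranking reproducible.
    """

    genes: tuple[str, ...]
    index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene symbols must be unique")
        object.__setattr__(self, "index", {g: i for i, g in enumerate(self.genes)})

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.index


@dataclass(frozen=True)
class PatientCohort:
    """Ordered list of patient identifiers (rows of the mutation profile)."""

    patients: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.patients)) != len(self.patients):
            raise ValueError("patient identifiers must be unique")

    def __len__(self) -> int:
        return len(self.patients)


@dataclass
class MutationProfile:
    """Binary patient x gene matrix B; B[i, j] = 1 iff patient i has gene j mutated."""

    cohort: PatientCohort
    universe: GeneUniverse
    B: np.ndarray

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B)
        m, n = self.B.shape
        if m != len(self.cohort) or n != len(self.universe):
            raise ValueError("mutation matrix shape does not match axes")
        if not np.isin(self.B, (0, 1)).all():
            raise ValueError("mutation matrix entries must be 0 or 1")
        self.B = self.B.astype(np.int8)

    @property
    def n_patients(self) -> int:
        return self.B.shape[0]

    @property
    def n_genes(self) -> int:
        return self.B.shape[1]


@dataclass
class ExpressionMatrix:
    """Real-valued gene x sample expression matrix (arbitrary units)."""

    universe: GeneUniverse
    samples: tuple[str, ...]
    X: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape != (len(self.universe), len(self.samples)):
            raise ValueError("expression matrix shape does not match axes")
        if len(self.samples) < 3:
            raise ValueError("at least 3 expression samples are required")
        if np.isnan(self.X).any():
            raise ValueError("expression matrix contains missing values")


def _check_symmetric_nonneg_diag0(M: np.ndarray, name: str) -> None:
    if M.shape[0] != M.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.array_equal(M, M.T):
        raise ValueError(f"{name} must be symmetric")
    if np.diag(M).any():
        raise ValueError(f"{name} must have a zero diagonal")


@dataclass
class GeneNetwork:
    """Symmetric nonnegative gene--gene interaction weight matrix W, zero diagonal."""

    universe: GeneUniverse
    W: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        _check_symmetric_nonneg_diag0(self.W, "W")
        if (self.W < 0).any():
            raise ValueError("interaction weights must be nonnegative")
        if self.W.shape[0] != len(self.universe):
            raise ValueError("W shape does not match the gene universe")


@dataclass
class CorrelationNetwork:
    """Symmetric matrix H of pairwise Pearson correlations, zero diagonal.

    The diagonal is zeroed so the self-correlation of 1 never dominates the
    row-normalized co-expression walk.
    """

    universe: GeneUniverse
    H: np.ndarray

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype=float)
        _check_symmetric_nonneg_diag0(self.H, "H")
        if (np.abs(self.H) > 1 + 1e-12).any():
            raise ValueError("correlations must lie in [-1, 1]")
        if self.H.shape[0] != len(self.universe):
            raise ValueError("H shape does not match the gene universe")


# ---------------------------------------------------------------------------
# loaders
# ---------------------------------------------------------------------------

def load_ppi(path) -> GeneNetwork:
    """Read a weighted edge-list TSV (gene_a, gene_b[, weight]) into a GeneNetwork.

    A missing third column means weight 1.0.  Duplicate edges are collapsed
    by keeping the maximum weight (deterministic and order-independent);
    self-edges are dropped, but their endpoint still enters the universe.
    """
    edges: dict[tuple[str, str], float] = {}
    genes: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: expected at least 2 columns")
            a, b = parts[0], parts[1]
            if len(parts) >= 3:
                try:
                    w = float(parts[2])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}: line {lineno}: malformed weight {parts[2]!r}"
                    ) from exc
            else:
                w = 1.0
            if w < 0:
                raise ValueError(f"{path}: line {lineno}: negative weight {w}")
            genes.update((a, b))
            if a == b:
                continue
            key = (a, b) if a < b else (b, a)
            edges[key] = max(w, edges.get(key, 0.0))
    universe = GeneUniverse(tuple(sorted(genes)))
    n = len(universe)
    W = np.zeros((n, n))
    for (a, b), w in edges.items():
        i, j = universe.index[a], universe.index[b]
        W[i, j] = W[j, i] = w
    return GeneNetwork(universe, W)


def load_expression(path) -> ExpressionMatrix:
    """Read a genes x samples TSV (header = sample IDs, first column = symbols).

    Rows containing any non-numeric or missing cell are dropped; the count of
    dropped rows is logged.  Duplicate gene symbols are an error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[1] < 3:
        raise ValueError(
            f"{path}: expression requires >= 3 samples, found {df.shape[1]}"
        )
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate gene symbol {dup[0]!r}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    keep = ~numeric.isna().any(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("load_expression: dropped %d rows with missing/non-numeric cells", n_dropped)
    kept = df.loc[keep]
    # parse through Python's float for exact (correctly rounded) round-trips
    X = np.array([[float(x) for x in row] for row in kept.to_numpy(str)])
    universe = GeneUniverse(tuple(str(g) for g in kept.index))
    return ExpressionMatrix(universe, tuple(str(s) for s in df.columns), X)


def load_mutation_profile(path) -> MutationProfile:
    """Read a patients x genes 0/1 TSV (header = gene symbols, first column = patient IDs)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no patients")
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate patient identifier")
    if df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate gene symbol")
    values = df.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() | ~values.isin((0, 1))
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: entry at (patient {df.index[i]!r}, gene {df.columns[j]!r}) "
            f"is {df.iat[i, j]!r}, expected 0 or 1"
        )
    universe = GeneUniverse(tuple(str(g) for g in df.columns))
    cohort = PatientCohort(tuple(str(p) for p in df.index))
    return MutationProfile(cohort, universe, values.to_numpy(int))


def load_gene_list(path) -> tuple[str, ...]:
    """Read a plain-text gene list, one symbol per line; '#' starts a comment."""
    out: list[str] = []
    seen: set[str] = set()
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if line and line not in seen:
                seen.add(line)
                out.append(line)
    return tuple(out)


# ---------------------------------------------------------------------------
# alignment and correlation
# ---------------------------------------------------------------------------

def align(
    profile: MutationProfile,
    ppi: GeneNetwork,
    expr: ExpressionMatrix,
) -> tuple[MutationProfile, GeneNetwork, ExpressionMatrix]:
    """Reconcile the three sources onto one gene universe and patient cohort.

    The shared universe is the intersection of the three gene sets, then
    iteratively pruned to a fixed point so that every surviving gene is
    mutated in >= 1 surviving patient and every surviving patient carries
    >= 1 mutation within the universe.  All structures are re-indexed onto
    the lexicographically sorted universe.  Idempotent on aligned inputs.
    """
    shared = sorted(
        set(profile.universe.genes)
        & set(ppi.universe.genes)
        & set(expr.universe.genes)
    )
    if not shared:
        raise ValueError("alignment failed: the three sources share no genes")

    gcols = np.array([profile.universe.index[g] for g in shared])
    B = profile.B[:, gcols]
    genes = np.array(shared)
    patients = np.array(profile.cohort.patients)

    while True:
        gene_keep = B.sum(axis=0) > 0
        B = B[:, gene_keep]
        genes = genes[gene_keep]
        patient_keep = B.sum(axis=1) > 0
        B = B[patient_keep]
        patients = patients[patient_keep]
        if gene_keep.all() and patient_keep.all():
            break
    if genes.size == 0 or patients.size == 0:
        raise ValueError("alignment failed: pruning removed every gene or patient")

    n_gene_drop = len(set(profile.universe.genes) | set(ppi.universe.genes) | set(expr.universe.genes)) - genes.size
    n_pat_drop = len(profile.cohort) - patients.size
    if n_gene_drop or n_pat_drop:
        logger.info("align: universe has %d genes (%d dropped), %d patients (%d dropped)",
                    genes.size, n_gene_drop, patients.size, n_pat_drop)

    universe = GeneUniverse(tuple(genes))
    cohort = PatientCohort(tuple(patients))

    widx = np.array([ppi.universe.index[g] for g in universe.genes])
    W = ppi.W[np.ix_(widx, widx)]
    eidx = np.array([expr.universe.index[g] for g in universe.genes])
    X = expr.X[eidx]

    return (
        MutationProfile(cohort, universe, B),
        GeneNetwork(universe, W),
        ExpressionMatrix(universe, expr.samples, X),
    )


def compute_correlation_network(expr: ExpressionMatrix) -> CorrelationNetwork:
    """Pairwise Pearson correlation of gene expression rows across samples.

    The diagonal is zeroed, and genes whose expression has zero variance get
    an all-zero correlation row/column instead of NaN; such genes fall back
    to the dangling-row rule when the walk operator is built.
    """
    X = expr.X
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt((Xc**2).sum(axis=1))
    ok = norms > 0
    n = X.shape[0]
    H = np.zeros((n, n))
    if ok.any():
        Y = Xc[ok] / norms[ok, None]
        H[np.ix_(ok, ok)] = np.clip(Y @ Y.T, -1.0, 1.0)
    # exact symmetry: keep the upper triangle, mirror it, drop the diagonal
    H = np.triu(H, 1)
    H = H + H.T
    return CorrelationNetwork(expr.universe, H)
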