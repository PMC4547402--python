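"""Synthetic tumor cohorts with planted driver genes.

Generates the three inputs the framework consumes — mutation profile, PPI
edge list, expression matrix — with exactly the statistical structure the
models assume:

* genes fall into functional modules; the PPI network is a planted
  partition (dense within modules, sparse between);
* expression is driven by one latent factor per module, so genes in a
  module are co-expressed at a target correlation ``rho_within``;
* a small set of planted driver genes mutates at an elevated per-patient
  probability ``p_driver_mut`` over the passenger background
  ``p_passenger_mut``.

Drivers are spread round-robin across modules, so driver signal enters
only through mutation frequency plus ordinary module membership — the
minimal generative premise under which network integration can help.

Defaults are the package's reference study conditions: 500 genes in 10
modules, 25 drivers, 100 patients, 60 expression samples,
p_driver_mut = 0.15 vs p_passenger_mut = 0.02, within-module expression
correlation 0.6, PPI edge probabilities 0.1 within / 0.005 between.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np

from .construction import (
    ExpressionMatrix,
    GeneNetwork,
    GeneUniverse,
    MutationProfile,
    PatientCohort,
    align,
)
from .evaluation import GroundTruthSet

__all__ = ["SyntheticParams", "SyntheticDataset", "generate", "write_dataset"]

MAX_RETRIES = 10


@dataclass(frozen=True)
class SyntheticParams:
    """Generator knobs; defaults are the reference cohort conditions."""

    n_genes: int = 500
    n_patients: int = 100
    n_samples: int = 60
    n_modules: int = 10
    n_drivers: int = 25
    p_driver_mut: float = 0.15
    p_passenger_mut: float = 0.02
    p_within: float = 0.1
    p_between: float = 0.005
    rho_within: float = 0.6
    noise_sd: float = 0.1
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("p_driver_mut", "p_passenger_mut", "p_within", "p_between", "rho_within"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.p_driver_mut < self.p_passenger_mut:
            raise ValueError("p_driver_mut must be >= p_passenger_mut")
        if not 0 < self.n_drivers <= self.n_genes:
            raise ValueError("n_drivers must lie in (0, n_genes]")
        if self.n_modules < 1:
            raise ValueError("n_modules must be >= 1")
        if self.n_samples < 3:
            raise ValueError("n_samples must be >= 3")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass(frozen=True)
class SyntheticDataset:
    """Generated cohort plus the planted driver set and the parameters used."""

    profile: MutationProfile
    expression: ExpressionMatrix
    network: GeneNetwork
    truth: GroundTruthSet
    params: SyntheticParams

    @property
    def drivers(self) -> frozenset[str]:
        return self.truth.genes


def _gene_names(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"G{i:0{width}d}" for i in range(n)]


def _generate_once(params: SyntheticParams, seed: int) -> SyntheticDataset:
    rng = np.random.default_rng(seed)
    n, m, s = params.n_genes, params.n_patients, params.n_samples

    genes = _gene_names(n)
    universe = GeneUniverse(tuple(genes))
    patients = PatientCohort(tuple(f"P{i:03d}" for i in range(m)))

    # module assignment round-robin; drivers are spread round-robin across
    # modules but placed at random positions within each module, so driver
    # status is independent of the lexicographic gene order that breaks
    # score ties downstream
    modules = np.arange(n) % params.n_modules
    members = [rng.permutation(np.flatnonzero(modules == k)) for k in range(params.n_modules)]
    drivers = np.zeros(n, dtype=bool)
    for d in range(params.n_drivers):
        k = d % params.n_modules
        drivers[members[k][d // params.n_modules]] = True

    # planted-partition PPI, weight 1 per edge
    same = modules[:, None] == modules[None, :]
    probs = np.where(same, params.p_within, params.p_between)
    upper = np.triu(rng.random((n, n)) < probs, k=1)
    W = (upper | upper.T).astype(float)
    network = GeneNetwork(universe, W)

    # module-factor expression: X_g = sqrt(rho)*factor_module(g) + sqrt(1-rho)*eps + noise
    factors = rng.standard_normal((params.n_modules, s))
    eps = rng.standard_normal((n, s))
    X = (
        np.sqrt(params.rho_within) * factors[modules]
        + np.sqrt(1.0 - params.rho_within) * eps
        + params.noise_sd * rng.standard_normal((n, s))
    )
    expression = ExpressionMatrix(universe, tuple(f"S{i:02d}" for i in range(s)), X)

    # independent per-(patient, gene) mutation coin flips
    p_gene = np.where(drivers, params.p_driver_mut, params.p_passenger_mut)
    B = (rng.random((m, n)) < p_gene[None, :]).astype(int)
    profile = MutationProfile(patients, universe, B)

    truth = GroundTruthSet(frozenset(np.array(genes)[drivers]))
    return SyntheticDataset(profile, expression, network, truth, params)


def generate(params: SyntheticParams | None = None, **overrides) -> SyntheticDataset:
    """Generate a cohort that survives alignment with all drivers intact.

    All randomness comes from ``params.seed``.  If alignment would drop a
    planted driver (possible when a driver happens to mutate in no
    patient), the whole dataset is regenerated with the seed incremented,
    up to 10 retries.
    """
    if params is None:
        params = SyntheticParams(**overrides)
    elif overrides:
        params = replace(params, **overrides)
    for attempt in range(MAX_RETRIES):
        ds = _generate_once(params, params.seed + attempt)
        aligned_profile, _, _ = align(ds.profile, ds.network, ds.expression)
        if ds.truth.genes <= set(aligned_profile.universe.genes):
            return ds
    raise RuntimeError(
        f"could not generate a cohort keeping all {params.n_drivers} drivers "
        f"after {MAX_RETRIES} attempts (seeds {params.seed}..{params.seed + MAX_RETRIES - 1})"
    )


def write_dataset(ds: SyntheticDataset, outdir) -> dict[str, str]:
    """Write the cohort in the package's ingestion formats.

    Emits ppi.tsv (edge list), expression.tsv (genes x samples),
    mutations.tsv (patients x genes, 0/1) and truth_genes.txt; the files
    round-trip losslessly through the loaders.  Deterministic byte-for-byte.
    """
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "ppi": os.path.join(outdir, "ppi.tsv"),
        "expression": os.path.join(outdir, "expression.tsv"),
        "mutations": os.path.join(outdir, "mutations.tsv"),
        "truth": os.path.join(outdir, "truth_genes.txt"),
    }
    genes = ds.network.universe.genes
    with open(paths["ppi"], "w") as fh:
        fh.write("#gene_a\tgene_b\tweight\n")
        rows, cols = np.nonzero(np.triu(ds.network.W, k=1))
        for i, j in zip(rows, cols):
            fh.write(f"{genes[i]}\t{genes[j]}\t{ds.network.W[i, j]:.17g}\n")
        # a self-edge records an isolated gene's membership in the universe;
        # the loader drops the edge but keeps the endpoint
        for i in np.flatnonzero(ds.network.W.sum(axis=1) == 0):
            fh.write(f"{genes[i]}\t{genes[i]}\t0\n")
    with open(paths["expression"], "w") as fh:
        fh.write("gene\t" + "\t".join(ds.expression.samples) + "\n")
        for g, row in zip(genes, ds.expression.X):
            fh.write(g + "\t" + "\t".join(repr(float(x)) for x in row) + "\n")
    with open(paths["mutations"], "w") as fh:
        fh.write("patient\t" + "\t".join(genes) + "\n")
        for p, row in zip(ds.profile.cohort.patients, ds.profile.B):
            fh.write(p + "\t" + "\t".join(str(int(x)) for x in row) + "\n")
    with open(paths["truth"], "w") as fh:
        fh.write("# planted driver genes\n")
        for g in sorted(ds.truth.genes):
            fh.write(g + "\n")
    return paths
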