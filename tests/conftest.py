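"""Shared fixtures and independent oracles for the test suite."""

from pathlib import Path

import numpy as np
import pytest

from driverank.construction import (
    CorrelationNetwork,
    GeneNetwork,
    GeneUniverse,
    MutationProfile,
    PatientCohort,
)
from driverank.pipeline import load_cohort, prepare
from driverank.synthetic import SyntheticParams, generate
from driverank.transitions import build_transition_set

DATA = Path(__file__).parent / "data"


# ---------------------------------------------------------------------------
# matrix-level builders (bypass file IO and alignment)
# ---------------------------------------------------------------------------

def make_domain(B, W, H):
    """Wrap raw matrices in domain objects over generic gene/patient names.

    Names are assigned in index order, so matrix order is preserved exactly
    as given (no lexicographic resorting happens outside align()).
    """
    m, n = np.asarray(B).shape
    uni = GeneUniverse(tuple(f"g{i:03d}" for i in range(n)))
    coh = PatientCohort(tuple(f"p{i:03d}" for i in range(m)))
    return (
        MutationProfile(coh, uni, B),
        GeneNetwork(uni, np.asarray(W, float)),
        CorrelationNetwork(uni, np.asarray(H, float)),
    )


def make_ts(B, W, H, alpha=0.75):
    profile, net, corr = make_domain(B, W, H)
    return build_transition_set(profile, net, corr, alpha=alpha)


def random_instance(rng, m, n, p_extra=0.3):
    """Random aligned (B, W, H): every B row/column nonzero, W/H symmetric."""
    B = np.zeros((m, n), dtype=int)
    for i in range(m):
        B[i, rng.integers(n)] = 1
    for j in range(n):
        B[rng.integers(m), j] = 1
    B |= (rng.random((m, n)) < p_extra).astype(int)
    W = np.triu(rng.random((n, n)) * (rng.random((n, n)) < 0.5), 1)
    W = W + W.T
    H = np.triu(rng.uniform(-1, 1, (n, n)) * (rng.random((n, n)) < 0.7), 1)
    H = H + H.T
    return B, W, H


def principal_eigvec(M):
    """Independent oracle: unit-eigenvalue eigenvector of a positive stochastic
    matrix via dense eigendecomposition, made positive and L1-normalized."""
    w, V = np.linalg.eig(M)
    v = np.real(V[:, np.argmin(np.abs(w - 1.0))])
    v = np.abs(v)
    return v / v.sum()


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def tiny_paths():
    return {
        "ppi": DATA / "tiny_ppi.tsv",
        "expression": DATA / "tiny_expression.tsv",
        "mutations": DATA / "tiny_mutations.tsv",
        "truth": DATA / "tiny_truth.txt",
    }


@pytest.fixture(scope="session")
def tiny_cohort(tiny_paths):
    return load_cohort(tiny_paths["ppi"], tiny_paths["expression"], tiny_paths["mutations"])


@pytest.fixture(scope="session")
def small_dataset():
    """A quick synthetic cohort with planted signal for evaluation tests."""
    return generate(SyntheticParams(
        n_genes=60, n_patients=40, n_samples=20, n_modules=4, n_drivers=8,
        p_driver_mut=0.3, p_passenger_mut=0.05,
        p_within=0.3, p_between=0.05,  # connected, triangle-rich PPI graph
        seed=7,
    ))


@pytest.fixture(scope="session")
def small_cohort(small_dataset):
    return prepare(small_dataset.profile, small_dataset.network, small_dataset.expression)
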