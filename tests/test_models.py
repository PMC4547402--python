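"""Stationary solver and the nine ranking models."""

import numpy as np
import pytest

from driverank.construction import GeneUniverse
from driverank.models import (
    AdditiveWeights,
    ConvergenceError,
    MMASchedule,
    benchmark_frequency,
    benchmark_rw_gc,
    benchmark_rw_pm,
    rank_rw_am,
    rank_rw_mma,
    rank_rw_mmgcs,
    rank_rw_mmgis,
    rank_rw_mmp,
    rank_rw_mmpfs,
    scores_to_ranks,
    stationary,
)
from driverank.transitions import build_penalized_transition

from conftest import make_domain, make_ts, principal_eigvec, random_instance


def _toy_ts(alpha=0.75):
    """Fixed 3-gene x 2-patient toy used by the dense-oracle checks."""
    B = np.array([[1, 1, 0], [0, 1, 1]])
    W = np.array([[0, 2, 1], [2, 0, 0], [1, 0, 0.0]])
    H = np.array([[0, 0.5, -0.4], [0.5, 0, 0.1], [-0.4, 0.1, 0.0]])
    return make_ts(B, W, H, alpha=alpha)


class TestStationary:
    def test_identity_chain_converges_immediately(self):
        v, it, res = stationary(lambda x: x, 5)
        assert np.allclose(v, 0.2) and it == 1 and res == 0.0

    def test_periodic_chain_fails_from_asymmetric_start(self):
        M = np.array([[0, 1], [1, 0.0]])
        with pytest.raises(ConvergenceError) as err:
            stationary(lambda v: M @ v, 2, max_iter=200, start=np.array([1.0, 0.0]))
        assert err.value.residual > 1  # still oscillating at full amplitude

    def test_periodic_chain_uniform_start_is_fixed_point(self):
        # uniform is stationary for the swap chain, so the default start converges
        M = np.array([[0, 1], [1, 0.0]])
        v, it, _ = stationary(lambda v: M @ v, 2)
        assert np.allclose(v, 0.5) and it == 1

    def test_matches_eigendecomposition_on_random_chain(self):
        rng = np.random.default_rng(0)
        M = rng.random((6, 6)) + 0.05
        M /= M.sum(axis=0, keepdims=True)  # positive column-stochastic
        v, _, _ = stationary(lambda x: M @ x, 6)
        assert np.abs(v - principal_eigvec(M)).sum() < 1e-8


MULTIPLICATIVE = {
    "RW-MMGCS": (rank_rw_mmgcs, lambda ts, P: ts.Cr.T @ ts.Cc @ ts.Cg.T @ ts.Ch.T),
    "RW-MMGIS": (rank_rw_mmgis, lambda ts, P: ts.Cr.T @ ts.Cc @ ts.Ch.T @ ts.Cg.T),
    "RW-MMPFS": (rank_rw_mmpfs, lambda ts, P: ts.Ch.T @ ts.Cg.T @ ts.Cr.T @ ts.Cc),
    "RW-PM": (benchmark_rw_pm, lambda ts, P: ts.Cr.T @ ts.Cc),
}


class TestModelOracles:
    @pytest.mark.parametrize("model_id", sorted(MULTIPLICATIVE))
    def test_toy_matches_dense_eigenvector(self, model_id):
        ts = _toy_ts()
        run, chain = MULTIPLICATIVE[model_id]
        res = run(ts)
        assert np.abs(res.mu - principal_eigvec(chain(ts, None))).sum() < 1e-8

    def test_rw_am_toy_matches_dense_eigenvector(self):
        ts = _toy_ts()
        res = rank_rw_am(ts, AdditiveWeights(0.3, 0.3, 0.4))
        M = 0.3 * ts.Cr.T @ ts.Cc + 0.3 * ts.Cg.T + 0.4 * ts.Ch.T
        assert np.abs(res.mu - principal_eigvec(M)).sum() < 1e-8

    def test_rw_mmp_toy_matches_dense_eigenvector(self):
        ts = _toy_ts()
        _, net, corr = make_domain(
            [[1, 1, 0], [0, 1, 1]],
            [[0, 2, 1], [2, 0, 0], [1, 0, 0.0]],
            [[0, 0.5, -0.4], [0.5, 0, 0.1], [-0.4, 0.1, 0.0]],
        )
        _, Cg_pen = build_penalized_transition(net, corr)
        res = rank_rw_mmp(ts, Cg_pen)
        assert np.abs(res.mu - principal_eigvec(ts.Cr.T @ ts.Cc @ Cg_pen.T)).sum() < 1e-8

    def test_rw_gc_toy_matches_dense_eigenvector(self):
        ts = _toy_ts()
        n = ts.n_genes
        M = ts.alpha * ts.Ch.T + (1 - ts.alpha) / n * np.ones((n, n))
        res = benchmark_rw_gc(ts)
        assert np.abs(res.mu - principal_eigvec(M)).sum() < 1e-8

    def test_single_gene_single_patient(self):
        ts = make_ts([[1]], [[0.0]], [[0.0]])
        res = rank_rw_mmgcs(ts)
        assert res.mu.tolist() == [1.0] and res.pi.tolist() == [1.0]


class TestClosedFormLimits:
    @pytest.mark.parametrize(
        "run",
        [rank_rw_mmgcs, rank_rw_mmgis, benchmark_rw_pm],
        ids=["rw-mmgcs", "rw-mmgis", "rw-pm"],
    )
    def test_alpha_zero_gives_uniform_mu(self, run):
        ts = _toy_ts(alpha=0.0)
        assert run(ts).mu == pytest.approx([1 / 3] * 3, abs=1e-12)

    def test_alpha_zero_rw_mmp_uniform(self):
        ts = _toy_ts(alpha=0.0)
        _, net, corr = make_domain(
            [[1, 1, 0], [0, 1, 1]],
            [[0, 2, 1], [2, 0, 0], [1, 0, 0.0]],
            [[0, 0.5, -0.4], [0.5, 0, 0.1], [-0.4, 0.1, 0.0]],
        )
        _, Cg_pen = build_penalized_transition(net, corr)
        assert rank_rw_mmp(ts, Cg_pen).mu == pytest.approx([1 / 3] * 3, abs=1e-12)

    def test_alpha_zero_rw_mmpfs_is_smoothed_uniform(self):
        ts = _toy_ts(alpha=0.0)
        u = np.full(3, 1 / 3)
        expected = ts.Ch.T @ (ts.Cg.T @ u)
        assert rank_rw_mmpfs(ts).mu == pytest.approx(expected, abs=1e-10)

    def test_identical_networks_make_gcs_equal_gis(self):
        B = np.array([[1, 1, 0], [0, 1, 1]])
        W = np.array([[0, 2, 1], [2, 0, 0], [1, 0, 0.0]])
        H = W / 2  # same topology and relative weights => Cg == Ch
        ts = make_ts(B, W, H)
        assert np.allclose(ts.Cg, ts.Ch, atol=1e-15)
        assert rank_rw_mmgcs(ts).mu == pytest.approx(rank_rw_mmgis(ts).mu, abs=1e-9)

    def test_constant_correlation_mmp_equals_unpenalized_chain(self):
        B = np.array([[1, 1, 0], [0, 1, 1]])
        W = np.array([[0, 2, 1], [2, 0, 1], [1, 1, 0.0]])
        H = np.where(W > 0, 0.3, 0.0)
        ts = make_ts(B, W, H)
        _, net, corr = make_domain(B, W, H)
        _, Cg_pen = build_penalized_transition(net, corr)
        penalized = rank_rw_mmp(ts, Cg_pen).mu
        unpenalized = principal_eigvec(ts.Cr.T @ ts.Cc @ ts.Cg.T)
        assert np.abs(penalized - unpenalized).sum() < 1e-8


class TestAdditiveModel:
    def test_degenerate_bipartite_weights_alpha_zero_uniform(self):
        ts = _toy_ts(alpha=0.0)
        res = rank_rw_am(ts, AdditiveWeights(1.0, 0.0, 0.0))
        assert res.mu == pytest.approx([1 / 3] * 3, abs=1e-12)

    def test_pure_ppi_weights_recover_cg_walk(self):
        # triangle network: the bare PPI walk is aperiodic, so the mixture
        # degenerates cleanly to the stationary vector of Cg^T alone
        B = np.array([[1, 1, 0], [0, 1, 1]])
        W = np.array([[0, 2, 1], [2, 0, 1], [1, 1, 0.0]])
        H = np.array([[0, 0.5, -0.4], [0.5, 0, 0.1], [-0.4, 0.1, 0.0]])
        ts = make_ts(B, W, H)
        res = rank_rw_am(ts, AdditiveWeights(0.0, 1.0, 0.0))
        expected, _, _ = stationary(lambda v: ts.Cg.T @ v, 3)
        assert res.mu == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("bad", [(0.5, 0.5, 0.5), (0.2, 0.2, 0.2)])
    def test_weight_sum_violation_rejected(self, bad):
        with pytest.raises(ValueError, match="sum to 1"):
            AdditiveWeights(*bad)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            AdditiveWeights(-0.1, 0.6, 0.5)


class TestMultiplicativeAverage:
    def test_single_step_hand_oracle(self):
        ts = _toy_ts()
        res = rank_rw_mma(ts, schedule=MMASchedule(1, 1, 1))
        u = np.full(3, 1 / 3)
        expected = (ts.Cr.T @ (ts.Cc @ u) + ts.Cg.T @ u + ts.Ch.T @ u) / 3
        assert res.mu == pytest.approx(expected, abs=1e-12)
        assert res.iterations == 1

    def test_indicator_logic_second_step_bipartite_only(self):
        ts = _toy_ts()
        r1 = rank_rw_mma(ts, schedule=MMASchedule(1, 1, 1)).mu
        r2 = rank_rw_mma(ts, schedule=MMASchedule(2, 1, 1)).mu
        assert r2 == pytest.approx(ts.Cr.T @ (ts.Cc @ r1), abs=1e-12)

    def test_trivial_size_one(self):
        ts = make_ts([[1]], [[0.0]], [[0.0]])
        assert rank_rw_mma(ts, schedule=MMASchedule(1, 1, 1)).mu.tolist() == [1.0]

    def test_convergence_mode_matches_mixture_eigenvector(self):
        ts = _toy_ts()
        M = (ts.Cr.T @ ts.Cc + ts.Cg.T + ts.Ch.T) / 3
        assert np.abs(rank_rw_mma(ts).mu - principal_eigvec(M)).sum() < 1e-8

    @pytest.mark.parametrize("caps", [(0, 1, 1), (1, -2, 1)])
    def test_invalid_schedule_rejected(self, caps):
        with pytest.raises(ValueError, match=">= 1"):
            MMASchedule(*caps)


class TestBenchmarks:
    def test_frequency_column_sums(self):
        prof, _, _ = make_domain([[1, 1], [0, 1]], np.zeros((2, 2)), np.zeros((2, 2)))
        assert benchmark_frequency(prof).mu == pytest.approx([1 / 3, 2 / 3])

    def test_frequency_uniform_when_equal(self):
        prof, _, _ = make_domain(np.ones((3, 4), int), np.zeros((4, 4)), np.zeros((4, 4)))
        assert benchmark_frequency(prof).mu == pytest.approx([0.25] * 4)

    def test_frequency_rejects_unaligned_profile(self):
        prof, _, _ = make_domain([[1, 1], [0, 1]], np.zeros((2, 2)), np.zeros((2, 2)))
        prof.B = np.array([[1, 0], [1, 0]], dtype=np.int8)
        with pytest.raises(ValueError, match="never-mutated"):
            benchmark_frequency(prof)

    def test_rw_gc_alpha_zero_uniform(self):
        assert benchmark_rw_gc(_toy_ts(alpha=0.0)).mu == pytest.approx([1 / 3] * 3)

    def test_rw_gc_doubly_stochastic_ch_uniform(self):
        # symmetric two-cycle: Ch doubly stochastic => uniform fixed point
        B = np.array([[1, 0], [0, 1]])
        H = np.array([[0, 0.8], [0.8, 0.0]])
        ts = make_ts(B, np.zeros((2, 2)), H, alpha=0.6)
        assert benchmark_rw_gc(ts).mu == pytest.approx([0.5, 0.5], abs=1e-10)

    def test_rw_pm_identity_profile_symmetric(self):
        ts = make_ts(np.eye(3, dtype=int), np.zeros((3, 3)), np.zeros((3, 3)), alpha=0.75)
        assert benchmark_rw_pm(ts).mu == pytest.approx([1 / 3] * 3, abs=1e-10)

    def test_rw_pm_invariant_under_cohort_replication(self):
        # vote interpretation: doubling every patient's vote changes nothing
        B = np.array([[1, 1, 0], [0, 1, 1]])
        W = np.zeros((3, 3))
        H = np.zeros((3, 3))
        mu1 = benchmark_rw_pm(make_ts(B, W, H)).mu
        mu2 = benchmark_rw_pm(make_ts(np.vstack([B, B]), W, H)).mu
        assert np.abs(mu1 - mu2).sum() < 1e-12


class TestStationaryInvariants:
    @pytest.mark.parametrize("seed", range(5))
    def test_positive_normalized_and_start_independent(self, seed):
        rng = np.random.default_rng(seed)
        B, W, H = random_instance(rng, 5, 8)
        ts = make_ts(B, W, H)
        base = rank_rw_mmgcs(ts)
        assert (base.mu > 0).all()
        assert base.mu.sum() == pytest.approx(1.0, abs=1e-9)
        assert base.residual < 1e-10
        for _ in range(3):
            start = rng.dirichlet(np.ones(8))
            again = rank_rw_mmgcs(ts, start=start)
            assert np.abs(again.mu - base.mu).sum() < 1e-8

    @pytest.mark.parametrize("seed", range(3))
    def test_permutation_equivariance(self, seed):
        rng = np.random.default_rng(100 + seed)
        B, W, H = random_instance(rng, 5, 7)
        perm = rng.permutation(7)
        ts = make_ts(B, W, H)
        tsp = make_ts(B[:, perm], W[np.ix_(perm, perm)], H[np.ix_(perm, perm)])
        for run in (rank_rw_mmgcs, rank_rw_mmgis, rank_rw_mmpfs, benchmark_rw_pm):
            mu = run(ts).mu
            mup = run(tsp).mu
            assert np.abs(mup - mu[perm]).sum() < 1e-8


class TestScoresToRanks:
    def test_descending_order(self):
        uni = GeneUniverse(("A", "B", "C"))
        out = scores_to_ranks(np.array([0.2, 0.5, 0.3]), uni)
        assert [(g, r) for g, _, r in out] == [("B", 1), ("C", 2), ("A", 3)]

    def test_lexicographic_tie_break(self):
        uni = GeneUniverse(("B", "A"))
        out = scores_to_ranks(np.array([0.5, 0.5]), uni)
        assert [(g, r) for g, _, r in out] == [("A", 1), ("B", 2)]

    def test_single_gene(self):
        assert scores_to_ranks(np.array([1.0]), GeneUniverse(("X",))) == [("X", 1.0, 1)]
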