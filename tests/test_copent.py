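"""Copula-entropy estimation: folds, pseudo-observations, KDE, bandwidth."""

import numpy as np
import pytest
from scipy.special import ndtri

from copulagm.copent import (
    CopulaEntropyEstimator,
    EstimatorConfig,
    PseudoObsFolds,
    RawKDEEstimator,
    kde_log_copula_density,
    make_folds,
    pseudo_obs,
    select_bandwidth,
)


class TestMakeFolds:
    def test_equal_division(self):
        folds = make_folds(10, 5, seed=0)
        assert [len(f) for f in folds] == [2] * 5

    def test_remainder_spread(self):
        folds = make_folds(7, 3, seed=1)
        assert sorted(len(f) for f in folds) == [2, 2, 3]

    def test_partition_and_determinism(self):
        a = make_folds(23, 4, seed=7)
        b = make_folds(23, 4, seed=7)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))
        assert sorted(np.concatenate(a)) == list(range(23))
        c = make_folds(23, 4, seed=8)
        assert not all(np.array_equal(x, y) for x, y in zip(a, c))

    def test_out_of_range_k(self):
        with pytest.raises(ValueError):
            make_folds(5, 6, seed=0)
        with pytest.raises(ValueError):
            make_folds(5, 1, seed=0)


class TestPseudoObs:
    train = np.array([[1.0], [2.0], [3.0], [4.0]])

    def test_rank_count_at_maximum(self):
        u = pseudo_obs(self.train, np.array([[4.0]]), epsilon=1e-5)
        assert u[0, 0] == pytest.approx(0.8)  # (4/5) * F=1

    def test_below_all_clamped_to_epsilon(self):
        u = pseudo_obs(self.train, np.array([[0.5]]), epsilon=1e-5)
        assert u[0, 0] == 1e-5

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 3))
        u1 = pseudo_obs(X, X, epsilon=1e-5)
        Y = np.exp(X)
        u2 = pseudo_obs(Y, Y, epsilon=1e-5)
        np.testing.assert_array_equal(u1, u2)

    def test_rejects_non_finite(self):
        X = np.array([[1.0], [np.nan]])
        with pytest.raises(ValueError):
            pseudo_obs(X, X, epsilon=1e-5)

    def test_ties_share_value(self):
        train = np.array([[1.0], [2.0], [2.0], [3.0]])
        u = pseudo_obs(train, np.array([[2.0], [2.0]]), epsilon=1e-5)
        assert u[0, 0] == u[1, 0] == pytest.approx(0.75 * 0.8)


class TestKdeLogCopulaDensity:
    def test_kernel_equals_jacobian_at_center(self):
        # one center at z=0, query u=0.5 (z=0), theta=1: c-hat = 1 exactly
        val = kde_log_copula_density(
            np.array([[0.5]]), np.zeros((1, 1)), np.array([1.0]))
        assert val[0] == pytest.approx(0.0, abs=1e-12)

    def test_density_floor_clamp(self):
        # query far in the tail of a tight kernel: floored
        val = kde_log_copula_density(
            np.array([[0.999]]), np.zeros((1, 1)), np.array([1e-6]),
            density_floor=1e-10)
        assert val[0] == pytest.approx(np.log(1e-10))

    def test_uniform_copula_density_is_one(self):
        # large standard-uniform sample: log c -> 0 at interior points
        rng = np.random.default_rng(0)
        u = rng.uniform(size=(5000, 1))
        z = ndtri(np.clip(u, 1e-5, 1 - 1e-5))
        bw = select_bandwidth(z, EstimatorConfig())
        queries = np.linspace(0.2, 0.8, 7)[:, None]
        vals = kde_log_copula_density(queries, z, bw.theta)
        assert np.all(np.abs(vals) < 0.05)


class TestSelectBandwidth:
    def test_two_point_closed_form_hits_upper_bound(self):
        # LOO objective is log g(2a | theta), increasing in theta up to
        # 4a^2; the box top is Var/beta_min = 2a^2, so the optimum is there
        a = 1.5
        Z = np.array([[-a], [a]])
        bw = select_bandwidth(Z, EstimatorConfig(beta_min=1.0, beta_max=4.0))
        assert bw.theta[0] == pytest.approx(2 * a * a, rel=1e-6)

    def test_agrees_with_grid_search_oracle(self):
        rng = np.random.default_rng(5)
        Z = rng.normal(size=(500, 1))
        cfg = EstimatorConfig()
        bw = select_bandwidth(Z, cfg)
        # oracle: 50 log-spaced candidates across the same box
        grid = np.exp(np.linspace(bw.lower[0], bw.upper[0], 50))
        from copulagm.copent import _loo_objective_and_grad
        sqd = (Z[:, 0][:, None] - Z[:, 0][None, :]) ** 2
        objs = [-_loo_objective_and_grad(np.log([t]), sqd[None])[0]
                for t in grid]
        best = grid[int(np.argmax(objs))]
        step = grid[1] / grid[0]
        assert best / step <= bw.theta[0] <= best * step
        # and within a factor 3 of the Silverman-scale variance
        silverman = (1.06 * 500 ** -0.2) ** 2 * Z.var(ddof=1)
        assert silverman / 3 <= bw.theta[0] <= silverman * 3

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        Z = rng.normal(size=(100, 3))
        t1 = select_bandwidth(Z, EstimatorConfig()).theta
        t2 = select_bandwidth(Z, EstimatorConfig()).theta
        np.testing.assert_array_equal(t1, t2)


class TestPsiHat:
    def test_empty_set_is_zero(self, gaussian_copula_pair):
        est = CopulaEntropyEstimator(gaussian_copula_pair(0.5, 80))
        assert est.psi([]) == 0.0

    def test_singleton_near_zero(self, gaussian_copula_pair):
        # the copula of one variable is uniform: entropy 0
        est = CopulaEntropyEstimator(gaussian_copula_pair(0.3, 1400))
        assert abs(est.psi([0])) < 0.05
        assert abs(est.psi([1])) < 0.05

    @pytest.mark.parametrize("r,tol", [(0.0, 0.05), (0.5, 0.1), (0.9, 0.1)])
    def test_gaussian_copula_mutual_information(self, gaussian_copula_pair,
                                                r, tol):
        X = gaussian_copula_pair(r, 1400, seed=11)
        est = CopulaEntropyEstimator(X)
        target = -0.5 * np.log(1 - r ** 2)
        assert est.psi([0, 1]) == pytest.approx(target, abs=tol)

    def test_marginal_invariance_bit_for_bit(self, gaussian_copula_pair):
        X = gaussian_copula_pair(0.6, 250, seed=4)
        est1 = CopulaEntropyEstimator(X)
        # strictly increasing per-column transforms
        Y = np.column_stack([np.exp(X[:, 0]), X[:, 1] ** 3])
        est2 = CopulaEntropyEstimator(Y)
        for A in ([0], [1], [0, 1]):
            assert est1.psi(A) == est2.psi(A)

    def test_no_leakage_across_folds(self, gaussian_copula_pair):
        # perturbing a held-out row of fold r must not change fold r's
        # fitted marginals, hence other rows' fold-r pseudo-observations
        X = gaussian_copula_pair(0.4, 60, seed=9)
        folds = make_folds(60, 4, seed=0)
        p1 = PseudoObsFolds(X, folds, epsilon=1e-5)
        t = folds[2][0]
        X2 = X.copy()
        X2[t] = X2[t] + 0.01  # stays a fold-2 test row
        p2 = PseudoObsFolds(X2, folds, epsilon=1e-5)
        keep = np.setdiff1d(np.arange(60), [t])
        np.testing.assert_array_equal(p1.U[2][keep], p2.U[2][keep])

    def test_finite_under_truncation_and_floor(self):
        rng = np.random.default_rng(1)
        X = np.repeat(rng.normal(size=(10, 2)), 3, axis=0)  # heavy ties
        est = CopulaEntropyEstimator(X, EstimatorConfig(k_folds=3))
        assert np.isfinite(est.psi([0, 1]))


class TestRawKDEEstimator:
    def test_standard_normal_entropy(self):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(4000, 2))
        est = RawKDEEstimator(X)
        # E[log phi(X)] = -(1/2) log(2 pi e) = -1.4189
        assert est.psi([0]) == pytest.approx(-1.4189, abs=0.05)

    def test_not_rank_invariant(self):
        rng = np.random.default_rng(22)
        X = rng.normal(size=(200, 2))
        est1 = RawKDEEstimator(X)
        Y = X.copy()
        Y[:, 0] = np.exp(Y[:, 0])
        est2 = RawKDEEstimator(Y)
        assert est1.psi([0]) != est2.psi([0])
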