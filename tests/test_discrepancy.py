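import math

import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

from dmdtraj.discrepancy import (
    GPHyperparams,
    RWParams,
    gp_condition,
    gp_loglik,
    rw_cov,
    rw_loglik,
    rw_simulate,
    sqexp_kernel,
)


def dense_gp_posterior(mean_T, mean_X, X, Y, hyper, T):
    """Independently coded direct evaluation of the GP posterior formulas."""
    K = lambda a, b: hyper.rho**2 * np.exp(
        -(((np.asarray(a, float)[:, None] - np.asarray(b, float)[None, :]) / hyper.ell) ** 2)
    )
    Sigma = K(X, X) + hyper.tau_obs**2 * np.eye(len(X))
    Si = np.linalg.inv(Sigma)
    mu = np.asarray(mean_T) + K(T, X) @ Si @ (np.asarray(Y) - np.asarray(mean_X))
    cov = K(T, T) - K(T, X) @ Si @ K(T, X).T
    return mu, cov


class TestKernel:
    def test_diagonal_value(self):
        assert sqexp_kernel(3.0, 3.0, 2.0, 5.0) == pytest.approx(4.0)

    def test_one_length_scale_apart(self):
        assert sqexp_kernel(0.0, 5.0, 2.0, 5.0) == pytest.approx(4.0 * math.exp(-1))

    def test_symmetry(self):
        assert sqexp_kernel(1.0, 4.0, 1.5, 3.0) == sqexp_kernel(4.0, 1.0, 1.5, 3.0)

    def test_full_grid_psd(self):
        g = np.arange(1, 70, dtype=float)
        K = sqexp_kernel(g[:, None], g[None, :], 1.3, 6.0)
        assert np.linalg.eigvalsh(K).min() >= -1e-8

    def test_rejects_nonpositive_hyper(self):
        with pytest.raises(ValueError):
            sqexp_kernel(0.0, 1.0, -1.0, 2.0)


class TestGPCondition:
    def test_empty_design_returns_prior(self):
        hyper = GPHyperparams(1.0, 4.0, 0.3)
        T = np.arange(1, 6, dtype=float)
        mean = np.zeros(5)
        mu, cov = gp_condition(mean, np.zeros(0), [], [], hyper, T)
        assert mu == pytest.approx(mean)
        assert cov == pytest.approx(sqexp_kernel(T[:, None], T[None, :], 1.0, 4.0))

    def test_noiseless_interpolation(self):
        hyper = GPHyperparams(1.0, 4.0, 1e-7)
        T = np.array([3.0])
        mu, cov = gp_condition([0.0], [0.0], [3.0], [1.7], hyper, T)
        assert mu[0] == pytest.approx(1.7, abs=1e-4)
        assert cov[0, 0] == pytest.approx(0.0, abs=1e-4)

    def test_matches_dense_oracle(self, rng):
        hyper = GPHyperparams(1.4, 5.5, 0.25)
        X = rng.choice(np.arange(1, 70), size=5, replace=False).astype(float)
        Y = rng.normal(0, 1, 5)
        T = np.arange(1, 70, dtype=float)
        mean_T, mean_X = np.sin(T / 10), np.sin(X / 10)
        mu, cov = gp_condition(mean_T, mean_X, X, Y, hyper, T)
        mu0, cov0 = dense_gp_posterior(mean_T, mean_X, X, Y, hyper, T)
        assert np.max(np.abs(mu - mu0)) < 1e-8
        assert np.max(np.abs(cov - cov0)) < 1e-6

    def test_posterior_variance_never_exceeds_prior(self, rng):
        hyper = GPHyperparams(1.0, 6.0, 0.3)
        T = np.arange(1, 70, dtype=float)
        X = np.array([10.0, 30.0, 50.0])
        _, cov = gp_condition(np.zeros(69), np.zeros(3), X, rng.normal(size=3), hyper, T)
        assert np.all(np.diag(cov) <= hyper.rho**2 + 1e-8)

    def test_extra_design_point_reduces_variance(self, rng):
        hyper = GPHyperparams(1.0, 6.0, 0.3)
        T = np.arange(1, 70, dtype=float)
        X1 = np.array([10.0, 30.0])
        X2 = np.array([10.0, 30.0, 45.0])
        _, c1 = gp_condition(np.zeros(69), np.zeros(2), X1, [0.1, -0.2], hyper, T)
        _, c2 = gp_condition(np.zeros(69), np.zeros(3), X2, [0.1, -0.2, 0.4], hyper, T)
        assert np.all(np.diag(c2) <= np.diag(c1) + 1e-10)


class TestGPLoglik:
    def test_single_observation(self):
        hyper = GPHyperparams(1.2, 4.0, 0.5)
        ll = gp_loglik([0.7], [0.0], [5.0], hyper)
        expected = norm.logpdf(0.7, 0.0, math.sqrt(1.2**2 + 0.5**2))
        assert ll == pytest.approx(expected, abs=1e-6)

    def test_matches_mvn_oracle(self, rng):
        hyper = GPHyperparams(1.0, 5.0, 0.3)
        X = np.array([2.0, 9.0, 20.0, 33.0])
        mean = rng.normal(size=4)
        Y = rng.normal(size=4)
        K = sqexp_kernel(X[:, None], X[None, :], 1.0, 5.0) + 0.09 * np.eye(4)
        expected = multivariate_normal.logpdf(Y, mean, K)
        assert gp_loglik(Y, mean, X, hyper) == pytest.approx(expected, abs=1e-6)

    def test_permutation_invariance(self, rng):
        hyper = GPHyperparams(1.0, 5.0, 0.3)
        X = np.array([2.0, 9.0, 20.0, 33.0])
        Y = rng.normal(size=4)
        mean = np.zeros(4)
        perm = rng.permutation(4)
        assert gp_loglik(Y, mean, X, hyper) == pytest.approx(
            gp_loglik(Y[perm], mean[perm], X[perm], hyper), abs=1e-9
        )


class TestRandomWalk:
    def test_zero_innovation_is_iid(self):
        params = RWParams(0.5, 0.0, eps0=0.3)
        eps = rw_simulate(params, 10, np.random.default_rng(0))
        assert eps == pytest.approx(np.full(10, 0.3))
        bins = np.array([1, 3, 7])
        mean = np.zeros(3)
        Y = np.array([0.4, 0.1, 0.6])
        ll = rw_loglik(Y, mean, bins, params)
        expected = norm.logpdf(Y, 0.3, 0.5).sum()
        assert ll == pytest.approx(expected, abs=1e-9)

    def test_variance_growth(self, rng):
        params = RWParams(0.5, 0.2, eps0=0.0)
        n, t = 100_000, 10
        sims = np.cumsum(rng.normal(0, 0.2, size=(n, t)), axis=1)
        var_t = sims[:, -1].var()
        se = math.sqrt(2.0 / (n - 1)) * t * 0.04
        assert abs(var_t - t * 0.04) < 3 * se

    def test_filter_matches_dense_oracle(self, rng):
        # dense covariance tau_obs^2 I + tau_innov^2 min(s,t), mean mu + eps0
        params = RWParams(0.4, 0.15, eps0=0.2)
        bins = np.array([1, 2, 4, 5, 8, 11])
        mean = rng.normal(size=6)
        Y = rng.normal(size=6)
        cov = rw_cov(params, bins) + params.tau_obs**2 * np.eye(6)
        expected = multivariate_normal.logpdf(Y, mean + params.eps0, cov)
        assert rw_loglik(Y, mean, bins, params) == pytest.approx(expected, abs=1e-8)

    def test_filter_dense_agreement_random_instances(self, rng):
        for _ in range(10):
            params = RWParams(
                float(rng.uniform(0.1, 1.0)), float(rng.uniform(0.01, 0.5)),
                eps0=float(rng.normal()),
            )
            bins = np.sort(rng.choice(np.arange(1, 30), size=6, replace=False))
            mean = rng.normal(size=6)
            Y = rng.normal(size=6)
            cov = rw_cov(params, bins) + params.tau_obs**2 * np.eye(6)
            expected = multivariate_normal.logpdf(Y, mean + params.eps0, cov)
            assert rw_loglik(Y, mean, bins, params) == pytest.approx(expected, abs=1e-8)

    def test_empty_observations_rejected(self):
        with pytest.raises(ValueError):
            rw_loglik([], [], [], RWParams(0.5, 0.1))
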