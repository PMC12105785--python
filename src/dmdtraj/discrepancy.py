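"""Stochastic discrepancy structures around the deterministic mean trajectory.

Two alternatives are supported:

* a Gaussian-process discrepancy with a squared-exponential kernel over
  time-bin indices plus white observation noise, and
* a random-walk-plus-noise structure, where a latent walk ``eps`` drifts
  between bins and observations scatter around ``mean + eps``.

The GP likelihood and posterior use standard Cholesky-based conditioning
with jitter.  The random-walk marginal likelihood integrates the walk out
with a scalar Kalman filter over all 69 bins, skipping bins without
observations, so irregular visit schedules need no special handling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .cohort_io import N_BINS

_JITTER = 1e-8


@dataclass
class GPHyperparams:
    rho: float      # output scale
    ell: float      # correlation length, in 3-month bins
    tau_obs: float  # white-noise SD

    def __post_init__(self):
        if min(self.rho, self.ell, self.tau_obs) <= 0:
            raise ValueError("GP hyperparameters must be strictly positive")


@dataclass
class RWParams:
    tau_obs: float    # observation-noise SD
    tau_innov: float  # random-walk step SD
    eps0: float = 0.0

    def __post_init__(self):
        if self.tau_obs <= 0 or self.tau_innov < 0:
            raise ValueError("noise SDs must be positive")


def sqexp_kernel(x1, x2, rho: float, ell: float):
    """Squared-exponential kernel rho^2 exp(-((x1-x2)/ell)^2).

    Note the paper-style convention without the factor 1/2 in the exponent.
    """
    if rho <= 0 or ell <= 0:
        raise ValueError("kernel hyperparameters must be strictly positive")
    d = (np.asarray(x1, dtype=float) - np.asarray(x2, dtype=float)) / ell
    return rho**2 * np.exp(-(d**2))


def _kernel_matrix(xa, xb, rho, ell):
    return sqexp_kernel(
        np.asarray(xa, dtype=float)[:, None], np.asarray(xb, dtype=float)[None, :],
        rho, ell,
    )


def _robust_cho_factor(Sigma, rho):
    """Cholesky with escalating diagonal jitter (1e-8 rho^2 steps) on failure."""
    try:
        return cho_factor(Sigma, lower=True)
    except np.linalg.LinAlgError:
        pass
    n = Sigma.shape[0]
    for scale in (1.0, 1e2, 1e4):
        try:
            return cho_factor(Sigma + scale * _JITTER * rho**2 * np.eye(n), lower=True)
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError(
        "GP conditioning failed: design covariance not positive definite"
    )


def gp_condition(mean_targets, mean_design, X, Y, hyper: GPHyperparams, T):
    """Posterior mean and covariance of the GP at targets T given (X, Y).

    ``mean_targets``/``mean_design`` are the prior mean evaluated at T and X.
    Returns the noise-free posterior over the latent function; add
    ``tau_obs^2 I`` for a predictive observation distribution.
    """
    T = np.asarray(T, dtype=float)
    mean_targets = np.asarray(mean_targets, dtype=float)
    Ktt = _kernel_matrix(T, T, hyper.rho, hyper.ell)
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        return mean_targets.copy(), Ktt
    Y = np.asarray(Y, dtype=float)
    if len(X) != len(Y):
        raise ValueError("X and Y must have equal length")
    Kxx = _kernel_matrix(X, X, hyper.rho, hyper.ell)
    Sigma = Kxx + hyper.tau_obs**2 * np.eye(len(X))
    Ktx = _kernel_matrix(T, X, hyper.rho, hyper.ell)
    cf = _robust_cho_factor(Sigma, hyper.rho)
    resid = Y - np.asarray(mean_design, dtype=float)
    post_mean = mean_targets + Ktx @ cho_solve(cf, resid)
    post_cov = Ktt - Ktx @ cho_solve(cf, Ktx.T)
    return post_mean, post_cov


def gp_loglik(Y, mean, X, hyper: GPHyperparams) -> float:
    """Log-density of observations Y under N(mean, K(X,X) + tau_obs^2 I)."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    mean = np.asarray(mean, dtype=float)
    n = len(X)
    if n == 0:
        return 0.0
    Kxx = _kernel_matrix(X, X, hyper.rho, hyper.ell)
    Sigma = Kxx + hyper.tau_obs**2 * np.eye(n)
    cf = _robust_cho_factor(Sigma, hyper.rho)
    resid = Y - mean
    alpha = cho_solve(cf, resid)
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    return float(-0.5 * (resid @ alpha + logdet + n * math.log(2.0 * math.pi)))


def rw_cov(params: RWParams, bins) -> np.ndarray:
    """Dense covariance of eps at the given bins: tau_innov^2 * min(s, t)."""
    b = np.asarray(bins, dtype=float)
    return params.tau_innov**2 * np.minimum(b[:, None], b[None, :])


def rw_simulate(params: RWParams, horizon: int, rng: np.random.Generator):
    """Simulate eps_1..eps_horizon from eps_0 = params.eps0."""
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    steps = rng.normal(0.0, params.tau_innov, size=horizon)
    return params.eps0 + np.cumsum(steps)


def rw_loglik(Y, mean, bins, params: RWParams, horizon: int = N_BINS) -> float:
    """Marginal log-likelihood of observations under the RW+noise model.

    ``bins`` are the 1-based bin indices that carry observations; the walk
    is integrated out with a scalar Kalman filter that steps through every
    bin and updates only where an observation exists.
    """
    bins = np.asarray(bins, dtype=int)
    if bins.size == 0:
        raise ValueError("empty observation set")
    Y = np.asarray(Y, dtype=float)
    mean = np.asarray(mean, dtype=float)
    obs_at = {int(t): j for j, t in enumerate(bins)}
    m, v = params.eps0, 0.0
    qi = params.tau_innov**2
    r = params.tau_obs**2
    ll = 0.0
    log2pi = math.log(2.0 * math.pi)
    for t in range(1, horizon + 1):
        v += qi
        j = obs_at.get(t)
        if j is None:
            continue
        innov = Y[j] - (mean[j] + m)
        S = v + r
        ll -= 0.5 * (log2pi + math.log(S) + innov * innov / S)
        K = v / S
        m += K * innov
        v *= 1.0 - K
    return ll
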