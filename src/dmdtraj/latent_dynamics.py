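"""Deterministic skeleton of the trajectory model.

Two latent states drive each outcome on the transformed scale:

* the healthy state theta, an AR(1)-with-drift recursion
  ``theta_t = alpha * theta_{t-1} + delta`` describing the motor-function
  gains of a maturing child, parameterized by its start value theta_0 and
  its value theta_mat at maturity (age 20, bin index 68);
* the disease state phi, a linear accumulation
  ``phi_t = phi_{t-1} + Delta - Gamma . x_t`` pushed through a softplus so
  the resulting deficit ``phi* = log(1 + exp(phi))`` is positive and only
  "switches on" around the onset time where phi crosses zero.

The observable mean for outcome k is ``theta^(k) - beta^(k) * phi*``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort_io import N_BINS
from .transforms import softplus

#: maturity bin (age 20 years) used when deriving delta from endpoints
T_MAT_INDEX = 68


@dataclass
class HealthyStateParams:
    alpha: float
    theta0: float
    theta_mat: float
    t_mat_index: int = T_MAT_INDEX

    def __post_init__(self):
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must be in (0, 1]")

    @property
    def delta(self) -> float:
        return delta_from_endpoints(
            self.alpha, self.theta0, self.theta_mat, self.t_mat_index
        )


@dataclass
class DiseaseParams:
    Delta: float
    t_onset: float
    beta: dict = field(default_factory=dict)  # outcome -> loading
    Gamma: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self):
        if self.Delta <= 0:
            raise ValueError("Delta must be positive")
        self.Gamma = np.atleast_1d(np.asarray(self.Gamma, dtype=float))

    @property
    def phi0(self) -> float:
        return -self.t_onset * self.Delta


def delta_from_endpoints(alpha, theta0, theta_mat, t_mat_index=T_MAT_INDEX):
    """Per-step drift delta that carries theta_0 to theta_mat in t_mat steps.

    Solves the geometric-series identity
    ``theta_mat = alpha^t theta_0 + delta (1 - alpha^t)/(1 - alpha)``;
    the alpha -> 1 limit (theta_mat - theta_0)/t_mat is taken analytically.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must be in (0, 1]")
    t = t_mat_index
    if alpha >= 1.0 - 1e-12:
        return (theta_mat - theta0) / t
    at = alpha**t
    return (theta_mat - at * theta0) * (1.0 - alpha) / (1.0 - at)


def healthy_path(params: HealthyStateParams, horizon: int = N_BINS) -> np.ndarray:
    """theta_t for t = 1..horizon via the closed-form AR(1) solution."""
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    a, th0, d = params.alpha, params.theta0, params.delta
    t = np.arange(1, horizon + 1)
    if a >= 1.0 - 1e-12:
        return th0 + d * t
    at = a**t
    return at * th0 + d * (1.0 - at) / (1.0 - a)


def disease_path(
    params: DiseaseParams,
    treatment_indicators: np.ndarray | None = None,
    horizon: int = N_BINS,
):
    """(phi, phi*) for t = 1..horizon.

    ``treatment_indicators`` is a (n_treatments, horizon) binary matrix; the
    column at step t reduces that step's increment by ``Gamma . x_t``.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    t = np.arange(1, horizon + 1)
    phi = params.phi0 + params.Delta * t
    if treatment_indicators is not None and len(params.Gamma) > 0:
        x = np.asarray(treatment_indicators, dtype=float)
        if x.shape != (len(params.Gamma), horizon):
            raise ValueError(
                f"indicator matrix shape {x.shape} does not match "
                f"({len(params.Gamma)}, {horizon})"
            )
        phi = phi - np.cumsum(params.Gamma @ x)
    phi_star = softplus(phi)
    return phi, phi_star


def mean_trajectory(
    healthy: dict,
    disease: DiseaseParams,
    treatment_indicators: np.ndarray | None = None,
    horizon: int = N_BINS,
) -> dict:
    """Per-outcome mean paths ``theta^(k) - beta^(k) phi*`` (model scale).

    ``healthy`` maps outcome -> HealthyStateParams; outcomes must match
    the keys of ``disease.beta``.
    """
    if set(healthy) != set(disease.beta):
        raise ValueError("healthy-state outcomes do not match beta outcomes")
    _, phi_star = disease_path(disease, treatment_indicators, horizon)
    return {
        k: healthy_path(healthy[k], horizon) - disease.beta[k] * phi_star
        for k in healthy
    }
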