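"""The eight model variants A-H and the Hibma baseline I.

Variants differ along three switches (Table-style bijection):

=========  ===========  ==========  ==========
label      discrepancy  covariates  treatments
=========  ===========  ==========  ==========
A          RW           yes         yes
B          RW           yes         no
C          RW           no          yes
D          RW           no          no
E          GP           yes         yes
F          GP           yes         no
G          GP           no          yes
H          GP           no          no
I (Hibma)  RW           n/a         yes
=========  ===========  ==========  ==========

Every individual-level parameter is modelled hierarchically: a normal
population law on a link scale (logit for alpha, log for positive scale
parameters, softplus for treatment effects, identity otherwise).  With
covariates on, the families alpha, beta, theta_0 and theta_mat are drawn
jointly across outcomes from a multivariate normal with a scaled
correlation matrix, so information flows between NSAA, walk and RFF
measurements of the same child.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from .cohort_io import N_BINS
from .discrepancy import GPHyperparams, RWParams, gp_loglik, rw_loglik
from .latent_dynamics import DiseaseParams, HealthyStateParams, mean_trajectory
from .transforms import softplus

_LABELS = {
    "A": ("RW", True, True),
    "B": ("RW", True, False),
    "C": ("RW", False, True),
    "D": ("RW", False, False),
    "E": ("GP", True, True),
    "F": ("GP", True, False),
    "G": ("GP", False, True),
    "H": ("GP", False, False),
}

#: families that covary across outcomes when covariates=True
COV_FAMILIES = ("alpha", "beta", "theta0", "theta_mat")


@dataclass(frozen=True)
class VariantSpec:
    discrepancy: str  # "RW" or "GP"
    covariates: bool
    treatments: bool
    label: str

    @classmethod
    def from_label(cls, label: str) -> "VariantSpec":
        label = label.upper()
        if label in ("I", "HIBMA"):
            return cls("RW", False, True, "HIBMA")
        if label not in _LABELS:
            raise ValueError(f"unknown model label {label!r}; expected A-H or I")
        d, c, t = _LABELS[label]
        return cls(d, c, t, label)

    @property
    def is_hibma(self) -> bool:
        return self.label == "HIBMA"


@dataclass
class HibmaParams:
    """Indirect-response baseline on the raw NSAA scale."""

    phi_prod: float  # production-rate effect
    xi: float        # dissipation-rate effect
    rw: RWParams = field(default_factory=lambda: RWParams(1.0, 0.1))


@dataclass
class IndividualParams:
    healthy: dict              # outcome -> HealthyStateParams
    disease: DiseaseParams
    disc: dict                 # outcome -> GPHyperparams | RWParams
    hibma: HibmaParams | None = None
    z: np.ndarray | None = None  # link-scale vector this was built from


@dataclass
class PatientData:
    """One patient's observations on the model scale (plus raw values)."""

    patient_id: str
    obs: dict          # outcome -> (bins int array, model-scale values)
    raw: dict          # outcome -> (bins int array, natural-scale values)
    treat: np.ndarray  # (n_treatments, N_BINS) binary indicator matrix

    def n_points(self, outcome: str) -> int:
        return 0 if outcome not in self.obs else len(self.obs[outcome][0])


# --------------------------------------------------------------------------
# parameter layout


_LINKS = {
    "logit": (expit, lambda p: logit(p)),
    "log": (np.exp, np.log),
    "identity": (lambda z: z, lambda v: v),
    "softplus": (softplus, lambda v: np.log(np.expm1(v))),
}


@dataclass
class ParamLayout:
    """Names, links and population grouping of the individual parameter vector."""

    names: list
    links: list
    groups: list        # (group_name, [coord indices]); one sigma per group
    cov_families: dict  # family name -> coord indices (covaried across outcomes)

    @property
    def n_coords(self) -> int:
        return len(self.names)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def to_natural(self, z: np.ndarray) -> np.ndarray:
        out = np.empty_like(z, dtype=float)
        for j, link in enumerate(self.links):
            out[..., j] = _LINKS[link][0](z[..., j])
        return out


def _build_layout(spec: VariantSpec, outcomes, treatment_names) -> ParamLayout:
    names, links = [], []
    if spec.is_hibma:
        names += ["phi_prod", "xi", "tau_obs", "tau_innov", "eps0"]
        links += ["identity", "identity", "log", "log", "identity"]
        groups = [(n, [i]) for i, n in enumerate(names)]
        return ParamLayout(names, links, groups, {})

    for k in outcomes:
        names += [f"alpha:{k}", f"theta0:{k}", f"theta_mat:{k}", f"beta:{k}"]
        links += ["logit", "identity", "identity", "identity"]
    names += ["Delta", "t_onset"]
    links += ["log", "identity"]
    for k in outcomes:
        if spec.discrepancy == "RW":
            names += [f"tau_obs:{k}", f"tau_innov:{k}", f"eps0:{k}"]
            links += ["log", "log", "identity"]
        else:
            names += [f"tau_obs:{k}", f"rho:{k}", f"ell:{k}"]
            links += ["log", "log", "log"]
    if spec.treatments:
        for p in treatment_names:
            names.append(f"gamma:{p}")
            links.append("softplus")

    cov_families = {}
    if spec.covariates and len(outcomes) > 1:
        for fam in COV_FAMILIES:
            cov_families[fam] = [names.index(f"{fam}:{k}") for k in outcomes]
    covered = {i for idx in cov_families.values() for i in idx}
    groups = [(fam, idx) for fam, idx in cov_families.items()]
    groups += [(n, [i]) for i, n in enumerate(names) if i not in covered]
    return ParamLayout(names, links, groups, cov_families)


# --------------------------------------------------------------------------
# population hyperparameters


@dataclass
class PopulationHyperparams:
    """Normal population laws on the link scale.

    ``mu`` has one entry per individual coordinate; ``sigma`` one entry per
    scale group (covaried families share a scalar sigma); ``corr`` maps a
    covaried family to its unit-diagonal correlation matrix, so the family's
    covariance across outcomes is ``sigma^2 * Corr``.
    """

    mu: np.ndarray
    sigma: np.ndarray
    corr: dict = field(default_factory=dict)

    def copy(self) -> "PopulationHyperparams":
        return PopulationHyperparams(
            self.mu.copy(), self.sigma.copy(), {k: v.copy() for k, v in self.corr.items()}
        )


def _group_sigma_per_coord(layout: ParamLayout, sigma: np.ndarray) -> np.ndarray:
    out = np.empty(layout.n_coords)
    for g, (_, idx) in enumerate(layout.groups):
        out[idx] = sigma[g]
    return out


def z_prior_logpdf(layout: ParamLayout, pop: PopulationHyperparams, z: np.ndarray) -> float:
    """Log-density of one individual's link-scale vector under the hierarchy."""
    ll = 0.0
    for g, (name, idx) in enumerate(layout.groups):
        resid = z[idx] - pop.mu[idx]
        s = pop.sigma[g]
        if name in pop.corr:
            C = pop.corr[name] * s**2
            L = np.linalg.cholesky(C)
            w = np.linalg.solve(L, resid)
            ll -= 0.5 * (w @ w) + np.sum(np.log(np.diag(L))) + 0.5 * len(idx) * math.log(2 * math.pi)
        else:
            ll -= 0.5 * float(resid @ resid) / s**2 + len(idx) * (
                math.log(s) + 0.5 * math.log(2 * math.pi)
            )
    return ll


def sample_z(
    layout: ParamLayout, pop: PopulationHyperparams, rng: np.random.Generator, n: int = 1
) -> np.ndarray:
    """Draw n link-scale individual parameter vectors from the hierarchy."""
    Z = np.empty((n, layout.n_coords))
    for g, (name, idx) in enumerate(layout.groups):
        s = pop.sigma[g]
        if name in pop.corr:
            C = pop.corr[name] * s**2
            L = np.linalg.cholesky(C)
            Z[:, idx] = pop.mu[idx] + rng.standard_normal((n, len(idx))) @ L.T
        else:
            Z[:, idx] = pop.mu[idx] + s * rng.standard_normal((n, len(idx)))
    return Z


# --------------------------------------------------------------------------
# variant model


@dataclass
class PriorConfig:
    """Weak hyperpriors on population-level parameters (link scale)."""

    mu_sd: float = 5.0        # Normal(0, mu_sd^2) on population means
    sigma_scale: float = 2.0  # half-Normal(0, sigma_scale^2) on population SDs
    lkj_eta: float = 2.0      # LKJ-style shape on correlation matrices


@dataclass
class VariantModel:
    spec: VariantSpec
    outcomes: tuple
    treatment_names: tuple
    layout: ParamLayout
    priors: PriorConfig = field(default_factory=PriorConfig)

    # ---- parameter bookkeeping ------------------------------------------
    def population_parameter_names(self) -> list:
        names = [f"mu_{n}" for n in self.layout.names]
        names += [f"sigma_{g}" for g, _ in self.layout.groups]
        names += [f"Corr_{fam}" for fam in self.layout.cov_families]
        return names

    def z_to_params(self, z: np.ndarray) -> IndividualParams:
        nat = self.layout.to_natural(np.asarray(z, dtype=float))
        get = lambda name: float(nat[self.layout.index(name)])
        if self.spec.is_hibma:
            hib = HibmaParams(
                get("phi_prod"), get("xi"),
                RWParams(get("tau_obs"), get("tau_innov"), get("eps0")),
            )
            return IndividualParams({}, None, {}, hibma=hib, z=np.asarray(z, float))
        healthy = {
            k: HealthyStateParams(get(f"alpha:{k}"), get(f"theta0:{k}"), get(f"theta_mat:{k}"))
            for k in self.outcomes
        }
        beta = {k: get(f"beta:{k}") for k in self.outcomes}
        Gamma = np.array(
            [get(f"gamma:{p}") for p in self.treatment_names]
            if self.spec.treatments else [],
        )
        disease = DiseaseParams(get("Delta"), get("t_onset"), beta, Gamma)
        disc = {}
        for k in self.outcomes:
            if self.spec.discrepancy == "RW":
                disc[k] = RWParams(get(f"tau_obs:{k}"), get(f"tau_innov:{k}"), get(f"eps0:{k}"))
            else:
                disc[k] = GPHyperparams(get(f"rho:{k}"), get(f"ell:{k}"), get(f"tau_obs:{k}"))
        return IndividualParams(healthy, disease, disc, z=np.asarray(z, float))

    def mean_paths(self, params: IndividualParams, treat: np.ndarray | None) -> dict:
        x = treat if (self.spec.treatments and treat is not None and treat.size) else None
        return mean_trajectory(params.healthy, params.disease, x, N_BINS)

    # ---- likelihood ------------------------------------------------------
    def individual_loglik(self, params: IndividualParams, patient: PatientData) -> float:
        """Joint log-likelihood of one patient's observations (model scale)."""
        if self.spec.is_hibma:
            return _hibma_loglik(params.hibma, patient)
        if not patient.obs:
            return 0.0
        means = self.mean_paths(params, patient.treat)
        ll = 0.0
        for k, (bins, y) in patient.obs.items():
            if len(bins) == 0:
                continue
            mu = means[k][np.asarray(bins, int) - 1]
            if self.spec.discrepancy == "RW":
                ll += rw_loglik(y, mu, bins, params.disc[k])
            else:
                ll += gp_loglik(y, mu, bins, params.disc[k])
        return ll


def build_variant(
    spec: VariantSpec | str,
    outcomes=("nsaa",),
    treatment_names=(),
    priors: PriorConfig | None = None,
) -> VariantModel:
    """Assemble a variant model definition (priors + likelihood structure)."""
    if isinstance(spec, str):
        spec = VariantSpec.from_label(spec)
    outcomes = tuple(outcomes)
    if spec.is_hibma and outcomes != ("nsaa",):
        raise ValueError("the Hibma baseline models NSAA scores only")
    if spec.treatments and not spec.is_hibma and not treatment_names:
        treatment_names = ("steroid",)
    layout = _build_layout(spec, outcomes, treatment_names)
    return VariantModel(spec, outcomes, tuple(treatment_names),
                        layout, priors or PriorConfig())


def sample_individual_params(
    variant: VariantModel, pop: PopulationHyperparams, rng: np.random.Generator
) -> IndividualParams:
    """Draw one individual's parameters from the population hierarchy."""
    z = sample_z(variant.layout, pop, rng, 1)[0]
    return variant.z_to_params(z)


# --------------------------------------------------------------------------
# Hibma baseline


def hibma_mean_path(params: HibmaParams, y0: float, horizon: int, t_start: int = 0):
    """Deterministic recursion y_t = y_{t-1} + phi - t xi y_{t-1} from y0."""
    out = np.empty(horizon)
    y = y0
    for j in range(horizon):
        t = t_start + j + 1
        y = y + params.phi_prod - t * params.xi * y
        out[j] = y
    return out


def _hibma_loglik(params: HibmaParams, patient: PatientData) -> float:
    """Likelihood on the raw NSAA scale, conditioning on the first point.

    The indirect-response mean recursion is run on the full bin grid from the
    first observed score; the random walk and observation noise around it are
    integrated out by the same Kalman filter used for the RW variants.
    """
    if "nsaa" not in patient.raw or len(patient.raw["nsaa"][0]) < 2:
        return 0.0
    bins, y = patient.raw["nsaa"]
    order = np.argsort(bins)
    bins, y = np.asarray(bins, int)[order], np.asarray(y, float)[order]
    t0 = int(bins[0])
    horizon = N_BINS - t0
    mean = hibma_mean_path(params, y[0], horizon, t_start=t0)
    rel_bins = bins[1:] - t0  # 1-based positions after t0
    return rw_loglik(y[1:], mean[rel_bins - 1], rel_bins, params.rw, horizon=horizon)


def hibma_predict(
    params: HibmaParams,
    y0: float,
    horizon: int,
    rng: np.random.Generator | None = None,
    n_draws: int = 0,
    t_start: int = 0,
):
    """Forecast raw NSAA scores from a starting score y0.

    Deterministic mode (``rng`` None) returns the mean recursion with point
    predictions floored at 0.  Stochastic mode returns ``n_draws`` sampled
    trajectories (mean + random walk + observation noise), from which
    interval bounds should be taken via :func:`hibma_quantiles` so lower
    bounds are floored at 0 and upper bounds capped at 34.
    """
    if not (0.0 <= y0 <= 34.0):
        raise ValueError("y0 must be a raw NSAA score in [0, 34]")
    mean = hibma_mean_path(params, y0, horizon, t_start)
    if rng is None:
        return np.maximum(mean, 0.0)
    draws = np.empty((n_draws, horizon))
    for d in range(n_draws):
        steps = rng.normal(0.0, params.rw.tau_innov, size=horizon)
        eps = params.rw.eps0 + np.cumsum(steps)
        draws[d] = mean + eps + rng.normal(0.0, params.rw.tau_obs, size=horizon)
    return draws


def hibma_quantiles(draws: np.ndarray, levels) -> np.ndarray:
    """Quantiles of Hibma draws with the clamping rules applied.

    Lower bounds (and the median) are floored at 0; upper bounds (levels
    above 0.5) are additionally capped at 34.
    """
    levels = np.asarray(levels, dtype=float)
    q = np.quantile(draws, levels, axis=0)
    q = np.maximum(q, 0.0)
    upper = levels > 0.5
    q[upper] = np.minimum(q[upper], 34.0)
    return q
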