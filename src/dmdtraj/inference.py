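"""Population fitting, posterior approximation and individual calibration.

The population model is fit by Metropolis-within-Gibbs MCMC: population
means get conjugate Gibbs updates, population SDs and correlation entries
get adaptive random-walk Metropolis steps on unconstrained scales, and each
patient's link-scale parameter block gets a joint adaptive random-walk
Metropolis update against the marginal likelihood of that patient's
observations (the RW discrepancy is integrated out by Kalman filtering,
the GP discrepancy analytically).

The population posterior is then summarized by a multivariate normal on a
working scale (log for positive-truncated hyperparameters, Fisher-z for
correlations).  New individuals are recalibrated against that MVN acting
as a fixed prior: a short MCMC over (population vector, individual
parameters) given the individual's prediction points.  Posterior
predictive draws condition the discrepancy process on those points and are
back-transformed to the natural outcome scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .cohort_io import N_BINS, Cohort
from .discrepancy import rw_cov, sqexp_kernel
from .model_variants import (
    PatientData,
    PopulationHyperparams,
    VariantModel,
    sample_z,
    z_prior_logpdf,
)
from .transforms import Normalizer

_LOG2PI = math.log(2.0 * math.pi)


@dataclass
class MCMCConfig:
    n_iter: int = 2000
    n_warmup: int = 1000
    n_chains: int = 2
    target_accept_vector: float = 0.23
    target_accept_scalar: float = 0.44
    adapt_rate: float = 0.66


# --------------------------------------------------------------------------
# data preparation


def prepare_patients(
    cohort: Cohort, variant: VariantModel, normalizer: Normalizer
) -> list:
    """Convert a cohort to per-patient model-scale observation blocks."""
    patients = []
    n_tr = len(variant.treatment_names)
    for pid, grp in cohort.data.groupby("patient_id", sort=True):
        obs, raw = {}, {}
        for k in variant.outcomes:
            sub = grp[grp["outcome"] == k].sort_values("time_bin")
            if len(sub) == 0:
                continue
            bins = sub["time_bin"].to_numpy(int)
            vals = sub["value"].to_numpy(float)
            raw[k] = (bins, vals)
            obs[k] = (bins, np.atleast_1d(normalizer.natural_to_model(k, vals)))
        treat = np.zeros((n_tr, N_BINS))
        for j, name in enumerate(variant.treatment_names):
            col = f"treat_{name}"
            if col in grp.columns:
                on = grp[grp[col] == 1]["time_bin"]
                if len(on):
                    treat[j, int(on.min()) - 1 :] = 1.0
        patients.append(PatientData(str(pid), obs, raw, treat))
    return patients


def heuristic_init(variant: VariantModel, patients) -> PopulationHyperparams:
    """Crude moment-based starting point for the population hierarchy."""
    layout = variant.layout
    mu = np.zeros(layout.n_coords)
    for j, name in enumerate(layout.names):
        fam = name.split(":")[0]
        k = name.split(":")[1] if ":" in name else None
        vals = [p.obs[k][1] for p in patients if k in p.obs] if k else []
        pooled = np.concatenate(vals) if vals else np.zeros(1)
        if fam == "alpha":
            mu[j] = 2.5
        elif fam == "theta0":
            mu[j] = float(np.median(pooled)) - 0.5
        elif fam == "theta_mat":
            mu[j] = float(np.quantile(pooled, 0.9))
        elif fam == "beta":
            mu[j] = 1.0 if k == "nsaa" else -0.5
        elif fam == "Delta":
            mu[j] = math.log(0.1)
        elif fam == "t_onset":
            mu[j] = 25.0
        elif fam == "tau_obs":
            mu[j] = math.log(0.3) if not variant.spec.is_hibma else math.log(1.5)
        elif fam in ("tau_innov", "rho"):
            mu[j] = math.log(0.15) if not variant.spec.is_hibma else math.log(0.5)
        elif fam == "ell":
            mu[j] = math.log(5.0)
        elif fam == "gamma":
            mu[j] = -3.0
        elif fam == "phi_prod":
            mu[j] = 0.5
        elif fam == "xi":
            mu[j] = 1e-3
        else:  # eps0
            mu[j] = 0.0
    sigma = np.full(layout.n_groups, 0.3)
    for g, (name, idx) in enumerate(layout.groups):
        if name.split(":")[0] == "t_onset":
            sigma[g] = 5.0
        elif name.split(":")[0] == "xi":
            sigma[g] = 5e-4
    corr = {fam: np.eye(len(idx)) for fam, idx in layout.cov_families.items()}
    return PopulationHyperparams(mu, sigma, corr)


# --------------------------------------------------------------------------
# working-scale packing of population hyperparameters


def working_names(variant: VariantModel) -> list:
    layout = variant.layout
    names = [f"mu_{n}" for n in layout.names]
    names += [f"log_sigma_{g}" for g, _ in layout.groups]
    for fam, idx in layout.cov_families.items():
        K = len(idx)
        for a in range(K):
            for b in range(a + 1, K):
                names.append(f"zcorr_{fam}_{a}{b}")
    return names


def pack_population(variant: VariantModel, pop: PopulationHyperparams) -> np.ndarray:
    parts = [pop.mu, np.log(pop.sigma)]
    for fam, idx in variant.layout.cov_families.items():
        C = pop.corr[fam]
        K = len(idx)
        off = [np.arctanh(np.clip(C[a, b], -0.999, 0.999))
               for a in range(K) for b in range(a + 1, K)]
        parts.append(np.asarray(off))
    return np.concatenate(parts)


def unpack_population(variant: VariantModel, w: np.ndarray) -> PopulationHyperparams:
    layout = variant.layout
    P, G = layout.n_coords, layout.n_groups
    mu = np.asarray(w[:P], dtype=float)
    sigma = np.exp(np.asarray(w[P : P + G], dtype=float))
    corr, pos = {}, P + G
    for fam, idx in layout.cov_families.items():
        K = len(idx)
        C = np.eye(K)
        for a in range(K):
            for b in range(a + 1, K):
                C[a, b] = C[b, a] = math.tanh(w[pos])
                pos += 1
        corr[fam] = _nearest_corr(C)
    return PopulationHyperparams(mu, sigma, corr)


def _nearest_corr(C: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    vals, vecs = np.linalg.eigh(C)
    if vals.min() >= floor:
        return C
    vals = np.clip(vals, floor, None)
    C = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(C))
    return C / np.outer(d, d)


# --------------------------------------------------------------------------
# hyperprior densities


def _halfnormal_logpdf(x, scale):
    if x <= 0:
        return -np.inf
    return math.log(2.0) - math.log(scale) - 0.5 * _LOG2PI - 0.5 * (x / scale) ** 2


def _lkj_logpdf(C, eta):
    sign, logdet = np.linalg.slogdet(C)
    if sign <= 0:
        return -np.inf
    return (eta - 1.0) * logdet


# --------------------------------------------------------------------------
# the population sampler


class _StepSize:
    """Robbins-Monro step-size adapter for a Metropolis block."""

    def __init__(self, log_step, target, rate):
        self.log_step = log_step
        self.target = target
        self.rate = rate
        self.t = 0

    @property
    def step(self):
        return math.exp(self.log_step)

    def update(self, accept_prob):
        self.t += 1
        self.log_step += (accept_prob - self.target) / (1.0 + self.t) ** self.rate


class _BlockAdapter:
    """Adaptive-covariance proposal for one Metropolis block.

    Starts from a diagonal scale; once enough warmup states are observed,
    proposals follow the running empirical covariance (2.38^2/d scaling),
    which lets the sampler track the strong ridges between e.g. the
    maturity value, the outcome loading and the progression increment.
    """

    _MIN_OBS = 100

    def __init__(self, dim, diag_scale):
        self.dim = dim
        self.diag = np.asarray(diag_scale, dtype=float)
        self.n = 0
        self.mean = np.zeros(dim)
        self.m2 = np.zeros((dim, dim))
        self.chol = None

    def observe(self, x):
        self.n += 1
        d = x - self.mean
        self.mean += d / self.n
        self.m2 += np.outer(d, x - self.mean)
        if self.n >= self._MIN_OBS and self.n % 50 == 0:
            cov = self.m2 / (self.n - 1)
            cov = cov + 1e-8 * np.eye(self.dim) + 1e-4 * np.diag(self.diag**2)
            try:
                self.chol = (2.38 / math.sqrt(self.dim)) * np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                self.chol = None

    def propose(self, rng):
        eps = rng.standard_normal(self.dim)
        if self.chol is None:
            return self.diag * eps
        return self.chol @ eps


def _group_block_loglik(pop, layout, Z, g):
    """Sum over patients of the hierarchy density for scale group g."""
    name, idx = layout.groups[g]
    s = pop.sigma[g]
    resid = Z[:, idx] - pop.mu[idx]
    n, K = resid.shape
    if name in pop.corr:
        C = pop.corr[name] * s**2
        try:
            L = np.linalg.cholesky(C)
        except np.linalg.LinAlgError:
            return -np.inf
        W = np.linalg.solve(L, resid.T)
        return float(
            -0.5 * np.sum(W**2) - n * np.sum(np.log(np.diag(L))) - 0.5 * n * K * _LOG2PI
        )
    return float(-0.5 * np.sum(resid**2) / s**2 - n * K * (math.log(s) + 0.5 * _LOG2PI))


def _map_init(variant, patients, pop0, maxiter: int = 800):
    """Per-patient penalized MAP under an inflated copy of the init hierarchy.

    Random-walk discrepancies make the per-patient likelihood multimodal in
    the structural parameters (the walk can soak up trajectory shape), so
    chains started far from the data-supported basin can stall there.  A
    cheap Nelder-Mead pass per patient lands every block in its basin; the
    population init is then re-centred on the MAP cloud.
    """
    from scipy.optimize import minimize

    layout = variant.layout
    wide = pop0.copy()
    wide.sigma = wide.sigma * 2.0
    Z = np.empty((len(patients), layout.n_coords))
    for i, pat in enumerate(patients):
        def neg(z):
            try:
                ll = variant.individual_loglik(variant.z_to_params(z), pat)
            except (ValueError, np.linalg.LinAlgError):
                return np.inf
            return -(ll + z_prior_logpdf(layout, wide, z))

        res = minimize(neg, pop0.mu, method="Nelder-Mead",
                       options={"maxiter": maxiter, "fatol": 1e-6})
        Z[i] = res.x
    pop = pop0.copy()
    pop.mu = Z.mean(axis=0)
    for g, (_, idx) in enumerate(layout.groups):
        pop.sigma[g] = max(float(Z[:, idx].std()), 0.05)
    return Z, pop


def _run_chain(variant, patients, init_pop, config, rng, record_z=False,
               init_Z=None):
    layout = variant.layout
    n_pat = len(patients)
    P, G = layout.n_coords, layout.n_groups
    pr = variant.priors

    pop = init_pop.copy()
    if init_Z is None:
        Z = np.tile(pop.mu, (n_pat, 1)) + 0.05 * rng.standard_normal((n_pat, P))
    else:
        Z = init_Z + 0.02 * rng.standard_normal((n_pat, P))
    z_ll = np.array([
        variant.individual_loglik(variant.z_to_params(Z[i]), patients[i])
        for i in range(n_pat)
    ])

    base_scale = np.maximum(_coord_sigma(layout, init_pop.sigma), 1e-3)
    # two Metropolis blocks per patient: structural trajectory parameters
    # and discrepancy/noise parameters mix better separately
    blocks = _patient_blocks(layout)
    z_adapt = [[_BlockAdapter(len(b), base_scale[b]) for b in blocks]
               for _ in range(n_pat)]
    z_steps = [[_StepSize(math.log(0.5), config.target_accept_vector, config.adapt_rate)
                for _ in blocks] for _ in range(n_pat)]
    s_steps = [_StepSize(math.log(0.3), config.target_accept_scalar, config.adapt_rate)
               for _ in range(G)]
    c_steps = {fam: _StepSize(math.log(0.1), config.target_accept_scalar, config.adapt_rate)
               for fam in layout.cov_families}

    n_keep = config.n_iter - config.n_warmup
    W = len(pack_population(variant, pop))
    draws = np.empty((n_keep, W))
    z_draws = np.empty((n_keep, n_pat, P)) if record_z else None

    for it in range(config.n_iter):
        warm = it < config.n_warmup

        # conjugate Gibbs for population means
        for g, (name, idx) in enumerate(layout.groups):
            s = pop.sigma[g]
            if name in pop.corr:
                Sg = pop.corr[name] * s**2
                Sg_inv = np.linalg.inv(Sg)
                prec = n_pat * Sg_inv + np.eye(len(idx)) / pr.mu_sd**2
                cov = np.linalg.inv(prec)
                mean = cov @ (Sg_inv @ Z[:, idx].sum(axis=0))
                pop.mu[idx] = rng.multivariate_normal(mean, cov)
            else:
                j = idx[0]
                prec = n_pat / s**2 + 1.0 / pr.mu_sd**2
                mean = (Z[:, j].sum() / s**2) / prec
                pop.mu[j] = mean + rng.standard_normal() / math.sqrt(prec)

        # Metropolis on log population SDs
        for g, (name, idx) in enumerate(layout.groups):
            cur = _group_block_loglik(pop, layout, Z, g) + _halfnormal_logpdf(
                pop.sigma[g], pr.sigma_scale) + math.log(pop.sigma[g])
            old = pop.sigma[g]
            pop.sigma[g] = old * math.exp(s_steps[g].step * rng.standard_normal())
            new = _group_block_loglik(pop, layout, Z, g) + _halfnormal_logpdf(
                pop.sigma[g], pr.sigma_scale) + math.log(pop.sigma[g])
            a = min(1.0, math.exp(min(0.0, new - cur)))
            if rng.random() >= a:
                pop.sigma[g] = old
            if warm:
                s_steps[g].update(a)

        # Metropolis on correlation entries
        for fam in layout.cov_families:
            g = [i for i, (n_, _) in enumerate(layout.groups) if n_ == fam][0]
            C = pop.corr[fam]
            K = C.shape[0]
            a_, b_ = rng.integers(K), rng.integers(K - 1)
            b_ = b_ + 1 if b_ >= a_ else b_
            a_, b_ = min(a_, b_), max(a_, b_)
            cur = _group_block_loglik(pop, layout, Z, g) + _lkj_logpdf(C, pr.lkj_eta)
            Cn = C.copy()
            Cn[a_, b_] = Cn[b_, a_] = C[a_, b_] + c_steps[fam].step * rng.standard_normal()
            acc = 0.0
            if abs(Cn[a_, b_]) < 0.999:
                pop.corr[fam] = Cn
                new = _group_block_loglik(pop, layout, Z, g) + _lkj_logpdf(Cn, pr.lkj_eta)
                if np.isfinite(new):
                    acc = min(1.0, math.exp(min(0.0, new - cur)))
                if rng.random() < acc:
                    pass
                else:
                    pop.corr[fam] = C
            if warm:
                c_steps[fam].update(acc)

        # blocked Metropolis updates per patient (adaptive-covariance proposals)
        for i in range(n_pat):
            for b, idx_b in enumerate(blocks):
                cur = z_ll[i] + z_prior_logpdf(layout, pop, Z[i])
                prop = Z[i].copy()
                prop[idx_b] += z_steps[i][b].step * z_adapt[i][b].propose(rng)
                try:
                    prop_ll = variant.individual_loglik(
                        variant.z_to_params(prop), patients[i])
                except (ValueError, np.linalg.LinAlgError):
                    prop_ll = -np.inf
                new = prop_ll + z_prior_logpdf(layout, pop, prop)
                a = 0.0 if not np.isfinite(new) else min(
                    1.0, math.exp(min(0.0, new - cur)))
                if rng.random() < a:
                    Z[i] = prop
                    z_ll[i] = prop_ll
                if warm:
                    z_steps[i][b].update(a)
                    z_adapt[i][b].observe(Z[i][idx_b])

        if not warm:
            draws[it - config.n_warmup] = pack_population(variant, pop)
            if record_z:
                z_draws[it - config.n_warmup] = Z
    return draws, z_draws


_NOISE_FAMILIES = ("tau_obs", "tau_innov", "eps0", "rho", "ell")


def _patient_blocks(layout):
    noise = [j for j, n in enumerate(layout.names)
             if n.split(":")[0] in _NOISE_FAMILIES]
    struct = [j for j in range(layout.n_coords) if j not in noise]
    return [np.asarray(b, int) for b in (struct, noise) if b]


def _coord_sigma(layout, sigma):
    out = np.empty(layout.n_coords)
    for g, (_, idx) in enumerate(layout.groups):
        out[idx] = sigma[g]
    return out


# --------------------------------------------------------------------------
# convergence summaries


def split_rhat(chains: np.ndarray) -> np.ndarray:
    """Split-R-hat per parameter; ``chains`` has shape (C, N, W)."""
    C, N, W = chains.shape
    half = N // 2
    seq = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    m, n = seq.shape[0], seq.shape[1]
    means = seq.mean(axis=1)
    B = n * means.var(axis=0, ddof=1)
    Wv = seq.var(axis=1, ddof=1).mean(axis=0)
    var_plus = (n - 1) / n * Wv + B / n
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.sqrt(var_plus / Wv)
    return np.where(Wv > 0, out, 1.0)


def effective_sample_size(chains: np.ndarray) -> np.ndarray:
    """Autocorrelation-based bulk ESS (Geyer initial positive sequence)."""
    C, N, W = chains.shape
    ess = np.empty(W)
    for w in range(W):
        acov = np.zeros(N)
        for c in range(C):
            x = chains[c, :, w] - chains[c, :, w].mean()
            f = np.fft.rfft(x, 2 * N)
            ac = np.fft.irfft(f * np.conj(f))[:N] / N
            acov += ac
        acov /= C
        if acov[0] <= 0:
            ess[w] = C * N
            continue
        rho = acov / acov[0]
        tau = 1.0
        for t in range(1, N - 1, 2):
            pair = rho[t] + rho[t + 1]
            if pair < 0:
                break
            tau += 2.0 * pair
        ess[w] = C * N / tau
    return ess


# --------------------------------------------------------------------------
# population posterior containers


@dataclass
class PopulationPosterior:
    variant: VariantModel
    normalizer: Normalizer
    draws: np.ndarray       # (n_chains, n_keep, W) on the working scale
    param_names: list
    rhat: dict = field(default_factory=dict)
    ess: dict = field(default_factory=dict)

    def flat_draws(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])

    def posterior_mean_population(self) -> PopulationHyperparams:
        return unpack_population(self.variant, self.flat_draws().mean(axis=0))

    def summary(self):
        import pandas as pd

        flat = self.flat_draws()
        return pd.DataFrame({
            "param": self.param_names,
            "mean": flat.mean(axis=0),
            "sd": flat.std(axis=0, ddof=1),
            "q2.5": np.quantile(flat, 0.025, axis=0),
            "q97.5": np.quantile(flat, 0.975, axis=0),
            "rhat": [self.rhat[n] for n in self.param_names],
            "ess": [self.ess[n] for n in self.param_names],
        })


def fit_population(
    cohort: Cohort,
    variant: VariantModel,
    config: MCMCConfig,
    seed: int,
    normalizer: Normalizer | None = None,
    init: PopulationHyperparams | None = None,
) -> PopulationPosterior:
    """Fit the population hierarchy to a training cohort by MCMC."""
    if cohort.data.empty:
        raise ValueError("training cohort is empty")
    if normalizer is None:
        normalizer = (
            Normalizer.identity(variant.outcomes)
            if variant.spec.is_hibma
            else Normalizer.fit(cohort)
        )
    patients = prepare_patients(cohort, variant, normalizer)
    if init is None:
        init = heuristic_init(variant, patients)
    init_Z, init = _map_init(variant, patients, init)
    seeds = np.random.SeedSequence(seed).spawn(config.n_chains)
    chains = []
    for c in range(config.n_chains):
        rng = np.random.default_rng(seeds[c])
        draws, _ = _run_chain(variant, patients, init, config, rng, init_Z=init_Z)
        chains.append(draws)
    chains = np.stack(chains)
    names = working_names(variant)
    rhat = dict(zip(names, split_rhat(chains)))
    ess = dict(zip(names, effective_sample_size(chains)))
    return PopulationPosterior(variant, normalizer, chains, names, rhat, ess)


# --------------------------------------------------------------------------
# multivariate-normal approximation


@dataclass
class PopulationMVN:
    """MVN summary of the population posterior on the working scale."""

    variant: VariantModel
    normalizer: Normalizer
    mean: np.ndarray
    cov: np.ndarray
    param_names: list

    def __post_init__(self):
        self._chol = np.linalg.cholesky(self.cov)
        self._cf = cho_factor(self.cov, lower=True)
        self._logdet = 2.0 * np.sum(np.log(np.diag(self._chol)))

    def logpdf(self, w: np.ndarray) -> float:
        r = w - self.mean
        return float(-0.5 * (r @ cho_solve(self._cf, r) + self._logdet
                             + len(r) * _LOG2PI))

    def sample_working(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        return self.mean + rng.standard_normal((n, len(self.mean))) @ self._chol.T

    def sample_population(self, rng: np.random.Generator) -> PopulationHyperparams:
        return unpack_population(self.variant, self.sample_working(rng, 1)[0])

    @classmethod
    def from_population(
        cls, variant, pop: PopulationHyperparams, normalizer=None, spread: float = 1e-3
    ) -> "PopulationMVN":
        """Degenerate MVN centred on explicit hyperparameters (ground truth)."""
        w = pack_population(variant, pop)
        return cls(variant, normalizer or Normalizer.identity(variant.outcomes),
                   w, spread**2 * np.eye(len(w)), working_names(variant))


def approximate_mvn(posterior: PopulationPosterior, ridge: float = 1e-8) -> PopulationMVN:
    """Moment-matched MVN of the working-scale population posterior."""
    flat = posterior.flat_draws()
    if flat.shape[0] < 100:
        raise ValueError("need at least 100 draws for the MVN approximation")
    mean = flat.mean(axis=0)
    cov = np.cov(flat, rowvar=False)
    cov = np.atleast_2d(cov)
    vals = np.linalg.eigvalsh(cov)
    if vals.min() < ridge:
        cov = cov + (ridge - min(vals.min(), 0.0)) * np.eye(cov.shape[0])
    return PopulationMVN(posterior.variant, posterior.normalizer, mean, cov,
                         posterior.param_names)


# --------------------------------------------------------------------------
# individual calibration


@dataclass
class IndividualPosterior:
    variant: VariantModel
    normalizer: Normalizer
    patient: PatientData
    z_draws: np.ndarray  # (n_draws, P) link-scale individual parameters
    w_draws: np.ndarray


def calibrate_individual(
    patient: PatientData,
    mvn: PopulationMVN,
    config: MCMCConfig,
    seed: int,
    n_draws: int = 400,
) -> IndividualPosterior:
    """Posterior over one individual's parameters given their prediction points.

    With zero prediction points this returns prior draws (population-level
    information alone); otherwise a joint MCMC over the working-scale
    population vector (MVN prior) and the individual's link-scale block.
    """
    variant, layout = mvn.variant, mvn.variant.layout
    rng = np.random.default_rng(seed)
    total = sum(len(b) for b, _ in patient.obs.values())

    if total == 0:
        W = mvn.sample_working(rng, n_draws)
        Zs = np.empty((n_draws, layout.n_coords))
        for d in range(n_draws):
            pop = unpack_population(variant, W[d])
            Zs[d] = sample_z(layout, pop, rng, 1)[0]
        return IndividualPosterior(variant, mvn.normalizer, patient, Zs, W)

    w = mvn.mean.copy()
    pop = unpack_population(variant, w)
    z = pop.mu.copy()
    if total >= 3:  # land in the data-supported basin before sampling
        from scipy.optimize import minimize

        def _neg(zv):
            try:
                ll = variant.individual_loglik(variant.z_to_params(zv), patient)
            except (ValueError, np.linalg.LinAlgError):
                return np.inf
            return -(ll + z_prior_logpdf(layout, pop, zv))

        z = minimize(_neg, z, method="Nelder-Mead",
                     options={"maxiter": 500, "fatol": 1e-6}).x

    def z_target(zv, popv):
        try:
            ll = variant.individual_loglik(variant.z_to_params(zv), patient)
        except (ValueError, np.linalg.LinAlgError):
            return -np.inf, -np.inf
        return ll, ll + z_prior_logpdf(layout, popv, zv)

    z_ll, z_post = z_target(z, pop)
    w_post = mvn.logpdf(w) + z_prior_logpdf(layout, pop, z)

    d_w = len(w)
    base_w = (2.38 / math.sqrt(d_w)) * mvn._chol
    base_z = np.maximum(_coord_sigma(layout, pop.sigma), 1e-3)
    st_w = _StepSize(math.log(0.5), config.target_accept_vector, config.adapt_rate)
    st_z = _StepSize(math.log(0.3), config.target_accept_vector, config.adapt_rate)
    z_adapt = _BlockAdapter(layout.n_coords, base_z)

    n_keep = config.n_iter - config.n_warmup
    keep_w = np.empty((n_keep, d_w))
    keep_z = np.empty((n_keep, layout.n_coords))

    for it in range(config.n_iter):
        warm = it < config.n_warmup

        # population-vector block (prior + hierarchy terms only)
        w_prop = w + st_w.step * (base_w @ rng.standard_normal(d_w))
        pop_prop = unpack_population(variant, w_prop)
        new = mvn.logpdf(w_prop) + z_prior_logpdf(layout, pop_prop, z)
        a = min(1.0, math.exp(min(0.0, new - w_post)))
        if rng.random() < a:
            w, pop, w_post = w_prop, pop_prop, new
            z_post = z_ll + z_prior_logpdf(layout, pop, z)
        if warm:
            st_w.update(a)

        # individual block (likelihood + hierarchy)
        z_prop = z + st_z.step * z_adapt.propose(rng)
        ll_new, post_new = z_target(z_prop, pop)
        a = 0.0 if not np.isfinite(post_new) else min(
            1.0, math.exp(min(0.0, post_new - z_post)))
        if rng.random() < a:
            z, z_ll, z_post = z_prop, ll_new, post_new
            w_post = mvn.logpdf(w) + z_prior_logpdf(layout, pop, z)
        if warm:
            st_z.update(a)
            z_adapt.observe(z)

        if not warm:
            keep_w[it - config.n_warmup] = w
            keep_z[it - config.n_warmup] = z

    idx = np.linspace(0, n_keep - 1, min(n_draws, n_keep)).astype(int)
    return IndividualPosterior(variant, mvn.normalizer, patient,
                               keep_z[idx], keep_w[idx])


# --------------------------------------------------------------------------
# posterior predictive


PI_LEVELS = np.round(np.arange(0.005, 1.0, 0.005), 3)


@dataclass
class PredictiveSummary:
    """Predictive draws per outcome over all 69 bins, natural scale."""

    draws: dict  # outcome -> (n_draws, N_BINS); NaN where undefined
    n_prediction_points: int = 0

    def quantile(self, outcome: str, level: float) -> np.ndarray:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            q = np.nanquantile(self.draws[outcome], level, axis=0)
        if outcome == "nsaa":
            q = np.clip(q, 0.0, 34.0)
        return q

    def pi_bounds(self, outcome: str, level: float):
        lo = self.quantile(outcome, 0.5 - level / 2.0)
        hi = self.quantile(outcome, 0.5 + level / 2.0)
        return lo, hi

    def median(self, outcome: str) -> np.ndarray:
        return self.quantile(outcome, 0.5)


def _condition_and_sample(mean_T, K_TT, bins, y, mean_X, K_TX, K_XX, tau_obs, rng, n):
    """Sample latent paths given noisy observations; returns (n, T) draws."""
    Tn = len(mean_T)
    if len(bins) == 0:
        cond_mean, cond_cov = mean_T, K_TT
    else:
        Sigma = K_XX + tau_obs**2 * np.eye(len(bins)) + 1e-10 * np.eye(len(bins))
        cf = cho_factor(Sigma, lower=True)
        cond_mean = mean_T + K_TX @ cho_solve(cf, y - mean_X)
        cond_cov = K_TT - K_TX @ cho_solve(cf, K_TX.T)
    cond_cov = cond_cov + 1e-9 * np.eye(Tn)
    L = np.linalg.cholesky(cond_cov)
    return cond_mean + rng.standard_normal((n, Tn)) @ L.T


def posterior_predictive(
    ipost: IndividualPosterior,
    seed: int,
    n_per_draw: int = 2,
    horizon: int = N_BINS,
) -> PredictiveSummary:
    """Simulate the observation model per posterior draw and back-transform.

    Discrepancy processes are conditioned on the individual's prediction
    points (analytically, via dense Gaussian conditioning with the variant's
    kernel: squared-exponential for GP variants, the random-walk covariance
    ``tau_innov^2 min(s,t)`` for RW variants).
    """
    variant, norm, patient = ipost.variant, ipost.normalizer, ipost.patient
    rng = np.random.default_rng(seed)
    grid = np.arange(1, horizon + 1, dtype=float)
    n_dr = len(ipost.z_draws)
    n_pts = sum(len(b) for b, _ in patient.obs.values())

    if variant.spec.is_hibma:
        return _hibma_predictive(ipost, rng, n_per_draw, horizon, n_pts)

    out = {k: np.empty((n_dr * n_per_draw, horizon)) for k in variant.outcomes}
    for d in range(n_dr):
        params = variant.z_to_params(ipost.z_draws[d])
        means = variant.mean_paths(params, patient.treat)
        for k in variant.outcomes:
            mu_T = means[k]
            bins, y = patient.obs.get(k, (np.zeros(0, int), np.zeros(0)))
            disc = params.disc[k]
            if variant.spec.discrepancy == "GP":
                K_TT = sqexp_kernel(grid[:, None], grid[None, :], disc.rho, disc.ell)
                xb = np.asarray(bins, float)
                K_TX = sqexp_kernel(grid[:, None], xb[None, :], disc.rho, disc.ell)
                K_XX = sqexp_kernel(xb[:, None], xb[None, :], disc.rho, disc.ell)
                mean_T, mean_X = mu_T, mu_T[bins - 1]
            else:
                K_TT = rw_cov(disc, grid)
                K_TX = rw_cov(disc, grid)[:, np.asarray(bins, int) - 1] if len(bins) else np.zeros((horizon, 0))
                K_XX = rw_cov(disc, np.asarray(bins, float)) if len(bins) else np.zeros((0, 0))
                mean_T = mu_T + disc.eps0
                mean_X = mu_T[np.asarray(bins, int) - 1] + disc.eps0 if len(bins) else np.zeros(0)
            paths = _condition_and_sample(
                mean_T, K_TT, bins, y, mean_X, K_TX, K_XX, disc.tau_obs, rng, n_per_draw
            )
            sims = paths + rng.normal(0.0, disc.tau_obs, size=paths.shape)
            nat = np.asarray(norm.model_to_natural(k, sims))
            out[k][d * n_per_draw : (d + 1) * n_per_draw] = nat
    return PredictiveSummary(out, n_prediction_points=n_pts)


_HIBMA_DEFAULT_Y0 = 25.0


def _hibma_predictive(ipost, rng, n_per_draw, horizon, n_pts):
    from .model_variants import hibma_mean_path

    variant, patient = ipost.variant, ipost.patient
    bins, y = patient.raw.get("nsaa", (np.zeros(0, int), np.zeros(0)))
    if len(bins):
        t0, y0 = int(bins[0]), float(y[0])
        later_bins, later_y = bins[1:], y[1:]
    else:
        t0, y0 = 0, _HIBMA_DEFAULT_Y0
        later_bins, later_y = np.zeros(0, int), np.zeros(0)
    n_dr = len(ipost.z_draws)
    draws = np.full((n_dr * n_per_draw, horizon), np.nan)
    rel_grid = np.arange(1, horizon - t0 + 1, dtype=float)
    for d in range(n_dr):
        params = variant.z_to_params(ipost.z_draws[d]).hibma
        mean = hibma_mean_path(params, y0, horizon - t0, t_start=t0)
        rel = np.asarray(later_bins, int) - t0
        K_TT = rw_cov(params.rw, rel_grid)
        K_TX = K_TT[:, rel - 1] if len(rel) else np.zeros((len(rel_grid), 0))
        K_XX = rw_cov(params.rw, rel.astype(float)) if len(rel) else np.zeros((0, 0))
        mean_T = mean + params.rw.eps0
        mean_X = mean[rel - 1] + params.rw.eps0 if len(rel) else np.zeros(0)
        paths = _condition_and_sample(
            mean_T, K_TT, rel, later_y, mean_X, K_TX, K_XX,
            params.rw.tau_obs, rng, n_per_draw,
        )
        sims = paths + rng.normal(0.0, params.rw.tau_obs, size=paths.shape)
        draws[d * n_per_draw : (d + 1) * n_per_draw, t0:] = sims
    return PredictiveSummary({"nsaa": draws}, n_prediction_points=n_pts)
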