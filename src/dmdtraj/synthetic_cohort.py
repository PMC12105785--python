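"""Synthetic-cohort generation and missingness emulation.

Full trajectories are sampled from the population model (either explicit
ground-truth hyperparameters or the MVN approximation of a fitted
posterior), simulated through the observation model on every time bin,
and back-transformed to the natural scale (NSAA rounded to valid integer
scores).  Real-registry missingness is then emulated in three stages
estimated from training data: the initial-visit bin t0, an arithmetic
visit schedule {t0 + n*omega}, and informative stopping via a 6x6 grid of
per-box "last point" probabilities over the (time, NSAA) plane; finally
all NSAA scores of zero are removed, as none occur in the registry.

This module doubles as the ground-truth simulator behind every parameter
recovery and self-consistency test in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_io import AGE_MIN, BIN_WIDTH, N_BINS, NSAA_MAX, Cohort, make_cohort
from .discrepancy import rw_simulate, sqexp_kernel
from .model_variants import PopulationHyperparams, VariantModel, sample_z
from .transforms import Normalizer

#: study-scale defaults: validation-sized cohort, 100 bootstrap replicates
DEFAULT_N_TRAJECTORIES = 294
DEFAULT_BOOTSTRAP_REPS = 100
GRID_SIZE = 6


@dataclass
class MissingnessModel:
    t0_values: np.ndarray        # empirical first-observation bins
    interval_values: np.ndarray  # empirical between-visit gaps (bins)
    stop_prob: np.ndarray        # (6, 6) last-point probability per box
    t_edges: np.ndarray = field(
        default_factory=lambda: np.linspace(1.0, N_BINS + 1.0, GRID_SIZE + 1))
    nsaa_edges: np.ndarray = field(
        default_factory=lambda: np.linspace(0.0, NSAA_MAX + 1e-9, GRID_SIZE + 1))

    def box(self, time_bin: int, nsaa: float):
        ti = min(int(np.searchsorted(self.t_edges, time_bin, side="right")) - 1,
                 GRID_SIZE - 1)
        si = min(int(np.searchsorted(self.nsaa_edges, nsaa, side="right")) - 1,
                 GRID_SIZE - 1)
        return ti, si


@dataclass
class SyntheticCohort:
    full: pd.DataFrame      # every bin, columns patient_id/time_bin/outcome/value
    observed: pd.DataFrame  # after missingness emulation
    seed: int
    provenance: str = ""

    def observed_cohort(self, treatment_names=()) -> Cohort:
        df = self.observed.copy()
        df["age_years"] = AGE_MIN + (df["time_bin"] - 1) * BIN_WIDTH
        return make_cohort(df, treatment_names)


def _default_treatment_start(rng: np.random.Generator) -> int:
    # paper is silent on synthetic treatment schedules; start uniformly in
    # the pre-onset plateau (ages ~6.5-12)
    return int(rng.integers(15, 37))


def sample_trajectories(
    source,
    variant: VariantModel,
    n: int,
    seed: int,
    normalizer: Normalizer | None = None,
    treatment_start_sampler=None,
):
    """Sample n full-grid trajectories from the population model.

    ``source`` is either explicit PopulationHyperparams (ground-truth mode;
    shared by all individuals) or a PopulationMVN (one hyperparameter draw
    per individual).  Returns (DataFrame of natural-scale values on every
    bin, list of IndividualParams, treatment indicator array (n, T, 69)).
    """
    rng = np.random.default_rng(seed)
    if normalizer is None:
        normalizer = getattr(source, "normalizer", None) or Normalizer.identity(
            variant.outcomes)
    fixed_pop = isinstance(source, PopulationHyperparams)
    start_sampler = treatment_start_sampler or _default_treatment_start
    n_tr = len(variant.treatment_names)
    grid = np.arange(1, N_BINS + 1, dtype=float)

    rows, params_list = [], []
    treats = np.zeros((n, n_tr, N_BINS))
    for i in range(n):
        pop = source if fixed_pop else source.sample_population(rng)
        z = sample_z(variant.layout, pop, rng, 1)[0]
        params = variant.z_to_params(z)
        params_list.append(params)
        pid = f"synth{i:04d}"
        if variant.spec.is_hibma:
            # raw-scale recursion from a typical early-childhood score
            from .model_variants import hibma_mean_path

            hib = params.hibma
            y0 = float(np.clip(rng.normal(12.0, 3.0), 2.0, 25.0))
            mean = hibma_mean_path(hib, y0, N_BINS, t_start=0)
            eps = rw_simulate(hib.rw, N_BINS, rng)
            y = mean + eps + rng.normal(0.0, hib.rw.tau_obs, N_BINS)
            nat = np.clip(np.round(y), 0, NSAA_MAX)
            for t in range(N_BINS):
                rows.append((pid, t + 1, "nsaa", float(nat[t])))
            continue
        if n_tr and variant.spec.treatments:
            for j in range(n_tr):
                treats[i, j, start_sampler(rng) - 1 :] = 1.0
        means = variant.mean_paths(params, treats[i])
        for k in variant.outcomes:
            disc = params.disc[k]
            if variant.spec.discrepancy == "RW":
                eps = rw_simulate(disc, N_BINS, rng)
                y = means[k] + eps + rng.normal(0.0, disc.tau_obs, N_BINS)
            else:
                K = sqexp_kernel(grid[:, None], grid[None, :], disc.rho, disc.ell)
                L = np.linalg.cholesky(K + 1e-9 * disc.rho**2 * np.eye(N_BINS))
                y = means[k] + L @ rng.standard_normal(N_BINS) + rng.normal(
                    0.0, disc.tau_obs, N_BINS)
            nat = np.asarray(normalizer.model_to_natural(k, y))
            if k == "nsaa":
                nat = np.clip(np.round(nat), 0, NSAA_MAX)
            for t in range(N_BINS):
                rows.append((pid, t + 1, k, float(nat[t])))
    full = pd.DataFrame(rows, columns=["patient_id", "time_bin", "outcome", "value"])
    return full, params_list, treats


def fit_missingness(cohort: Cohort, outcome: str = "nsaa") -> MissingnessModel:
    """Estimate the three-stage missingness model from training data."""
    df = cohort.data[cohort.data["outcome"] == outcome]
    if df.empty:
        raise ValueError("no observations to fit the missingness model")
    t0s, gaps = [], []
    model = MissingnessModel(np.zeros(0), np.zeros(0),
                             np.zeros((GRID_SIZE, GRID_SIZE)))
    points = np.zeros((GRID_SIZE, GRID_SIZE))
    lasts = np.zeros((GRID_SIZE, GRID_SIZE))
    for _, grp in df.groupby("patient_id"):
        bins = np.sort(grp["time_bin"].to_numpy(int))
        vals = grp.sort_values("time_bin")["value"].to_numpy(float)
        t0s.append(bins[0])
        gaps.extend(np.diff(bins).tolist())
        for b, v in zip(bins, vals):
            points[model.box(b, v)] += 1
        lasts[model.box(bins[-1], vals[-1])] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        prob = np.where(points > 0, lasts / np.maximum(points, 1), 0.0)
    gaps = [g for g in gaps if g >= 1] or [2]
    model.t0_values = np.asarray(t0s, int)
    model.interval_values = np.asarray(gaps, int)
    model.stop_prob = prob
    return model


def apply_missingness(
    full: pd.DataFrame,
    model: MissingnessModel,
    seed: int,
    outcome: str = "nsaa",
) -> pd.DataFrame:
    """Thin full trajectories to registry-like observation records.

    Per individual: sample t0 and a visit gap omega, keep bins in
    {t0 + n*omega}, scan retained points in time order flagging each as
    "last" by a Bernoulli draw with its grid-box probability (truncating
    the remainder on success), then drop all NSAA scores of zero.
    """
    rng = np.random.default_rng(seed)
    out = []
    df = full[full["outcome"] == outcome]
    for pid, grp in df.groupby("patient_id", sort=True):
        grp = grp.sort_values("time_bin")
        bins = grp["time_bin"].to_numpy(int)
        vals = grp["value"].to_numpy(float)
        t0 = int(rng.choice(model.t0_values))
        omega = int(rng.choice(model.interval_values))
        keep = (bins >= t0) & ((bins - t0) % omega == 0)
        bins, vals = bins[keep], vals[keep]
        for b, v in zip(bins, vals):
            out.append((pid, int(b), outcome, float(v)))
            if rng.random() < model.stop_prob[model.box(int(b), v)]:
                break
    obs = pd.DataFrame(out, columns=["patient_id", "time_bin", "outcome", "value"])
    if outcome == "nsaa":
        obs = obs[obs["value"] > 0].reset_index(drop=True)
    return obs


def generate_synthetic_cohort(
    source, variant, model: MissingnessModel, n: int, seed: int,
    normalizer: Normalizer | None = None,
) -> SyntheticCohort:
    """sample_trajectories + apply_missingness with a single seed."""
    child = np.random.SeedSequence(seed).spawn(2)
    full, _, _ = sample_trajectories(
        source, variant, n, child[0].generate_state(1)[0] % (2**31), normalizer)
    observed = apply_missingness(full, model, child[1].generate_state(1)[0] % (2**31))
    prov = "hyperparameters" if isinstance(source, PopulationHyperparams) else "posterior-mvn"
    return SyntheticCohort(full, observed, seed, prov)


def bootstrap_generate(
    source,
    variant: VariantModel,
    model: MissingnessModel,
    metric_fn,
    n: int = DEFAULT_N_TRAJECTORIES,
    reps: int = DEFAULT_BOOTSTRAP_REPS,
    seed: int = 0,
    normalizer: Normalizer | None = None,
):
    """Average a metric over repeated generate->thin->score replications.

    ``metric_fn`` maps an observed-records DataFrame to a dict of scalar
    metrics; returns (means dict, SDs dict).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    seeds = np.random.SeedSequence(seed).spawn(reps)
    acc = {}
    for r in range(reps):
        sc = generate_synthetic_cohort(
            source, variant, model, n, seeds[r].generate_state(1)[0] % (2**31),
            normalizer)
        for key, val in metric_fn(sc.observed).items():
            acc.setdefault(key, []).append(float(val))
    means = {k: float(np.mean(v)) for k, v in acc.items()}
    sds = {k: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0 for k, v in acc.items()}
    return means, sds
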