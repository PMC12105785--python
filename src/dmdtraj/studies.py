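"""Reduced-scale simulation studies exercising the full pipeline.

Each study simulates cohorts from the reference population
(:mod:`dmdtraj.populations`), runs the corresponding piece of the
modelling pipeline, and returns scalar summaries.  They are shared by the
analysis drivers, the test suite and the acceptance script.

Problem sizes (60-patient training cohorts, two chains of a few thousand
iterations, 50 calibration replicates) are the package's working scale:
large enough for the hierarchy to pool and for coverage statistics to be
meaningful, small enough to iterate on.
"""

from __future__ import annotations

import numpy as np

from .cohort_io import N_BINS
from .discrepancy import rw_simulate, sqexp_kernel
from .inference import (
    MCMCConfig,
    PopulationMVN,
    approximate_mvn,
    calibrate_individual,
    fit_population,
)
from .model_variants import PatientData, build_variant, sample_z
from .pipeline import RunConfig, evaluate_predictions, simulate_ground_truth
from .populations import default_population
from .synth_eval import evaluate_synthetic
from .synthetic_cohort import fit_missingness, generate_synthetic_cohort
from .transforms import Normalizer

#: population means whose recovery the studies report
RECOVERY_PARAMS = ("mu_alpha:nsaa", "mu_Delta", "mu_beta:nsaa")


def recovery_study(
    label: str,
    n_patients: int = 60,
    n_iter: int = 3000,
    data_seed: int = 3,
    fit_seed: int = 5,
) -> dict:
    """Simulate-from-known-hyperparameters, fit, and score CI coverage.

    Returns per-parameter posterior means, 95% credible intervals, truth,
    and coverage flags for the population means of alpha, Delta and beta.
    """
    variant = build_variant(label)
    cfg = RunConfig(model=label, n_patients=n_patients, master_seed=data_seed)
    cohort, _ = simulate_ground_truth(cfg)
    post = fit_population(
        cohort, variant, MCMCConfig(n_iter=n_iter, n_warmup=n_iter // 2),
        seed=fit_seed, normalizer=Normalizer.identity(variant.outcomes))
    pop = default_population(variant)
    truth = dict(zip([f"mu_{n}" for n in variant.layout.names], pop.mu))
    flat = post.flat_draws()
    out = {"label": label, "params": {}}
    for name in RECOVERY_PARAMS:
        j = post.param_names.index(name)
        lo, hi = np.quantile(flat[:, j], [0.025, 0.975])
        out["params"][name] = {
            "mean": float(flat[:, j].mean()),
            "q2.5": float(lo),
            "q97.5": float(hi),
            "truth": float(truth[name]),
            "covered": bool(lo <= truth[name] <= hi),
        }
    out["n_covered"] = sum(p["covered"] for p in out["params"].values())
    out["rhat_max"] = float(np.nanmax(list(post.rhat.values())))
    out["posterior"] = post
    return out


def simulate_patient(variant, pop, rng, min_points: int = 8, max_points: int = 15):
    """One self-simulated patient with a registry-like visit schedule."""
    z = sample_z(variant.layout, pop, rng, 1)[0]
    params = variant.z_to_params(z)
    means = variant.mean_paths(params, None)["nsaa"]
    disc = params.disc["nsaa"]
    if variant.spec.discrepancy == "RW":
        y = means + rw_simulate(disc, N_BINS, rng)
    else:
        grid = np.arange(1, N_BINS + 1, dtype=float)
        K = sqexp_kernel(grid[:, None], grid[None, :], disc.rho, disc.ell)
        y = means + np.linalg.cholesky(
            K + 1e-9 * disc.rho**2 * np.eye(N_BINS)) @ rng.standard_normal(N_BINS)
    y = y + rng.normal(0.0, disc.tau_obs, N_BINS)
    t0 = int(rng.integers(2, 15))
    om = int(rng.choice([1, 2]))
    n = int(rng.integers(min_points, max_points))
    bins = np.arange(t0, min(N_BINS + 1, t0 + om * n), om)
    pat = PatientData("sim", {"nsaa": (bins, y[bins - 1])},
                      {"nsaa": (bins, y[bins - 1])}, np.zeros((0, N_BINS)))
    return z, pat


def individual_coverage_study(
    label: str = "D",
    n_replicates: int = 50,
    seed: int = 2024,
    ci_level: float = 0.90,
    n_iter: int = 1600,
) -> dict:
    """Coverage of individual-parameter CIs after calibration with 7+ points."""
    variant = build_variant(label)
    pop = default_population(variant)
    mvn = PopulationMVN.from_population(
        variant, pop, Normalizer.identity(variant.outcomes), spread=0.02)
    rng = np.random.default_rng(seed)
    cfg = MCMCConfig(n_iter=n_iter, n_warmup=n_iter // 2)
    cover = []
    a = (1.0 - ci_level) / 2.0
    for r in range(n_replicates):
        z, pat = simulate_patient(variant, pop, rng)
        ipost = calibrate_individual(pat, mvn, cfg, seed=seed + 1000 + r, n_draws=400)
        lo = np.quantile(ipost.z_draws, a, axis=0)
        hi = np.quantile(ipost.z_draws, 1.0 - a, axis=0)
        cover.append((lo <= z) & (z <= hi))
    cover = np.asarray(cover)
    return {
        "label": label,
        "coverage": float(cover.mean()),
        "per_parameter": dict(zip(variant.layout.names,
                                  cover.mean(axis=0).tolist())),
        "n_replicates": n_replicates,
    }


def self_consistency_study(
    label: str = "D",
    n_patients: int = 50,
    master_seed: int = 9,
) -> dict:
    """Predictive calibration on self-simulated validation patients.

    The true population (as a tight MVN) plays the fitted posterior's role,
    so any miscalibration reflects the calibration/prediction machinery
    (plus NSAA discretization), not estimation error.
    """
    variant = build_variant(label)
    cfg = RunConfig(
        model=label, n_patients=n_patients, master_seed=master_seed,
        calibration_mcmc=MCMCConfig(n_iter=1600, n_warmup=800),
        n_predictive_draws=400)
    cohort, _ = simulate_ground_truth(cfg)
    mvn = PopulationMVN.from_population(
        variant, default_population(variant),
        Normalizer.identity(variant.outcomes), spread=0.02)
    metrics, qq, _ = evaluate_predictions(cohort, mvn, cfg)
    w = qq.set_index("level")["coverage"]
    return {
        "label": label,
        "sad": float(metrics["sad"]),
        "coverage_50": float(w[0.50]),
        "coverage_90": float(w[0.90]),
        "n_validation_points": int(metrics["n_validation_points"]),
        "widths": metrics["widths"],
        "qq": qq,
    }


def synthetic_quality_study(
    label: str = "D",
    n_patients: int = 80,
    seed: int = 31,
) -> dict:
    """KL and LC scores between two cohorts from the same population.

    Both the "real" cohort and the synthetic one come from the reference
    population, so good generation shows up as small KL and strongly
    negative LC.
    """
    variant = build_variant(label)
    pop = default_population(variant)
    cfg = RunConfig(model=label, n_patients=n_patients, master_seed=seed)
    cohort, _ = simulate_ground_truth(cfg)
    miss = fit_missingness(cohort)
    sc = generate_synthetic_cohort(pop, variant, miss, n_patients, seed=seed + 1)
    real = cohort.data[cohort.data["outcome"] == "nsaa"][
        ["patient_id", "time_bin", "value"]]
    res = evaluate_synthetic(
        real, sc.observed[["patient_id", "time_bin", "value"]], seed=seed + 2)
    res["label"] = label
    return res
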