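"""End-to-end orchestration of the simulate / fit / predict / synthesize flows.

A single master seed fans out to per-stage seeds through
``numpy.random.SeedSequence(master).spawn``; every stage records the seed
it used, so any pipeline run is reproducible from its config alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort_io import AGE_MIN, BIN_WIDTH, Cohort, make_cohort, split_cohort, write_cohort
from .inference import (
    MCMCConfig,
    PopulationMVN,
    approximate_mvn,
    calibrate_individual,
    fit_population,
    posterior_predictive,
    prepare_patients,
)
from .model_variants import PatientData, VariantSpec, build_variant
from .populations import default_population
from .prediction_eval import (
    assign_prediction_points,
    coverage_curve,
    mcid_width,
    mean_pi_width,
    sad_score,
)
from .synth_eval import evaluate_synthetic
from .synthetic_cohort import (
    fit_missingness,
    generate_synthetic_cohort,
    sample_trajectories,
)
from .transforms import Normalizer

_STAGES = ("simulate", "split", "fit", "calibrate", "synthesize", "eval")


@dataclass
class RunConfig:
    model: str = "D"
    outcomes: tuple = ("nsaa",)
    treatment_names: tuple = ()
    n_patients: int = 60
    validation_fraction: float = 0.3
    master_seed: int = 0
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    calibration_mcmc: MCMCConfig = field(
        default_factory=lambda: MCMCConfig(n_iter=1200, n_warmup=600))
    n_predictive_draws: int = 300
    pi_levels: tuple = (0.70, 0.95)
    n_synthetic: int = 60
    bootstrap_reps: int = 1

    def __post_init__(self):
        if not (0 < self.validation_fraction < 1):
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")
        VariantSpec.from_label(self.model)  # validates the label

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "mcmc" in raw:
            raw["mcmc"] = MCMCConfig(**raw["mcmc"])
        if "calibration_mcmc" in raw:
            raw["calibration_mcmc"] = MCMCConfig(**raw["calibration_mcmc"])
        for key in ("outcomes", "treatment_names", "pi_levels"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def stage_seed(self, stage: str) -> int:
        idx = _STAGES.index(stage)
        child = np.random.SeedSequence(self.master_seed).spawn(len(_STAGES))[idx]
        return int(child.generate_state(1)[0] % (2**31))


def simulate_ground_truth(config: RunConfig, out_dir=None):
    """Simulate a cohort from the reference population; optionally write
    cohort CSV + generating-parameter JSON.  Returns (Cohort, truth dict)."""
    variant = build_variant(config.model, config.outcomes, config.treatment_names)
    pop = default_population(variant)
    full, params, treats = sample_trajectories(
        pop, variant, config.n_patients, config.stage_seed("simulate"))
    obs = _thin_for_visits(full, config.stage_seed("simulate") + 1)
    obs["age_years"] = AGE_MIN + (obs["time_bin"] - 1) * BIN_WIDTH
    for j, name in enumerate(variant.treatment_names):
        pid_idx = {p: i for i, p in enumerate(sorted(full["patient_id"].unique()))}
        obs[f"treat_{name}"] = [
            int(treats[pid_idx[p], j, t - 1])
            for p, t in zip(obs["patient_id"], obs["time_bin"])
        ]
    cohort = make_cohort(obs, variant.treatment_names)
    truth = {
        "model": config.model,
        "outcomes": list(config.outcomes),
        "population_mu": dict(zip(variant.layout.names, pop.mu.tolist())),
        "population_sigma": {g: s for (g, _), s in zip(variant.layout.groups,
                                                       pop.sigma.tolist())},
        "seed": config.stage_seed("simulate"),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_cohort(cohort, out_dir / "cohort.csv")
        (out_dir / "true_parameters.json").write_text(json.dumps(truth, indent=2))
    return cohort, truth


def _thin_for_visits(full: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Registry-like visit schedule: start bin, ~6-month spacing, dropout."""
    rng = np.random.default_rng(seed)
    keep = []
    for pid, grp in full.groupby("patient_id", sort=True):
        t0 = int(rng.integers(2, 20))
        omega = int(rng.choice([1, 2, 3], p=[0.2, 0.6, 0.2]))
        duration = int(rng.integers(12, 56))
        bins = set(range(t0, min(70, t0 + duration), omega))
        sub = grp[grp["time_bin"].isin(bins)]
        sub = sub[~((sub["outcome"] == "nsaa") & (sub["value"] == 0))]
        keep.append(sub)
    return pd.concat(keep, ignore_index=True)


def evaluate_predictions(
    validation: Cohort,
    mvn: PopulationMVN,
    config: RunConfig,
    outcome: str = "nsaa",
):
    """Calibrate each validation patient and score coverage/width.

    Returns (metrics dict, per-level QQ DataFrame, summaries list).
    """
    variant = mvn.variant
    patients = prepare_patients(validation, variant, mvn.normalizer)
    patients = [p for p in patients if outcome in p.obs]
    split = assign_prediction_points(
        {p.patient_id: p.obs[outcome][0] for p in patients},
        config.stage_seed("calibrate"),
    )
    val_points, summaries = [], []
    for j, p in enumerate(patients):
        n_pred, pred_bins, val_bins = split[p.patient_id]
        mask = np.isin(p.obs[outcome][0], pred_bins)
        pred_patient = PatientData(
            p.patient_id,
            {outcome: (p.obs[outcome][0][mask], p.obs[outcome][1][mask])},
            {outcome: (p.raw[outcome][0][mask], p.raw[outcome][1][mask])},
            p.treat,
        )
        ipost = calibrate_individual(
            pred_patient, mvn, config.calibration_mcmc,
            seed=config.stage_seed("calibrate") + 17 * j + 1,
            n_draws=config.n_predictive_draws,
        )
        summary = posterior_predictive(
            ipost, seed=config.stage_seed("calibrate") + 17 * j + 2)
        summaries.append(summary)
        vmask = np.isin(p.raw[outcome][0], val_bins)
        for b, v in zip(p.raw[outcome][0][vmask], p.raw[outcome][1][vmask]):
            val_points.append((summary, outcome, int(b), float(v)))
    curve = coverage_curve(val_points)
    metrics = {
        "sad": sad_score(curve),
        "n_validation_points": curve.n_points,
        "widths": {
            f"{int(level * 100)}": {
                g: {"natural": w, "mcid": mcid_width(w) if outcome == "nsaa" else None}
                for g, w in mean_pi_width(summaries, outcome, level).items()
            }
            for level in config.pi_levels
        },
    }
    qq = pd.DataFrame({"level": curve.levels, "coverage": curve.W})
    return metrics, qq, summaries


def run_pipeline(config: RunConfig, out_dir=None, synthesize: bool = True) -> dict:
    """simulate -> split -> fit -> calibrate/evaluate (-> synthesize -> score)."""
    artifacts = {}
    cohort, truth = simulate_ground_truth(config, out_dir)
    train, valid = split_cohort(cohort, config.validation_fraction,
                                config.stage_seed("split"))
    artifacts["truth"] = truth

    variant = build_variant(config.model, config.outcomes, config.treatment_names)
    posterior = fit_population(train, variant, config.mcmc,
                               seed=config.stage_seed("fit"))
    artifacts["rhat_max"] = float(np.nanmax(list(posterior.rhat.values())))
    mvn = approximate_mvn(posterior)

    metrics, qq, _ = evaluate_predictions(valid, mvn, config)
    artifacts["prediction"] = metrics

    if synthesize:
        miss = fit_missingness(train)
        sc = generate_synthetic_cohort(
            mvn, variant, miss, config.n_synthetic, config.stage_seed("synthesize"),
            normalizer=mvn.normalizer)
        real_df = valid.data[valid.data["outcome"] == "nsaa"][
            ["patient_id", "time_bin", "value"]]
        artifacts["synthetic"] = evaluate_synthetic(
            real_df, sc.observed[["patient_id", "time_bin", "value"]],
            seed=config.stage_seed("eval"))

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        qq.to_csv(out_dir / "qq_curve.csv", index=False)
        (out_dir / "metrics.json").write_text(json.dumps(artifacts, indent=2))
    return artifacts
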