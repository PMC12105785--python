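"""Personalized prediction evaluation on the held-out patients.

Each validation patient's first 20-80% of visits calibrate their
individual model; the remaining visits score the predictions.  Writes the
quantile-coverage (QQ) curve, the SAD score and the group-averaged 70/95%
interval widths in NSAA points and MCID multiples.
"""

import json
from pathlib import Path

import numpy as np

from dmdtraj.cohort_io import read_cohort
from dmdtraj.inference import MCMCConfig, PopulationMVN
from dmdtraj.model_variants import build_variant
from dmdtraj.pipeline import RunConfig, evaluate_predictions
from dmdtraj.transforms import Normalizer

OUT = Path(__file__).resolve().parents[1] / "results"

config = RunConfig(model="D", n_patients=60, master_seed=3,
                   calibration_mcmc=MCMCConfig(n_iter=1600, n_warmup=800),
                   n_predictive_draws=400)


def load_mvn():
    meta = json.loads((OUT / "population_meta.json").read_text())
    data = np.load(OUT / "population_mvn.npz")
    variant = build_variant(meta["model"])
    return PopulationMVN(variant, Normalizer.from_json(meta["normalizer"]),
                         data["mean"], data["cov"],
                         list(data["names"])), meta


if __name__ == "__main__":
    mvn, meta = load_mvn()
    cohort = read_cohort(OUT / "cohort.csv")
    valid = cohort.subset(meta["validation_patients"])
    metrics, qq, _ = evaluate_predictions(valid, mvn, config)
    qq.to_csv(OUT / "qq_curve.csv", index=False)
    (OUT / "prediction_metrics.json").write_text(json.dumps(metrics, indent=2))
    print(f"{valid.n_patients} validation patients, "
          f"{metrics['n_validation_points']} pooled validation points")
    print(f"SAD = {metrics['sad']:.2f} (0 = perfectly calibrated)")
    for level, groups in metrics["widths"].items():
        row = ", ".join(
            f"{g}: {d['natural']:.1f} NSAA ({d['mcid']:.2f} MCID)"
            for g, d in groups.items())
        print(f"{level}% PI width by prediction-point group -> {row}")
    print(f"wrote {OUT/'qq_curve.csv'} and {OUT/'prediction_metrics.json'}")
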