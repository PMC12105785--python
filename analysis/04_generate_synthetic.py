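"""Generate a synthetic cohort from the fitted population posterior.

Samples trajectories from the MVN posterior approximation, emulates the
training data's missingness (first-visit times, visit spacing, grid-based
informative stopping, zero-score removal) and writes the synthetic
observation records.
"""

from pathlib import Path

from dmdtraj.cohort_io import read_cohort
from dmdtraj.pipeline import RunConfig
from dmdtraj.synthetic_cohort import fit_missingness, generate_synthetic_cohort

import importlib.util as _ilu

_spec = _ilu.spec_from_file_location(
    "eval_preds", Path(__file__).with_name("03_evaluate_predictions.py"))
_mod = _ilu.module_from_spec(_spec)
_spec.loader.exec_module(_mod)
load_mvn = _mod.load_mvn

OUT = Path(__file__).resolve().parents[1] / "results"

config = RunConfig(model="D", n_patients=60, master_seed=3, n_synthetic=60)

if __name__ == "__main__":
    mvn, meta = load_mvn()
    cohort = read_cohort(OUT / "cohort.csv")
    train = cohort.subset(
        [p for p in cohort.patients if p not in set(meta["validation_patients"])])
    miss = fit_missingness(train)
    sc = generate_synthetic_cohort(mvn, mvn.variant, miss, config.n_synthetic,
                                   config.stage_seed("synthesize"),
                                   normalizer=mvn.normalizer)
    sc.observed.to_csv(OUT / "synthetic.csv", index=False)
    per = sc.observed.groupby("patient_id").size()
    print(f"synthesized {per.size} individuals, {len(sc.observed)} records "
          f"({per.min()}-{per.max()} per individual) from the {sc.provenance}")
    print(f"wrote {OUT/'synthetic.csv'}")
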