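"""Longitudinal cohort I/O on the quarter-year time grid.

Clinical visits are binned into 69 three-month periods covering ages 3 to
20.25 years.  A cohort is a long-format table with one row per
(patient, time bin, outcome) measurement; outcomes are the NSAA total score
(integer 0-34), the 10-m walk time and the rise-from-floor (RFF) time (both
positive seconds).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: number of quarter-year bins between ages 3 and 20.25
N_BINS = 69
AGE_MIN = 3.0
AGE_MAX = 20.25
BIN_WIDTH = 0.25

#: canonical outcome order; k = 1, 2, 3 in the model
OUTCOMES = ("nsaa", "walk", "rff")

NSAA_MAX = 34

_REQUIRED_COLUMNS = ("patient_id", "age_years", "outcome", "value")


class CohortValidationError(ValueError):
    """Raised when a cohort table violates the schema or value ranges."""


def bin_age(age_years: float) -> int:
    """Map an age in years to its quarter-year time bin in {1..69}.

    Bins are half-open: bin t covers [3 + 0.25(t-1), 3 + 0.25 t).
    """
    if not (AGE_MIN <= age_years < AGE_MAX):
        raise ValueError(
            f"age {age_years!r} outside the admissible window "
            f"[{AGE_MIN}, {AGE_MAX}) years"
        )
    return int(math.floor((age_years - AGE_MIN) / BIN_WIDTH)) + 1


def bin_midpoint_age(time_bin: int | np.ndarray) -> float | np.ndarray:
    """Age in years at the centre of a time bin."""
    return AGE_MIN + (np.asarray(time_bin) - 0.5) * BIN_WIDTH


@dataclass
class Cohort:
    """A validated long-format collection of observations.

    ``data`` columns: patient_id (str), age_years (float), time_bin (int),
    outcome (str in OUTCOMES), value (float), plus zero or more binary
    ``treat_<name>`` columns.
    """

    data: pd.DataFrame
    treatment_names: tuple[str, ...] = field(default_factory=tuple)

    @property
    def patients(self) -> list[str]:
        return sorted(self.data["patient_id"].unique().tolist())

    @property
    def n_patients(self) -> int:
        return self.data["patient_id"].nunique()

    def counts_by_outcome(self) -> dict[str, int]:
        c = self.data["outcome"].value_counts()
        return {k: int(c.get(k, 0)) for k in OUTCOMES}

    def for_patient(self, patient_id: str) -> pd.DataFrame:
        return self.data[self.data["patient_id"] == patient_id]

    def subset(self, patient_ids) -> "Cohort":
        ids = set(patient_ids)
        return Cohort(
            self.data[self.data["patient_id"].isin(ids)].reset_index(drop=True),
            self.treatment_names,
        )


def _validate(df: pd.DataFrame, treatment_names: tuple[str, ...]) -> pd.DataFrame:
    bad_outcome = ~df["outcome"].isin(OUTCOMES)
    if bad_outcome.any():
        rows = df.index[bad_outcome].tolist()[:5]
        raise CohortValidationError(f"unknown outcome in rows {rows}")

    problems = []
    for idx, row in df.iterrows():
        v = row["value"]
        if not np.isfinite(v):
            problems.append((idx, "non-finite value"))
        elif row["outcome"] == "nsaa":
            if v != int(v) or not (0 <= v <= NSAA_MAX):
                problems.append((idx, f"NSAA value {v} not an integer in [0, {NSAA_MAX}]"))
        elif v <= 0:
            problems.append((idx, f"{row['outcome']} time {v} not strictly positive"))
    if problems:
        msg = "; ".join(f"row {i}: {m}" for i, m in problems[:10])
        raise CohortValidationError(f"invalid values: {msg}")

    # age -> bin consistency and range
    try:
        bins = df["age_years"].map(bin_age)
    except ValueError as exc:
        raise CohortValidationError(str(exc)) from exc
    if "time_bin" in df.columns:
        mismatch = df["time_bin"].astype(int) != bins
        if mismatch.any():
            rows = df.index[mismatch].tolist()[:5]
            raise CohortValidationError(f"time_bin inconsistent with age in rows {rows}")
    df = df.copy()
    df["time_bin"] = bins.astype(int)

    dup = df.duplicated(subset=["patient_id", "time_bin", "outcome"], keep=False)
    if dup.any():
        rows = df.index[dup].tolist()[:10]
        raise CohortValidationError(
            f"duplicate (patient, time_bin, outcome) rows: {rows}"
        )

    for name in treatment_names:
        col = f"treat_{name}"
        if col not in df.columns:
            raise CohortValidationError(f"missing treatment column {col}")
        if not df[col].isin([0, 1]).all():
            raise CohortValidationError(f"treatment column {col} must be binary")
    return df


def make_cohort(df: pd.DataFrame, treatment_names=()) -> Cohort:
    """Validate a raw long-format DataFrame into a Cohort."""
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"missing required columns: {missing}")
    df = df.copy()
    df["patient_id"] = df["patient_id"].astype(str)
    df["age_years"] = df["age_years"].astype(float)
    df["value"] = df["value"].astype(float)
    df = _validate(df, tuple(treatment_names))
    order = ["patient_id", "age_years", "time_bin", "outcome", "value"] + [
        f"treat_{n}" for n in treatment_names
    ]
    return Cohort(df[order].reset_index(drop=True), tuple(treatment_names))


def read_cohort(path, treatment_names=()) -> Cohort:
    """Read and validate a cohort CSV (comma-separated, '.' decimal, header)."""
    df = pd.read_csv(path)
    return make_cohort(df, treatment_names)


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort in the same CSV dialect ``read_cohort`` expects."""
    cohort.data.to_csv(path, index=False)


def split_cohort(cohort: Cohort, validation_fraction: float, seed: int):
    """Split a cohort into (training, validation) by patient.

    Exactly ``round(n_patients * validation_fraction)`` patients are set
    aside, mirroring the roughly 30% validation hold-out used throughout;
    the split is deterministic given the seed.
    """
    if not (0.0 < validation_fraction < 1.0):
        raise ValueError("validation_fraction must be in (0, 1)")
    patients = cohort.patients
    n_val = int(round(len(patients) * validation_fraction))
    rng = np.random.default_rng(seed)
    val_ids = set(rng.choice(patients, size=n_val, replace=False).tolist())
    train_ids = [p for p in patients if p not in val_ids]
    return cohort.subset(train_ids), cohort.subset(sorted(val_ids))
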