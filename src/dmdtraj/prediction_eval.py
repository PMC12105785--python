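"""Prediction-quality evaluation: coverage curves, SAD, interval widths.

Each validation patient's first 20-80% of points (percentage drawn
uniformly, count rounded down) become prediction points used for
calibration; the remainder are validation points.  Calibration quality is
read off the quantile-coverage curve W_i (proportion of validation points
inside the central i-level prediction interval, i = 0.01..0.99) and its
sum of absolute deviations from the nominal levels (SAD; 0 = perfect).
Sharpness is the time-averaged central-interval width per individual,
grouped by how many prediction points the model saw, reported in NSAA
points and in multiples of the minimum clinically important difference
(MCID = 3.5 NSAA points).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

MCID_NSAA = 3.5

#: coverage levels for the QQ/SAD evaluation
LEVELS = np.round(np.arange(0.01, 1.0, 0.01), 2)

#: prediction-point-count groups: 0, 1-3, 4-6, 7+
POINT_GROUPS = ((0, 0), (1, 3), (4, 6), (7, math.inf))


def select_prediction_points(n_points: int, percentage: float) -> int:
    """floor(percentage * n_points); the first that-many points (by time)
    are prediction points, the rest validation."""
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if not (0.20 <= percentage <= 0.80):
        raise ValueError("percentage must be in [0.20, 0.80]")
    return int(math.floor(percentage * n_points))


def group_label(n_prediction_points: int) -> str:
    for lo, hi in POINT_GROUPS:
        if lo <= n_prediction_points <= hi:
            return f"{lo}" if lo == hi else (f"{lo}-{hi}" if math.isfinite(hi) else f"{lo}+")
    raise ValueError("negative point count")


@dataclass
class CoverageCurve:
    levels: np.ndarray
    W: np.ndarray
    n_points: int

    def __post_init__(self):
        if np.any((self.W < 0) | (self.W > 1)):
            raise ValueError("coverage proportions must lie in [0, 1]")


def coverage_curve(validation_points, levels=LEVELS) -> CoverageCurve:
    """Empirical coverage of central PIs, pooled over validation points.

    ``validation_points`` is an iterable of (PredictiveSummary, outcome,
    time_bin, observed_value) tuples.
    """
    validation_points = list(validation_points)
    if not validation_points:
        raise ValueError("empty validation set")
    levels = np.asarray(levels, dtype=float)
    inside = np.zeros(len(levels))
    for summary, outcome, time_bin, value in validation_points:
        col = summary.draws[outcome][:, time_bin - 1]
        col = col[np.isfinite(col)]
        los = np.quantile(col, 0.5 - levels / 2.0)
        his = np.quantile(col, 0.5 + levels / 2.0)
        if outcome == "nsaa":
            los, his = np.clip(los, 0.0, 34.0), np.clip(his, 0.0, 34.0)
        inside += (los <= value) & (value <= his)
    return CoverageCurve(levels, inside / len(validation_points), len(validation_points))


def sad_score(curve: CoverageCurve) -> float:
    """Sum over levels of |nominal - empirical coverage|; lower is better."""
    return float(np.sum(np.abs(curve.levels - curve.W)))


def sad_score_normalized(curve: CoverageCurve) -> float:
    """SAD divided by the number of levels (optional normalization)."""
    return sad_score(curve) / len(curve.levels)


def mean_pi_width(summaries, outcome: str = "nsaa", level: float = 0.70) -> dict:
    """Group-averaged, time-averaged central-PI widths on the natural scale.

    ``summaries`` is an iterable of PredictiveSummary (each carrying its
    ``n_prediction_points``).  Groups with no individuals are absent from
    the result rather than reported as zero.
    """
    widths = {}
    for s in summaries:
        lo, hi = s.pi_bounds(outcome, level)
        w = float(np.nanmean(hi - lo))
        widths.setdefault(group_label(s.n_prediction_points), []).append(w)
    return {g: float(np.mean(v)) for g, v in sorted(widths.items())}


def mcid_width(nsaa_width: float) -> float:
    """NSAA-point width expressed in multiples of the MCID (3.5 points)."""
    if nsaa_width < 0:
        raise ValueError("width must be non-negative")
    return nsaa_width / MCID_NSAA


def assign_prediction_points(patient_bins, seed: int, lo: float = 0.20, hi: float = 0.80):
    """Draw a per-patient percentage in [lo, hi] and split points by time.

    ``patient_bins`` maps patient id -> sorted observation bins; returns
    patient id -> (n_prediction_points, prediction bins, validation bins).
    """
    rng = np.random.default_rng(seed)
    out = {}
    for pid in sorted(patient_bins):
        bins = np.sort(np.asarray(patient_bins[pid]))
        pct = rng.uniform(lo, hi)
        n_pred = select_prediction_points(len(bins), pct)
        out[pid] = (n_pred, bins[:n_pred], bins[n_pred:])
    return out
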