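"""Outcome transforms between the natural and unconstrained model scales.

NSAA scores (integers 0-34) go through a shifted logit so that model
predictions back-transform into the valid score range; positive times
(10-m walk, rise-from-floor) go through the inverse-softplus so that
back-transformed predictions are always positive.  After transformation,
each outcome is z-scored with constants estimated once on the training
cohort, so every outcome lives on a comparable scale during fitting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .cohort_io import NSAA_MAX, OUTCOMES

_NSAA_CELLS = NSAA_MAX + 1  # 35


def nsaa_to_latent(score):
    """logit((score + 0.5) / 35); strictly increasing on {0..34}."""
    s = np.asarray(score, dtype=float)
    if np.any((s < 0) | (s > NSAA_MAX) | (s != np.round(s))):
        raise ValueError(f"NSAA score must be an integer in [0, {NSAA_MAX}]")
    p = (s + 0.5) / _NSAA_CELLS
    out = np.log(p / (1.0 - p))
    return out.item() if np.isscalar(score) else out


def nsaa_to_latent_continuous(score):
    """Same logit map without the integer check (for continuous draws)."""
    s = np.clip(np.asarray(score, dtype=float), 0.0, NSAA_MAX)
    p = (s + 0.5) / _NSAA_CELLS
    return np.log(p / (1.0 - p))


def latent_to_nsaa(z):
    """Inverse of :func:`nsaa_to_latent`: integer score clamped to {0..34}."""
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("latent value must be finite")
    s = np.round(latent_to_nsaa_continuous(z))
    s = np.clip(s, 0, NSAA_MAX).astype(int)
    return s.item() if s.ndim == 0 else s


def latent_to_nsaa_continuous(z):
    """Continuous-score inverse logit, in (-0.5, 34.5), clipped to [0, 34]."""
    z = np.asarray(z, dtype=float)
    p = 1.0 / (1.0 + np.exp(-z))
    return np.clip(p * _NSAA_CELLS - 0.5, 0.0, NSAA_MAX)


def softplus(z):
    """Overflow-safe log(1 + exp(z))."""
    z = np.asarray(z, dtype=float)
    out = np.logaddexp(0.0, z)
    return out.item() if out.ndim == 0 else out


def postime_to_latent(seconds):
    """Inverse softplus log(exp(x) - 1), mapping positive times to the reals."""
    x = np.asarray(seconds, dtype=float)
    if np.any(x <= 0):
        raise ValueError("time must be strictly positive")
    # log(exp(x)-1) = x + log1p(-exp(-x)), stable for large x
    out = x + np.log1p(-np.exp(-x))
    return out.item() if out.ndim == 0 else out


def latent_to_postime(z):
    """softplus(z): back-transform to a positive time in seconds."""
    return softplus(z)


_FORWARD = {
    "nsaa": nsaa_to_latent,
    "walk": postime_to_latent,
    "rff": postime_to_latent,
}
_BACKWARD = {
    "nsaa": latent_to_nsaa_continuous,
    "walk": latent_to_postime,
    "rff": latent_to_postime,
}


def to_latent(outcome: str, value):
    return _FORWARD[outcome](value)


def from_latent(outcome: str, z):
    """Back-transform to the natural scale (NSAA kept continuous in [0, 34])."""
    return _BACKWARD[outcome](z)


@dataclass
class Normalizer:
    """Per-outcome z-scoring constants estimated on transformed training data."""

    mean: dict = field(default_factory=dict)
    sd: dict = field(default_factory=dict)

    @classmethod
    def identity(cls, outcomes=OUTCOMES) -> "Normalizer":
        return cls({k: 0.0 for k in outcomes}, {k: 1.0 for k in outcomes})

    @classmethod
    def fit(cls, cohort) -> "Normalizer":
        """Estimate mean/sd per outcome from a training Cohort (natural scale)."""
        mean, sd = {}, {}
        for outcome, grp in cohort.data.groupby("outcome"):
            z = to_latent(outcome, grp["value"].to_numpy())
            z = np.atleast_1d(z)
            if len(np.unique(z)) < 2:
                raise ValueError(f"outcome {outcome}: zero variance in training data")
            mean[outcome] = float(np.mean(z))
            s = float(np.std(z, ddof=1))
            if s <= 0:
                raise ValueError(f"outcome {outcome}: zero variance in training data")
            sd[outcome] = s
        return cls(mean, sd)

    def apply(self, outcome: str, z):
        return (np.asarray(z, dtype=float) - self.mean[outcome]) / self.sd[outcome]

    def invert(self, outcome: str, u):
        return np.asarray(u, dtype=float) * self.sd[outcome] + self.mean[outcome]

    def natural_to_model(self, outcome: str, value):
        """Transform + normalize a natural-scale value onto the model scale."""
        return self.apply(outcome, to_latent(outcome, value))

    def model_to_natural(self, outcome: str, u):
        """Invert normalization then back-transform to the natural scale."""
        return from_latent(outcome, self.invert(outcome, u))

    def to_json(self) -> str:
        return json.dumps({"mean": self.mean, "sd": self.sd})

    @classmethod
    def from_json(cls, s: str) -> "Normalizer":
        d = json.loads(s)
        return cls(dict(d["mean"]), dict(d["sd"]))
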