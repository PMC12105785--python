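"""Reference population hyperparameters for the ground-truth simulator.

The proprietary clinical registry behind the original analysis is not
available, so recovery tests, self-consistency checks and the worked
pipeline all run on cohorts simulated from an explicit population.  The
values below are chosen once to give clinically plausible trajectories:
NSAA rising from roughly 8-10 at age 3 to a high-20s plateau, disease
onset biting around ages 8-11, decline toward single-digit scores by the
late teens, walk/rise-from-floor times of a few seconds that lengthen as
the disease progresses.  All values are on the link scale of the model
(logit for alpha, log for positive parameters, softplus for treatment
effects).
"""

from __future__ import annotations

import math

import numpy as np

from .model_variants import PopulationHyperparams, VariantModel

#: (mu, sigma) on the link scale per parameter family; ":k" suffixes resolve
#: per outcome.
_DEFAULTS = {
    "alpha:nsaa": (3.0, 0.4),
    "alpha:walk": (3.0, 0.4),
    "alpha:rff": (3.0, 0.4),
    "theta0:nsaa": (-1.2, 0.4),
    "theta0:walk": (6.0, 0.5),
    "theta0:rff": (5.0, 0.5),
    "theta_mat:nsaa": (2.6, 0.5),
    "theta_mat:walk": (4.0, 0.5),
    "theta_mat:rff": (3.0, 0.5),
    "beta:nsaa": (1.0, 0.25),
    "beta:walk": (-0.5, 0.15),
    "beta:rff": (-0.8, 0.2),
    "Delta": (math.log(0.12), 0.3),
    "t_onset": (24.0, 6.0),
    "tau_obs:nsaa": (math.log(0.18), 0.3),
    "tau_obs:walk": (math.log(0.20), 0.3),
    "tau_obs:rff": (math.log(0.20), 0.3),
    "tau_innov:nsaa": (math.log(0.05), 0.4),
    "tau_innov:walk": (math.log(0.05), 0.4),
    "tau_innov:rff": (math.log(0.05), 0.4),
    "eps0:nsaa": (0.0, 0.1),
    "eps0:walk": (0.0, 0.1),
    "eps0:rff": (0.0, 0.1),
    "rho:nsaa": (math.log(0.30), 0.3),
    "rho:walk": (math.log(0.30), 0.3),
    "rho:rff": (math.log(0.30), 0.3),
    "ell:nsaa": (math.log(6.0), 0.25),
    "ell:walk": (math.log(6.0), 0.25),
    "ell:rff": (math.log(6.0), 0.25),
    # softplus(-3) ~ 0.049: steroids slow the per-bin progression increment
    # by a bit under half of the typical Delta ~ 0.12
    "gamma:steroid": (-3.0, 0.7),
    # Hibma baseline (raw NSAA scale)
    "phi_prod": (0.5, 0.15),
    "xi": (8e-4, 3e-4),
    "tau_obs": (math.log(1.2), 0.3),
    "tau_innov": (math.log(0.4), 0.3),
    "eps0": (0.0, 0.3),
}

#: cross-outcome correlation used for covaried families in covariate variants
_DEFAULT_CORR = 0.5


def default_population(variant: VariantModel) -> PopulationHyperparams:
    """Reference PopulationHyperparams matching a variant's layout."""
    layout = variant.layout
    mu = np.empty(layout.n_coords)
    coord_sigma = np.empty(layout.n_coords)
    for j, name in enumerate(layout.names):
        base = name if name in _DEFAULTS else name.split(":")[0]
        if name.startswith("gamma:") and name not in _DEFAULTS:
            base = "gamma:steroid"
        m, s = _DEFAULTS[base] if base in _DEFAULTS else _DEFAULTS[name]
        mu[j], coord_sigma[j] = m, s
    sigma = np.empty(layout.n_groups)
    for g, (_, idx) in enumerate(layout.groups):
        sigma[g] = float(np.mean(coord_sigma[idx]))
    corr = {}
    for fam, idx in layout.cov_families.items():
        K = len(idx)
        C = np.full((K, K), _DEFAULT_CORR)
        np.fill_diagonal(C, 1.0)
        corr[fam] = C
    return PopulationHyperparams(mu, sigma, corr)
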