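"""Synthetic-cohort quality scores: 2-D KDE KL divergence and LC mixing.

Point-cloud similarity between a synthetic and a real (validation) cohort
is scored by the Kullback-Leibler divergence between product-Gaussian
kernel density estimates evaluated on the integer grid
{1..34} (NSAA) x {1..69} (time bin); the NSAA axis starts at 1 because
zero scores do not occur after the zero-removal step.  Bandwidths follow
the classic normal-reference convention of the standard 2-D KDE routine
(kernel SD per axis = 1.06 * min(sd, IQR/1.34) * n^{-1/5}).

Latent-structure similarity is scored by clustering real and synthetic
individuals together with a 4-class latent-class mixed model (class-
specific quadratic age trajectories, shared random intercept, EM with
restarts) and taking the log mean squared deviation of per-cluster real
fractions from the overall real fraction (the LC score; more negative =
better mixing).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .cohort_io import N_BINS, NSAA_MAX

DENSITY_FLOOR = 1e-12
LC_FLOOR = 1e-12
DEFAULT_N_CLASSES = 4

#: evaluation grid: NSAA rows 1..34, time-bin columns 1..69
NSAA_GRID = np.arange(1, NSAA_MAX + 1)
TIME_GRID = np.arange(1, N_BINS + 1)


@dataclass
class GridDensity:
    mass: np.ndarray  # (34, 69), non-negative, sums to 1

    def __post_init__(self):
        if self.mass.shape != (len(NSAA_GRID), len(TIME_GRID)):
            raise ValueError("density grid must be 34 x 69")
        if np.any(self.mass < 0) or not math.isclose(float(self.mass.sum()), 1.0,
                                                     rel_tol=1e-8):
            raise ValueError("density must be non-negative and sum to 1")


def nrd_bandwidth(x: np.ndarray) -> float:
    """Normal-reference kernel SD: 1.06 * min(sd, IQR/1.34) * n^{-1/5}."""
    x = np.asarray(x, dtype=float)
    sd = float(np.std(x, ddof=1))
    q1, q3 = np.quantile(x, [0.25, 0.75])
    spread = min(sd, (q3 - q1) / 1.34) if q3 > q1 else sd
    if spread <= 0:
        raise ValueError("degenerate spread: bandwidth would be zero")
    return 1.06 * spread * len(x) ** (-0.2)


def kde2d_density(points, floor: float = DENSITY_FLOOR) -> GridDensity:
    """Product-Gaussian KDE of (time_bin, NSAA) points on the 34x69 grid."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("need >= 2 (time_bin, NSAA) points")
    t, s = pts[:, 0], pts[:, 1]
    ht, hs = nrd_bandwidth(t), nrd_bandwidth(s)
    # (34, n) and (69, n) kernel factors; outer product summed over points
    ks = np.exp(-0.5 * ((NSAA_GRID[:, None] - s[None, :]) / hs) ** 2)
    kt = np.exp(-0.5 * ((TIME_GRID[:, None] - t[None, :]) / ht) ** 2)
    mass = ks @ kt.T / (2 * math.pi * hs * ht * len(pts))
    mass = np.maximum(mass, floor)
    return GridDensity(mass / mass.sum())


def kl_divergence(P: GridDensity, Q: GridDensity) -> float:
    """KL(P || Q) = sum P log(P/Q) over the grid; P synthetic, Q real."""
    if P.mass.shape != Q.mass.shape:
        raise ValueError("density grids do not match")
    return float(np.sum(P.mass * np.log(P.mass / Q.mass)))


def density_from_records(df: pd.DataFrame) -> GridDensity:
    """KDE density of NSAA observation records (time_bin, value columns)."""
    pts = df[["time_bin", "value"]].to_numpy(float)
    return kde2d_density(pts)


# --------------------------------------------------------------------------
# latent-class mixed model


@dataclass
class ClusterAssignment:
    table: pd.DataFrame  # columns: patient_id, source, cluster
    converged: bool = True
    loglik: float = float("nan")
    class_means: np.ndarray | None = None

    def counts(self):
        return self.table.groupby("cluster").agg(
            n=("patient_id", "size"),
            n_real=("source", lambda s: int((s == "real").sum())),
        )


def _pack_patients(df: pd.DataFrame):
    """Design matrices per patient: quadratic in the (standardized) bin."""
    out = []
    for (pid, src), grp in df.groupby(["patient_id", "source"], sort=True):
        t = grp["time_bin"].to_numpy(float)
        a = (t - N_BINS / 2.0) / (N_BINS / 4.0)
        X = np.column_stack([np.ones_like(a), a, a**2])
        out.append((pid, src, X, grp["value"].to_numpy(float)))
    return out


def _patient_loglik(X, y, gamma, s2, sb2):
    """Marginal N(X gamma, s2 I + sb2 J) log-density via Woodbury."""
    n = len(y)
    r = y - X @ gamma
    denom = s2 + n * sb2
    quad = (r @ r) / s2 - sb2 * (r.sum() ** 2) / (s2 * denom)
    logdet = (n - 1) * math.log(s2) + math.log(denom)
    return -0.5 * (quad + logdet + n * math.log(2 * math.pi))


def latent_class_fit(
    df: pd.DataFrame,
    n_classes: int = DEFAULT_N_CLASSES,
    seed: int = 0,
    n_restarts: int = 3,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> ClusterAssignment:
    """EM fit of a latent-class quadratic-trajectory model; MAP assignment.

    ``df`` needs columns patient_id, source ('real'/'synthetic'), time_bin,
    value, with >= 1 NSAA observation per individual.
    """
    patients = _pack_patients(df)
    if not patients:
        raise ValueError("no individuals to cluster")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, n_restarts)):
        res = _em_once(patients, n_classes, rng, max_iter, tol)
        if best is None or res[0] > best[0]:
            best = res
    ll, resp, gammas, converged = best
    cluster = resp.argmax(axis=1) + 1
    table = pd.DataFrame({
        "patient_id": [p[0] for p in patients],
        "source": [p[1] for p in patients],
        "cluster": cluster,
    })
    return ClusterAssignment(table, converged, ll, gammas)


def _em_once(patients, G, rng, max_iter, tol):
    n = len(patients)
    # initialize classes from quantiles of per-patient mean values + jitter
    means = np.array([y.mean() for _, _, _, y in patients])
    order = np.argsort(means + 0.1 * rng.standard_normal(n))
    labels = np.floor(np.linspace(0, G - 1e-9, n)).astype(int)[np.argsort(order)]
    resp = np.zeros((n, G))
    resp[np.arange(n), labels] = 1.0
    pi = np.full(G, 1.0 / G)
    s2, sb2 = np.var(np.concatenate([y for *_, y in patients])) * 0.5 + 1e-3, 1.0
    gammas = np.zeros((G, 3))
    prev_ll, converged = -np.inf, False
    for _ in range(max_iter):
        # M-step: weighted GLS per class under compound-symmetry covariance
        for g in range(G):
            A = np.zeros((3, 3))
            b = np.zeros(3)
            for (_, _, X, y), w in zip(patients, resp[:, g]):
                if w < 1e-12:
                    continue
                m = len(y)
                shrink = sb2 / (s2 + m * sb2)
                XtVi = (X.T - shrink * np.outer(X.sum(axis=0), np.ones(m))) / s2
                A += w * XtVi @ X
                b += w * XtVi @ y
            gammas[g] = np.linalg.solve(A + 1e-8 * np.eye(3), b)
        # variance components: profile the expected log-likelihood
        def nll(logv):
            v, vb = math.exp(logv[0]), math.exp(logv[1])
            tot = 0.0
            for (_, _, X, y), w in zip(patients, resp):
                for g in range(G):
                    if w[g] > 1e-12:
                        tot += w[g] * _patient_loglik(X, y, gammas[g], v, vb)
            return -tot
        opt = minimize(nll, [math.log(s2), math.log(sb2)], method="Nelder-Mead",
                       options={"maxiter": 60, "xatol": 1e-3, "fatol": 1e-4})
        s2, sb2 = math.exp(opt.x[0]), math.exp(opt.x[1])
        pi = np.maximum(resp.mean(axis=0), 1e-8)
        pi = pi / pi.sum()
        # E-step
        logp = np.empty((n, G))
        for i, (_, _, X, y) in enumerate(patients):
            for g in range(G):
                logp[i, g] = math.log(pi[g]) + _patient_loglik(X, y, gammas[g], s2, sb2)
        lse = logsumexp(logp, axis=1)
        resp = np.exp(logp - lse[:, None])
        ll = float(lse.sum())
        if abs(ll - prev_ll) < tol * max(1.0, abs(ll)):
            converged = True
            break
        prev_ll = ll
    return ll, resp, gammas, converged


def lc_score(assignment: ClusterAssignment, floor: float = LC_FLOOR):
    """log of the mean squared deviation of per-cluster real fractions
    from the overall real fraction; (score, perfect_mixing_flag)."""
    tab = assignment.table
    n_real = int((tab["source"] == "real").sum())
    n_synth = len(tab) - n_real
    if n_real == 0 or n_synth == 0:
        raise ValueError("need both real and synthetic individuals")
    c = n_real / (n_real + n_synth)
    devs = []
    for _, row in assignment.counts().iterrows():
        if row["n"] > 0:
            devs.append((row["n_real"] / row["n"] - c) ** 2)
    msd = float(np.mean(devs))
    perfect = msd < floor
    return math.log(max(msd, floor)), perfect


def evaluate_synthetic(real_df: pd.DataFrame, synth_df: pd.DataFrame,
                       n_classes: int = DEFAULT_N_CLASSES, seed: int = 0) -> dict:
    """KL + LC scoring of a synthetic NSAA record set against real records."""
    P = density_from_records(synth_df)
    Q = density_from_records(real_df)
    combined = pd.concat([
        real_df.assign(source="real"),
        synth_df.assign(source="synthetic"),
    ], ignore_index=True)
    assignment = latent_class_fit(combined, n_classes=n_classes, seed=seed)
    lc, perfect = lc_score(assignment)
    return {
        "kl_divergence": kl_divergence(P, Q),
        "lc_score": lc,
        "lc_perfect_mixing": perfect,
        "lcmm_converged": assignment.converged,
    }
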