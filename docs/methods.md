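# Methods

## Data conventions and transforms

Visits are mapped to 69 quarter-year bins by the half-open rule
`bin = floor((age − 3)/0.25) + 1`, valid for ages in [3, 20.25). NSAA
scores enter the model through `logit((s + 0.5)/35)`, which is finite at
both endpoints and makes back-transformed predictions respect {0..34} by
construction; walk and rise-from-floor times go through the
inverse-softplus `log(e^x − 1)` so back-transformed times are positive.
The softplus pair is oriented so the *forward* direction maps the
positive data to the real line; the back-transform `log(1 + e^z)` is the
literal softplus. After transformation each outcome is z-scored with
constants estimated once on the training cohort and stored alongside any
fitted model, so calibration and prediction always reuse the training
scale. NSAA back-conversion to reportable scores rounds to the nearest
integer and clamps to [0, 34]; predictive *intervals* are computed on
the continuous back-transformed scale, because quantizing interval
endpoints to the 35-point grid systematically over-covers central
intervals (we measured the effect and kept the continuous convention).

## Trajectory model

Healthy state: `θ_t = α θ_{t−1} + δ`, with α in (0,1) and δ derived from
the endpoints (θ₀, θ_mat) through the geometric-series identity; the
maturity bin is fixed at index 68 (age 20). α = 1 is handled by the
analytic limit `δ = (θ_mat − θ₀)/68` so samplers can touch the boundary.
Disease state: `φ_t = φ_{t−1} + Δ − Γ·x_t` with `φ₀ = −t_onset·Δ`;
t_onset is real-valued since it only enters through φ₀. The deficit is
`φ* = softplus(φ)`, scaled per outcome by a loading β. β is
*unconstrained* (identity link, plain normal hierarchy): NSAA loads
positively, but walk and rise-from-floor times must load negatively on
the transformed scale (disease lengthens times), and since φ* ≥ 0 the
sign of β is identified. Treatment effects Γ are positive via the
softplus link.

## Discrepancy structures

The RW structure adds a latent walk `ε_t ~ N(ε_{t−1}, τ_innov²)` started
from a hierarchically modelled ε₀, plus white noise τ_obs. Its marginal
likelihood is computed by a scalar Kalman filter over all 69 bins that
updates only at observed bins, so missing visits need no imputation.
The walk is marginalized everywhere rather than sampled as explicit
latent states: it is statistically equivalent and mixes far better under
Metropolis updates; the filter is cross-checked in the tests against a
dense evaluation of the implied covariance `τ_obs² I + τ_innov² min(s,t)`.

The GP structure uses the squared-exponential kernel
`ρ² exp(−((t−t′)/λ)²)` over bin indices (so λ is in units of 3-month
bins), with white noise entering as diagonal variance inflation
`Σ = K + τ_obs² I`. Conditioning and likelihood use Cholesky
factorizations; jitter (steps of 1e−8 ρ²) is added only if factorization
fails, so well-conditioned results agree with the textbook formulas to
machine precision. ρ and λ are hierarchical per individual; λ can be
fixed globally through the population SD if desired.

## Variants and hierarchy

Variants A–H cross {RW, GP} × covariates × treatments; I is the
indirect-response baseline fit on the raw NSAA scale with point
predictions floored at 0 and interval upper bounds capped at 34. With
covariates on, the four per-outcome families α, β, θ₀ and θ_mat are
drawn jointly across outcomes from `N(μ_f, σ_f² Corr_f)` with a scalar
σ_f and a unit-diagonal correlation matrix — the scaled-correlation
form keeps σ and Corr identifiable. Δ and t_onset are shared across
outcomes (the disease state is one process per patient). Links: logit
for α; log for Δ, τ_obs, τ_innov, ρ, λ; softplus for Γ; identity
otherwise. Hyperpriors are weak and exposed in `PriorConfig`:
Normal(0, 5²) on link-scale means, half-Normal(0, 2) on SDs, an
LKJ-style shape-2 prior on correlations.

## Inference

Population fitting is Metropolis-within-Gibbs with two chains:
conjugate Gibbs updates for population means, adaptive random-walk
Metropolis on log population SDs and on correlation entries, and two
blocked adaptive-covariance Metropolis updates per patient (structural
parameters vs discrepancy parameters). The per-patient likelihood is
multimodal — the random walk can absorb trajectory shape — so each
chain starts from per-patient penalized MAPs (Nelder-Mead under an
inflated copy of the initial hierarchy) and the population init is
re-centred on that cloud; proposal covariances adapt during warmup via
Robbins-Monro step-size control (targets 0.23 for blocks, 0.44 for
scalars) and running empirical covariances, frozen afterwards.
Convergence is summarized by split-R-hat and an autocorrelation-based
effective sample size for every hyperparameter; defaults (two chains,
2000–3000 iterations, half warmup) are configuration values, not
constants.

The population posterior is approximated by a moment-matched
multivariate normal on a working scale: identity for means, log for
SDs, Fisher-z for correlation entries; eigenvalue ridging guards
rank-deficient covariances. Individual recalibration runs a joint MCMC
over (working-scale population vector, individual block): the MVN is
the prior on the former, the hierarchy couples the two, and only the
individual's prediction points enter the likelihood. With zero
prediction points the routine returns exact prior draws — the
population-level prediction. Posterior predictive draws condition the
discrepancy process on the prediction points by dense Gaussian
conditioning (sqexp kernel for GP variants, `τ_innov² min(s,t)` for RW
variants), add observation noise, and back-transform.

## Evaluation conventions

Prediction points per validation patient: a percentage drawn uniformly
on [0.20, 0.80] (seeded), count rounded down, earliest points first.
Prediction intervals are central (equal-tailed). The SAD score is the
plain sum `Σ_i |i − W_i|` over levels {0.01..0.99} (an optional /99
normalization is exposed); widths are reported at the 70% and 95%
levels, time-averaged per individual and then averaged within the
prediction-point groups 0, 1–3, 4–6, 7+. NSAA widths are also reported
in MCID multiples (MCID = 3.5 points).

## Synthetic cohorts and their scoring

Trajectories are simulated on every bin (one hyperparameter draw from
the MVN per individual, or fixed ground-truth hyperparameters), NSAA
rounded to valid scores. Missingness is emulated from training data:
empirical first-visit bins t₀, empirical visit gaps ω (kept as positive
integer bins), retention of bins {t₀ + nω}, then a time-ordered
Bernoulli scan over a 6×6 equal-width grid on (bin, NSAA) where each
box's success probability is the fraction of its training points that
were a patient's last; boxes without training points get probability 0.
Every retained point, including the first, takes the Bernoulli trial.
Finally all zero scores are removed (none occur in the registry data
the procedure emulates). When a variant includes treatments, synthetic
indicator columns switch on at a start bin sampled uniformly from the
pre-onset plateau (bins 15–36) unless a sampler is supplied.

KDE densities are product-Gaussian on the grid {1..34} × {1..69}
(NSAA axis starts at 1, consistent with zero removal), with the
normal-reference bandwidth `1.06 · min(sd, IQR/1.34) · n^{−1/5}` per
axis — the convention of the classic 2-D KDE routine — floored at
1e−12 and renormalized so the KL divergence (synthetic ‖ real) is
finite. The latent-class model is a G = 4 mixture of class-specific
quadratic age trajectories with a class-shared random intercept and
shared residual variance, fit by EM (Woodbury compound-symmetry
marginals, weighted GLS M-step, Nelder-Mead variance updates, multiple
seeded restarts); this deliberately restricts the general
random-effects structure of full latent-class mixed models to keep the
fit fast and deterministic. The LC score takes the log of the mean
squared deviation of per-cluster real fractions, excluding empty
clusters, flooring the argument at 1e−12 and flagging perfect mixing.

## The simulator as study ground truth

The reference population in `dmdtraj.populations` defines the study
conditions for every recovery and self-consistency check: NSAA rising
from ~8–10 at age 3 toward a high-20s plateau, onset around ages 8–11
(t_onset mean 24 bins, SD 6), decline toward single digits by the late
teens, observation noise ~0.18 on the transformed scale, a slow walk
(τ_innov ~0.05/bin), and treatment effects of roughly a third of the
typical progression increment. Simulated visit schedules start between
ages 3.25 and 7.75, repeat every 3–9 months, and follow patients for
3–14 years — a natural-history-registry pattern that observes both the
rise and the decline. What the simulator does *not* emulate: real
registries' heavier per-patient sparsity, assessor effects and learning
curves on the NSAA items, informative treatment initiation, and the
survival process behind loss of ambulation. Passing recovery and
calibration tests on these cohorts therefore demonstrates correctness
of the machinery under the model's own assumptions, not clinical
validity on registry data.

NSAA values are rounded to integers by the generator but the model
treats the transformed rounded score as the observation; near the score
ceiling this discretization inflates effective noise on the logit
scale. It is the same mismatch the model faces on real integer scores
and is visible as a small calibration cost in the self-consistency
study.

## Problem sizes and numerical choices

Recovery studies use 60-patient cohorts, two chains of 2000–3000
iterations, and check 95% credible-interval coverage of the population
means of α, Δ and β; individual-calibration coverage uses 50
replicates of patients with 7+ prediction points; self-consistency
pools ≥400 validation points from 50 patients. These sizes give the
hierarchy enough data to pool while keeping each study in the
one-to-two-minute range. Degenerate inputs are handled explicitly:
empty design sets return the GP prior, zero-variance training columns
raise, empty stopping-grid boxes get probability zero, empty
point-count groups are absent rather than zero, and perfect LC mixing
is flagged rather than returned as −∞.

## Known limitations

Random-walk Metropolis on a hierarchical state-space posterior mixes
slowly along the (θ_mat, β, Δ, t_onset) ridge; R-hat values around
1.5–3 on the slowest hyperparameters are common at the default chain
lengths, and credible intervals for those parameters should be read as
approximate. The missingness model is estimated separately from the
trajectory model (visit times are treated as non-informative given the
grid), the Hibma baseline needs an anchor score and falls back to a
fixed typical value for patients with no prediction points, and
ensemble averaging across variants is not implemented.
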