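# Methods

## The generating process

Individuals enter a progression-free (PF) state at an enrollment time drawn
uniformly on [0, T1] with T1 = 1.5 y (calendar shift only; all disease
clocks start at enrollment), with baseline age ~ Normal(60, 6) y. Two
competing clocks run from PF:

* progression, with a Weibull hazard in the rate form
  S(t) = exp(−(r·t)^k) — shape k = 1 is exponential with rate r;
* background general-population mortality (GPM), whose clock runs on
  attained age: the remaining-life draw at age a inverts the cumulative
  hazard H(a → a+t) of a parametric mortality law.

On progression the subject enters progressed disease (PD), where a Weibull
*excess* disease-specific hazard (clock reset at state entry — semi-Markov)
competes with continued GPM at the attained age. Total PD mortality is
therefore the additive sum of background and excess hazards; deaths from PF
are always background deaths, because the generator places no excess hazard
before progression (so an analysis-side "excess hazard from PF" fit is
expected to be near-null, and its failure is handled by a documented
fallback rather than treated as a model failure).

Scenario parameter sets (progression rate/shape, excess-death rate/shape):
(0.5, 1.0, 0.2, 1.0), (0.5, 1.6, 0.2, 1.6), (0.5, 0.4, 0.2, 1.6),
(0.1, 0.4, 0.1, 1.6) — constant, increasing, decreasing-progression, and
decreasing-progression-with-lower-rates risk patterns.

The rate-form Weibull reading of the scenario tables is deliberate: with
shape 1.6 and rate 0.5 it gives a mean PF sojourn Γ(1 + 1/1.6)/0.5 ≈ 1.79 y
before GPM competition, consistent with the scenario-2 population summary
(≈1.77 y); a proportional-hazards reading gives ≈1.38 y and is not.

Ages below the mortality law's reference age (40 y) are resampled rather
than extrapolated below the fitted range; this affects ~0.04% of draws.

## Mortality laws and life-table fixtures

Two laws are used, intentionally different on the generation and analysis
sides so the estimators never see the exact generating background:

* generation: Kannisto–Makeham, μ(x) = c + a·e^{bx}/(1 + a·e^{bx}) — a
  logistic old-age hazard (plateau 1 + c) plus a Makeham constant;
* analysis: Gompertz from age 60, μ(x) = rate·e^{shape(x−60)}.

Both are fitted to life-table central death rates by minimum Poisson
deviance, with rates treated as piecewise constant over single-year age
intervals and the law evaluated at interval midpoints. Cumulative hazards
use closed forms for both laws; remaining-life sampling inverts them
(closed form for Gompertz via log1p, safeguarded Newton with a bisection
bracket for Kannisto–Makeham, residual tolerance 1e−10 relative).

The shipped life tables are **synthetic approximations** of Canadian period
tables (1980/82 and 2017/19, both sexes): round anchor rates at five-year
ages, log-linearly interpolated to single years 40–100, then level- and
slope-calibrated so each table reproduces two published life-expectancy
milestones (1980/82: e60 ≈ 20.4 y, e80 ≈ 8.0 y; 2017/19: e60 ≈ 25.3 y,
e80 ≈ 9.9 y). This pins the overall level and slope of mortality but not
the exact age profile of the true national tables, so population estimands
for the long-horizon scenarios (3 and 4) carry a residual uncertainty of a
few percent that the short-horizon scenarios do not. Scenario-1/2 reference
summaries are reproduced within ~1%; scenarios 3–4 within ~3%.

## Trial sampling and censoring

Each replication draws 1,050 subjects without replacement and splits them,
in fixed order, into cohorts of 30/60/90/120/250/500 (across replications,
sampling is effectively with replacement). For an event fraction pe, the
data cutoff is the calendar time of the ⌈pe·n⌉-th PFS event (ceiling, so at
least that fraction has progressed or died); each subject's follow-up is
cutoff − enrollment, later events are administratively censored, and
subjects enrolled after the cutoff are dropped and counted. pe = 1.0 uses
the same rule, so deaths after the last calendar PFS event remain censored.

## Estimation

All six families share one likelihood,
Σ_events ln(h\*(tᵢ) + λ(tᵢ)) − Σ_all (H\*(tᵢ) + Λ(tᵢ)), with the
background terms zero in naive mode — so the additive-hazards (relative
survival) fit reduces exactly to the standard censored MLE when the
background is null, a property the tests pin to 1e−8.

Numerical choices: estimation on the log scale for strictly positive
parameters (identity for the Gompertz shape, log-normal μ and generalized
gamma Q); Nelder–Mead followed by a BFGS polish, with up to three fixed
perturbed starts; covariance from a central-difference Hessian at the
optimum with a 1e−8 ridge. A fit is failed on optimizer non-success,
non-finite likelihood, a non-positive-definite Hessian, zero events, or an
under-identified sample (n ≤ k + 1, which also makes AICc undefined).
Zero observation times (possible when progression coincides with the
cutoff) are nudged to 1e−6 y. The generalized gamma uses the (μ, σ, Q)
parameterisation mapped onto gamma tail functions, with |Q| < 1e−6 treated
as log-normal; Q = 1 and Q = 0 reduce to Weibull and log-normal to 1e−10.

Model selection takes the lowest AICc (−2ℓ + 2k + 2k(k+1)/(n−k−1), n =
subjects in the transition's risk set) among converged families; ties break
toward fewer parameters, then a fixed family order. BIC is available by
configuration. Probabilistic analysis draws parameters from the
estimation-scale multivariate normal; PFS/OS and per-transition draws use
independent seeded streams.

## Decision models

**PSM.** Occupancy on a monthly grid: PF = S_PFS, PD = S_OS − S_PFS,
with S_OS either the naive fit or S\*(t)·R(t) (analysis Gompertz law at a
fixed starting age of 60 for every subject). Where extrapolated curves
cross, PFS is capped at OS pointwise, which keeps PD non-negative by
construction. State means are trapezoid areas (second-order accurate;
halving the cycle moves exponential results by <0.1%). Point estimates are
means over PSA iterations with percentile 2.5/97.5 CIs; the deterministic
base case is stored alongside for diagnostics.

**MSM.** The 5-transition matrix is PF→PD (fitted), PF→death (background +
fitted excess) and PD→death (background + fitted excess); if the PF→death
excess component is not estimable the model degrades to 4 transitions
without it, while a non-estimable PF→PD or PD→death component fails the
whole model (the failure proportion is a reported outcome, not an error).
The partly naive variant replaces both PF→death entries with a single
naively fitted hazard. Sojourns come from first-event-wins DES: one event
time per transition (closed-form quantiles; gamma-tail inversion for the
generalized gamma), the minimum decides the trajectory — which reproduces
the additive total hazard exactly. DES individuals all start at age 60; the
background clock advances with model time (PD entry age = 60 + time to
progression), and the PD→death excess fit likewise uses per-subject
background age 60 + observed progression time. First-order populations are
10,000 individuals per PSA iteration by default, with first- and
second-order randomness on separate logged streams.

## Estimands and performance

Truth is computed from the complete population: the horizon is the first
Kaplan–Meier OS time at or below 1% survival, rounded **up** to a whole
year (the reference summaries print integral horizons); PF and OS are KM
restricted means to that horizon and PD is their difference. Per grouping
(sample size × event fraction × method), non-failed replications yield
MAPE, MAE and bias against the estimands and the fraction of percentile
CIs covering them; failed replications are excluded from error metrics and
reported as a separate failure proportion.

## What the synthetic generator does and does not show

The generator reproduces the features the study design depends on —
competing semi-Markov transitions, additive background+excess mortality,
staggered enrollment, event-count cutoffs — under fully known truth, so
passing tests demonstrate correct machinery and the direction/magnitude of
extrapolation error under these idealised conditions. It does not emulate
interval-censored progression detection, dropout, treatment arms,
covariates beyond age, or real life-table irregularities; conclusions about
any particular real trial require the corresponding real inputs (supply a
real life-table CSV via `load_life_table`/`fit_mortality_law` and the
`--life-table` options to replace the synthetic fixtures).

## Problem sizes used by the shipped checks

The default test-and-acceptance runs use deliberately scaled problem
sizes chosen to keep the demonstrations statistically meaningful on one
CPU: populations of 50,000 (as in the full design), 100 replications ×
4 sample sizes for the short-follow-up error demonstration (100 PSA
iterations), 200 replications for the failure-proportion and coverage
checks, and 1e5-draw Monte-Carlo comparisons against closed-form or ODE
oracles. The full 48,000-dataset-per-scenario design is supported through
`run-study` configuration and per-replication checkpoint/resume.
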