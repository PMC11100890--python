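# Methods

This note documents the models, conventions and design choices behind
`pegf`: what is estimated, how the sequential models and the Monte Carlo
standardization are specified, what the synthetic cohort does and does not
emulate, and where the genuinely open choices were made.

## Estimand and identification

The unit of analysis is the school-year. For a static regime g — a fixed 0/1
path for each of the four intervention components over waves 1..T — the
estimand is the standardized final-wave mean outcome E[Y_T^g]: the average
proportion of tested students meeting aerobic-capacity standards had every
school followed g. Identification rests on sequential exchangeability given
the modelled history (adoption may depend on any *measured* past variable,
not on latent school traits), positivity, and correct specification of the
sequential models. The synthetic generator is built to satisfy these
assumptions — adoption depends on the lagged outcome and cohort only — so
that estimator error on synthetic data reflects the estimator, not an
identification gap. Real data offer no such guarantee; that is the usual
g-formula caveat and the reason the natural-course diagnostic exists.

## Step-1 sequential models

One pooled model per time-varying variable, over waves 1..T, each with an
intercept and categorical wave terms (secular trend control):

- **binary** (yearly All-Star status): pooled logistic on its own lag,
  cohort, lagged outcome and lagged FRPM.
- **binary_absorbing** (audit, feedback, PE teacher): pooled logistic
  discrete-time hazard fitted on the *at-risk* rows only (lag-1 value 0);
  simulation returns 1 deterministically once the indicator is on.
- **bounded_continuous** (outcome, FRPM, %White, PE days/week): pooled
  linear regression; simulation draws Gaussian noise at the stored residual
  SD and clips to the observed training range (the "bounded normal"
  convention).
- **count_continuous** (enrollment, students tested, PE teachers on staff,
  audit conditions, coaching interactions): as bounded_continuous, plus
  rounding half-to-even and a floor at 0.
- **categorical_fixed** (cohort): baseline constant, never fitted.

Audit-derived mediators carry a `zero_when` rule: conditions met/changed are
structurally 0 before the audit occurs, coaching interactions require both
audit and feedback. They are fitted on the component-on rows only and forced
to 0 elsewhere, in fitting and in simulation. This is a modelling convention
for quantities that are undefined pre-treatment; the alternative (fitting
them unconditionally) would let a "never" world carry phantom audit scores.

The outcome model regresses on its own lags (two by default, with the lag-2
term clamped to lag-1 at wave 1), cohort, the current-wave values of all four
components, lag-1 All-Star status, the mediators, staffing and demographic
covariates. Including the component indicators alongside the mediators is a
deliberate superset of the minimal specification: the structural effects in
the validation cohort act directly through the components, and omitting them
would push their effect through mediator proxies with an attenuation bias.
Predictor sets are declared per variable (`CovariateSpec.predictors`) and
fully configurable; nothing is searched or selected.

### Fitting

Linear models use `numpy.linalg.lstsq`; residual SD uses n − rank degrees of
freedom. Logistic models use an in-package Newton/IRLS solver with
step-halving and a ridge penalty of 1e-4 on non-intercept terms. The ridge
is a deliberate robustness device: absorbing components reach ~99% coverage,
so late-wave at-risk sets routinely have all-0 or all-1 responses, where the
unpenalised MLE diverges (quasi-separation). With the penalty, separated
terms settle at large finite values whose fitted hazards are numerically 0
or 1 — exactly the right simulation behaviour — while well-identified
coefficients match the exact MLE to ~1e-4 (cross-checked against statsmodels
in the test suite). Degenerate cases short-circuit: a constant response
yields a constant model; an empty at-risk set yields a probability-0
initiation rule with a logged warning.

A `saturated` flag replaces the regression by empirical cell means on the
discrete cross of wave × predictor values. It exists for the oracle
equivalence checks, where saturated fits make the parametric engine
nonparametric on a finite state space.

## Step-2 simulation

Baseline states are drawn with replacement from the wave-0 rows (default
Monte Carlo size: 10× the school count, at which the MC standard error of a
wave-4 mean is ≈0.3pp, well below the ≈1pp sampling SE). Within each wave
variables update in `sim_order`: components first (in audit, feedback,
teacher, All-Star order), then mediators, staffing, demographics, outcome
last — treatments precede mediators precede outcome, so lag-0 predictors are
always already simulated. Regime components are forced; "natural" components
are drawn from their own fitted hazards. All draws for one (regime,
replicate) come from a dedicated stream spawned from the master seed, so
adding a regime or replicate never perturbs another's draws and reports are
byte-identical under a fixed seed.

## Inference

Point estimates come from the original panel. CIs are empirical 2.5th/97.5th
percentiles over cluster-bootstrap replicates: resample schools (whole
histories) with replacement, refit all models, re-simulate all regimes
(default within-replicate MC size 4× the school count — the small extra MC
noise widens CIs by under ~10% at study scale). Replicates that fail to fit
are dropped with a logged count; more than 10% failures aborts the analysis.
Contrasts are reported in percentage points; internally everything is a
proportion, converted only at the reporting layer.

Stratified analyses (sex, race/ethnicity, FRPM strata) swap the outcome
column and rerun the identical pipeline. Replicate unit-resamples depend
only on the master seed and replicate index, so strata within one run are
paired; the effect-modification test refers (point difference of stratum
contrasts) / (bootstrap SD of the paired per-replicate difference) to a
standard normal. With zero bootstrap SD the convention is p = 1 for a zero
difference, p = 0 otherwise. This paired-bootstrap normal approximation is a
package convention — defensible, but not the only possible test.

## The synthetic cohort

The generator emulates the study design with known ground truth:

- **Scale**: 581 schools, one baseline plus four intervention waves.
- **Baseline distributions**: censored (range-clipped) Gaussians whose
  *post-clipping* moments match the calibration targets (enrollment
  647 ± 318, FRPM 73.7 ± 23.3%, %White 16.0 ± 22.6%, outcome 40.1 ± 24.8%,
  ~196 tested students). Parent parameters are solved numerically; clipping
  rather than resampling is what the simulation engine itself does, and it
  reproduces the heavily skewed FRPM/%White shapes a truncated normal
  cannot (the %White target is infeasible for any resampled truncated
  normal — its SD exceeds the family's exponential-tail bound at that mean).
- **Rollout**: capacity-constrained ranked selection. Each wave exactly the
  calibrated number of schools initiates each component (cumulative coverage
  28→99% audit, 0→71% feedback, 7→82% teacher; All-Star 12→77%), chosen by a
  score combining the lagged outcome (confounding by indication, weight 3
  per unit of outcome), cohort boosts (a 50-school pilot cohort selected on
  low baseline outcome and high FRPM adopts first), persistence for the
  yearly indicator, and Gumbel noise. Marginal coverage matches the targets
  by construction; individual adoption is outcome-dependent, which creates
  genuine treatment-confounder feedback (treatment moves the outcome, the
  outcome drives later adoption).
- **Outcome law**: y_t = ρ·y_{t-1} + Σ_c δ_c·A_{c,t} + γ·frpm_t + drift +
  σ_y·ε, clipped to [0,1]; defaults ρ = 0.85, δ = (0.0025, 0.0025, 0.020,
  0.015) for audit/feedback/teacher/All-Star, γ = −0.03, drift 0.085,
  σ_y = 0.03. Effects cumulate geometrically, so sustained full
  implementation beats the staggered natural course, which beats never —
  the qualitative ordering the pipeline must reproduce. σ_y reflects the
  binomial noise of a ~200-student testing pool (≈3.5pp SE) less the
  persistent component already carried by ρ and the baseline spread;
  drift is set so the no-intervention course stays near its baseline level.
- **Strata**: parallel outcome columns with a baseline offset, a
  configurable effect scale, and noise correlated 0.8 with the overall
  outcome — enough structure for paired effect-modification testing.

`true_regime_mean` simulates the structural equations directly with
components forced (no fitted models), giving the estimand for parameter
recovery.

What it does **not** emulate: student-level records, inter-school
correlation (districts/boroughs — units are independent), latent persistent
school effects (deliberately, since they would violate the estimator's
sequential-exchangeability assumption and conflate identification failure
with estimator error), missing data, or the numerical values of the real
study's effect estimates. Passing recovery tests therefore demonstrates
estimator correctness under the design's structure, not robustness to
violations real data may carry. One visible consequence of the pure-AR
outcome law: cross-sectional dispersion contracts toward the AR stationary
level over waves (SD ≈ 25% at baseline → ≈ 12% by wave 4), whereas real
school panels keep persistent heterogeneity.

## The enumeration oracle

`DiscreteSystem` specifies binary variables with explicit conditional
probability tables; `exact_gformula` enumerates all covariate paths (bounded
at 1e6) and sums E[Y_T | path]·P(path under regime), with treatment factors
replaced by regime indicators. Against it, the engine with saturated models
on a large sample from the same system must agree within Monte Carlo error —
the core correctness check, run on a two-wave feedback system in the
acceptance suite at n = 1e5.

## Numerical conventions and edge cases

- Lags clamp at wave 0 (`max(t − lag, 0)`), which implements the outcome
  lag-2 = lag-1 rule at wave 1 generically.
- Count rounding is half-to-even (unbiased, reproducible).
- Bounded draws clip to the observed training min/max, not the structural
  bounds; a fitted mean outside the observed range yields boundary draws.
- Saturated lookups for unseen predictor cells fall back to the training
  mean of the variable.
- Missing baseline covariates are imputed with the wave-0 mean (mode for
  binary/categorical) *after* the eligibility filter drops units missing
  two or more outcome waves; both are logged.
- CSV IO is lossless (`%.17g` on write, round-trip float parsing on read);
  values are taken as-is, with no percent rescaling.

## Problem sizes used in the validation suite

Unit tests run on reduced cohorts (80–300 schools) where the checked
identities are exact or tolerances are set by explicit SE arithmetic. The
acceptance suite runs at study scale: 100 replicated cohorts of 581 schools
for recovery/null studies with 100 bootstrap replicates each (the production
default would be 500), 1e5-path oracle samples, and 2e5-unit ground-truth
simulations. These sizes put Monte Carlo noise well below the tolerance of
every assertion they feed.

## Known limitations

- Static regimes only; no dynamic (covariate-responsive) rules, no
  mediation decomposition, no variance estimator other than the bootstrap.
- The effect-modification p-value method is a convention (see above);
  other reasonable tests would give different p-values.
- The ridge-stabilised hazards mean coefficients under complete separation
  are regularisation artefacts (their *predictions* are the correct 0/1).
- Positivity is not diagnosed beyond empty-cell degeneracies.
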