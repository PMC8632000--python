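# Methods

## Structural and statistical model

Drug disposition is a one-compartment model with first-order elimination
under constant-rate IV infusions. For an infusion of rate R (mg/h) starting
at t0 with duration T and elimination rate constant k = CL/V, the
concentration is

    C(t) = (R/CL) · (1 − e^{−k·min(t−t0, T)}) · e^{−k·max(t−t0−T, 0)}

and multiple doses superpose linearly. All production code uses this
analytic form (and the closed-form steady-state trough); numerical ODE
integration appears only as an independent test oracle. A standard
bi-exponential two-compartment solution is provided as a structural option
for exploratory use; estimation supports the one-compartment model, which is
the structure the analysis settled on.

Individual parameters are multiplicative:

    CL_j = tvcl · Π(covariate factors on CL) · e^{η1j}
    V_j  = tvv  · Π(covariate factors on V)  · e^{η2j}

with independent zero-mean normal random effects (variances ω²_CL, ω²_V,
reported as %CV = 100·√ω² — the plain convention, not the lognormal CV
formula). Covariate factor forms:

- `linear_centered`: 1 + β·(x − center). The reference model uses this for
  creatinine clearance (center 101.15 mL/min, β 0.0046) and weight
  (center 75 kg, β −0.011) on CL. Because the linear form is unbounded below
  (the weight factor crosses zero near 165.9 kg), factors are floored at
  0.01 with a logged warning; inside the fitting engine the floor is applied
  silently.
- `power_allometric`: (x/center)^e with e = 0.75 on CL and 1.0 on V.
- `fractional_categorical`: 1 + β·1{female}.

Centering constants default to the fitted dataset's covariate medians but
are fixed to the published 101.15 mL/min and 75 kg in the reference model so
its typical values mean what they meant in the original analysis.

Residual error is additive, proportional, or combined. The reference
configuration uses additive error with σ = 3.07 mg/L: the source analysis's
text and parameter table disagree on whether the selected residual model was
proportional or additive, and only the additive magnitude is reported, so
the reproduction uses the number that exists; proportional/combined remain
available by configuration. In the proportional variance the prediction is
floored at 0.01 mg/L to avoid a degenerate zero variance.

## FOCE-I estimation

The objective function value (OFV) is the first-order-conditional (with
interaction) approximation to −2 log marginal likelihood, omitting the
n·log 2π constant. Per subject:

1. The conditional mode η̂ minimizes
   Σ_j [(y_j − f_j(η))²/g_j(η) + log g_j(η)] + η′Ω⁻¹η, the residual variance
   g evaluated at η ("interaction"). The inner problem is solved by a damped
   Newton iteration (Gauss–Newton Hessian, Armijo backtracking, η start 0,
   gradient tolerance 1e−9 relative) with analytic ∂f/∂η from the
   closed-form solution.
2. The contribution is log|V_i| + r_i′V_i⁻¹r_i with
   V_i = G_iΩG_i′ + diag(g(η̂)), G_i = ∂f/∂η|η̂, r_i = y_i − f_i(η̂) + G_iη̂.

Two implementations coexist: a per-subject scalar path used for
verification, and a padded-array engine that solves all subjects' inner
problems simultaneously (the production path of `fit_model`); a test pins
their agreement. The outer problem is L-BFGS-B on a transformed scale (log
for tvcl/tvv/ω²/σ; covariate slopes divided by 0.1 so their curvature is
comparable to the log-scale parameters while the finite-difference step
still resolves slope gradients; bounds 1e−8–1e8 on the natural scale),
convergence at relative OFV change below 1e−10, with warm-started inner
modes across outer iterations. ω² estimates at the lower bound are
flagged as boundary solutions. When the line search stalls at an
already-stationary point (typical when a fit is warm-started at its own
optimum, as in bootstrap replicates of degenerate resamples), stationarity
is confirmed by a finite-difference gradient check and the fit is reported
converged.

Standard errors come from the inverse of a central finite-difference Hessian
of the OFV on the natural scale (covariance = 2·H⁻¹ since OFV is −2 log L);
RSE% = 100·SE/|estimate|. No sandwich estimator is attempted.

Diagnostics: PRED is the typical-value prediction (η = 0), IPRED the
conditional prediction f(η̂), and CWRES = L⁻¹(y − f(η̂) + Gη̂) with
V = LL′ the FOCE-I observation covariance — approximately standard normal
under a correct model.

## Covariate search

Stepwise covariate modeling is greedy: forward inclusion adds, among all
candidates whose OFV drop is at least 3.84 (χ²₁, α = 0.05), the one with the
largest drop, repeating until none qualifies; backward elimination then
removes, one at a time, any included relation whose removal raises the OFV
by less than 6.63 (α = 0.01). Thresholds are inclusive, implemented with a
1e−9 tolerance so that a drop of exactly 3.84 qualifies despite binary
floating point. Ties break deterministically (CL before V; covariates in
the order CRCL, WT, AGE, SCR, SEX). Candidate fits that fail to converge
are skipped for the round and logged. SCR and CRCL are both offered as
candidates although they are collinear (CRCL is computed from SCR, age,
weight, sex); a greedy search may absorb the renal-function signal through
either, which the analysis narrative points out when it happens.

## Evaluation

- **Bootstrap**: replicates resample subjects with replacement to the
  original subject count and refit, warm-started at the original estimates.
  Summaries are per-parameter median, 2.5th–97.5th percentile CI, and
  bias% = 100·(final − bootstrap median)/final on unrounded medians
  (positive when the original estimate exceeds the median). More than 20%
  failed replicates raises a warning, not an error.
- **VPC**: plain (non-prediction-corrected). The fitted model is simulated
  at the original design (same subjects, doses, times, covariates; fresh η
  and residual draws); observed 5th/50th/95th percentiles per time bin are
  compared with the 90% interval of the same percentiles across simulated
  replicates. Bins are time quantiles (default 6) so each holds roughly
  equal observation counts — at 176 observations this stabilizes the
  percentile estimates.
- **GOF**: one row per observation with DV, PRED, IPRED, CWRES and time
  after dose.

## Dose tailoring

Virtual patients are defined by creatinine clearance (20, 60, 100,
140 mL/min strata); weight is fixed at the population median 75 kg so the
weight factor is exactly 1. Each patient draws both η terms, maps to CL and
V, and the steady-state pre-dose trough follows in closed form, with trough
defined at τ after infusion start (the instant before the next dose).
Residual (assay) error is excluded: the 10–20 mg/L target applies to the
true concentration, mean-zero additive noise would not change the means, and
excluding it avoids negative simulated concentrations. The tailored dose
maximizes the fraction of patients inside the target range; candidates share
common random numbers, so the exact linearity trough(d) = (d/d₀)·trough(d₀)
holds patient-by-patient and ties break toward the smaller dose. The
selection rule was validated analytically: plugging the published
common-dose trough means/SDs into a normal approximation and scaling
linearly over 100-mg candidates reproduces all four published tailored doses.

With this package's own simulated troughs the selection reproduces the
published choices at the 20, 60 and 100 mL/min strata. At 140 mL/min the
published mean trough exceeds the model's own typical-value closed form by
~9%, which no mean-zero BSV can generate, and the fraction-in-range
criterion then prefers 1,100 mg over 1,000 mg by a small margin
(≈0.75 vs ≈0.72). The exact simulation settings behind the published table
(virtual weights, error inclusion, trough timing) are not stated; the
reproduction band for trough means is therefore ±15%, and the 140 mL/min
selection is the known residual discrepancy.

## Synthetic cohorts

The generator emulates the study design, not any real patient: 58 subjects;
1–7 samples each (probabilities 0.14/0.26/0.25/0.15/0.10/0.06/0.04 over
1–7, nudged to an exact total of 176); one dose at t = 0 (1,000 mg with
probability 0.7, else 500 or 750 mg) infused over 0.5 h; sampling times
drawn without replacement from the grid 0.5, 1, 2, 4, 6, 8, 12 h (a
plausible first-dose TDM schedule spanning distribution and elimination
phases — the real schedule is unpublished). Covariates are truncated
normals on the log scale centered at the published medians (age 54 y,
weight 75 kg, serum creatinine 0.935 mg/dL) with hard truncation at the
published ranges; log-SDs 0.25/0.16/0.35 were fixed once to land the
generated medians near the published ones. Sex is female with probability
19/58. CRCL is always computed by Cockcroft–Gault from the sampled
covariates — notably, the published covariate summary's own CRCL median
(101.15) is a few percent above what Cockcroft–Gault gives at the published
age/weight/SCR medians, so the generated CRCL median sits near 90 mL/min;
the tests treat agreement within 15% as the design target. Concentrations
below the assay quantification limit (0.25 mg/L) are retained and flagged,
not censored: the study's observed minimum (1.9 mg/L) is far above the
limit, so no BLQ model (M3 etc.) is warranted.

What passing tests on these cohorts show — and do not show: they verify the
estimator, search, and simulation machinery against known ground truth under
the study's design; they cannot certify the published covariate effects in
real patients, reproduce real-data OFVs (729.9/670.1), or validate the model
on dosing histories (multiple or irregular doses) the generator does not
emulate.

## Problem sizes and numerical choices

The test suite uses reduced but honest replicate counts chosen as its
experiment design: 200 bootstrap replicates (the bias bound is stated for
exactly this reduced n), 200 null datasets for the covariate-selection
false-inclusion rate (16-subject cohorts, one BSV term), 20 replicate
cohorts for parameter recovery, 500 VPC simulations, and Gauss–Hermite
quadrature (61 nodes/dimension) on 3-subject instances for the likelihood
oracle. The acceptance script uses 1,000 virtual patients per stratum and a
single 58-subject recovery cohort, all randomness derived from one seed.

Degenerate inputs: subjects must have at least one dose and one observation;
zero ω² fixes the corresponding η at 0 exactly; zero σ is allowed for
noise-free simulation but not reachable by the fitter. Dataset round-trips
write floats at 17 significant digits and parse them with round-trip
precision, so write→read is bit-exact.

## Known limitations

- FOCE-I is a linearization; its OFV deviates from the exact marginal
  likelihood as BSV grows (tested ≤1 point at study-like variability on
  small instances, observed up to ~1.7 points at 32% CV with rich sampling).
- No inter-occasion variability, no η correlation, no SAEM/Bayesian
  alternatives, no BLQ censoring model, no absorption or nonlinear
  elimination, no dialysis or loading-dose logic.
- The stepwise search inherits the usual greedy-selection instabilities
  under collinearity (SCR vs CRCL).
- Steady-state dosing records (SS/II) are not accepted as input; steady
  state is handled analytically in the dosing module.
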