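# Methods

## The estimand and the data it needs

The package estimates how the hazard of incident obesity depends jointly
on objectively measured physical activity (daily step counts from a
wearable device, summarised monthly) and polygenic risk for BMI, and
inverts that relationship into the step count at which a given level of
genetic risk reaches the cohort-reference hazard. Four input streams are
required: long-format daily step records with wear time, EHR-style BMI
measurements at clinic encounters, per-person polygenic scores (or a
dosage matrix plus SNP weights) with genetic principal components, and
baseline covariates with missingness. Real data of this kind live in
controlled-access enclaves, so a first-class synthetic generator emulates
all four streams from a known hazard model.

## Cohort curation

Day-level validity follows the standard wearable-curation rules: a day is
valid when wear time is at least 10 hours, steps lie in [100, 45000]
(bounds inclusive — the exclusions are *less than* 100 and *greater than*
45 000), and the participant is at least 18 that day. Monthly mean daily
steps are computed per calendar month and months with fewer than 15 valid
days are dropped. Time zero is each person's first valid monitoring day.
Baseline BMI is the record closest to time zero within ±180 days
(configurable); persons with baseline BMI ≥ 30 are excluded. The outcome
is the first BMI record ≥ 30 at least 6 months after time zero; persons
whose first obese record falls inside the 6-month landmark are excluded
outright rather than censored — exclusion matches an eligibility reading
of the landmark ("included only individuals…"), and because the landmark
leaves no events before 6 months, the partial likelihood contains no
risk-set terms there, so either choice leaves the hazard coefficients
unchanged. Censoring is the later of the last exposure-month end and the
last BMI record; which record ends follow-up is not derivable from first
principles, and this reading is one defensible choice, exposed in
`CurationConfig`. Every exclusion is counted, and attrition satisfies
input persons = analytic persons + Σ per-rule removals.

## The time-varying Cox model

The analytic cohort is expanded to counting-process rows: one row per
person-month carrying that month's mean daily steps, with the event
attached to the truncated interval containing the event time. Months that
fail the 15-valid-day rule inherit the previous month's mean (audited as
`gap_months`); follow-up past the last exposure month carries the last
mean forward, so intervals partition (0, time].

The partial likelihood with Efron tie correction is maximised by
Newton–Raphson with step halving (convergence: largest score component
below 1e-8; a coefficient passing |β| > 15 on this package's covariate
scales is monotone likelihood and raises an error). The fitter is
implemented in-package because downstream machinery needs term-addressable
covariance blocks (chunk tests), Schoenfeld residuals on start–stop data,
and exact agreement with a brute-force likelihood oracle; the test suite
cross-checks coefficients and standard errors against an independent
survival library to 1e-6.

Continuous terms (steps per 1000/day, PRS, age, SBP) enter as restricted
cubic splines with 3 knots at the 10th/50th/90th percentiles, in Harrell's
truncated-power parameterisation (one linear plus one curvature column;
linear beyond the boundary knots). The drop-to-linear rule Wald-tests each
curvature column at α = 0.05 and refits non-significant ones linear; the
steps exposure keeps its spline regardless, since the exposure–response
shape is the object of interest. The PRS × steps interaction multiplies
linear PRS into both steps-spline columns (2 df), and its chunk test is
the joint Wald statistic b'V⁻¹b. Indicator covariates whose level has no
events on one side are omitted from the default adjustment set before
fitting — with a 3%-prevalence condition and a few hundred events, a
separated indicator is otherwise guaranteed.

Monte Carlo calibration (in the test suite): under linear truth the steps
curvature term survives in ~2–10% of 100 cohorts of n = 1000; under a
strong quadratic distortion of −0.1 per (1000 steps)² it is retained in
≥ 90%. Pooled 95% intervals over 30 cohorts of n = 2000 with 20% MCAR
missingness in SBP cover the true coefficients at near-nominal rates with
mean absolute bias well under 0.05.

## Multiple imputation

Missingness is confined to baseline covariates (SBP, alcohol, education,
smoking, baseline BMI), so imputation runs on the person-level table. Each
of m = 10 rounds bootstraps the rows observed on the target variable, fits
a linear working model of the (numerically coded) target on the other
baseline predictors plus event status and follow-up time, and replaces
each missing entry with the observed value of a random one of the k = 5
donors nearest in predicted mean; categorical targets match on the same
predicted score. PMM never fabricates values, so imputed categories are
always valid levels and continuous imputations stay in the empirical
support. m and k follow common practice; neither is dictated by the
analysis. Pooling uses Rubin's rules (T = W̄ + (1 + 1/m)B) with
Barnard–Rubin small-sample degrees of freedom; intervals use the t
reference. Because the counting-process intervals depend only on exposure
and event times, the expansion is built once and person-level covariates
re-merged per completed dataset.

## Proportional-hazards diagnostics

Schoenfeld residuals at each event time (observed covariate minus the
risk-set weighted mean) are tested for association with event time using
the Grambsch–Therneau score statistic with the identity time transform:
per-coefficient χ²₁ = d·(Vu)ⱼ²/(Vⱼⱼ·Σ(g−ḡ)²) and a global χ²_p, where
u = Σ(g−ḡ)s and V is the coefficient covariance. Simulations in the suite
confirm near-nominal size under proportional truth and high power against
an effect that grows linearly in time. With a single event time the
statistic is undefined and the table reports NaN.

## Inversion to step targets

For a given PRS percentile (mapped to the residual scale through the
cohort's empirical quantiles), the log-HR curve over a 500-point step grid
spanning the 1st–99th percentile of person-month means is the design-row
contrast against the reference (50th percentile, cohort-median steps), with
pointwise delta-method variance d'Σd. The dense interpolating cubic spline
uses the grid points as knots (at least 100 required) — interpolation
reproduces the curve to machine precision at the grid, which a smoothing
spline with fewer knots could not. Roots of log-HR = 0 are found by a
1-step-resolution sign scan plus Brent's method (0.5-step tolerance);
multiple crossings return the smallest and set a flag, and a curve that
never crosses returns an absent target with its sign. Confidence limits
invert the lower and upper band curves separately: for a decreasing curve
the lower band yields the smaller step bound. A band edge with no crossing
gives a one-sided interval, flagged — expected at extreme percentiles,
where the band is wide. Baseline-BMI stratification evaluates the
BMI-adjusted model (the sensitivity specification; baseline BMI is kept
out of the primary model because it is collinear with the PRS) at fixed
BMI ∈ {22, 24, 26, 28} on the curve side only, so strata shift the whole
curve. The reference step count is a named parameter defaulting to the
cohort median the package computes.

## Cumulative incidence

The Breslow estimator dΛ₀(t) = d/Σ_{at risk} exp(x'β) on the
counting-process rows (risk sets honour (start, stop] membership) reduces
exactly to Nelson–Aalen at β = 0. Covariate-specific risk is
1 − exp(−Λ₀(t)·exp(x'β)) with the profile's steps held constant over the
horizon; the incidence table spans PRS percentile × assumed steps ×
years {1, 3, 5} with bands from a 200-draw parametric bootstrap of
N(β, Σ) (baseline held fixed — coefficient uncertainty only).

## The synthetic generator

The generator's defaults are the study conditions the analysis assumes.
Hazard: piecewise-constant over months, λ_im = λ₀·exp(0.5·PRS −
0.4·steps/1000 + γ'Z), with λ₀ = 0.98/person-year chosen so that annual
incidence at the median step count (~8 300/day) is roughly 4%; onsets are
drawn by inverting the cumulative hazard at Exp(1) draws (the draws are
stored so tests can replay an independent inverse-CDF oracle). A config
switch adds a quadratic steps term so spline selection can be shown to
detect curvature. Steps: log-normal with person intercepts (log-mean
log 8300, between-person SD 0.35, within-day SD 0.25 — the within-person
distribution is this module's assumption, not an observed fact); wear time
is a two-component mixture with 8% low-wear days, plus 0.5%/0.1% device
artifacts outside [100, 45000] steps, so the curation filters have work to
do. The true monthly exposure is the behavioural (artifact-free) mean.
BMI documentation: encounters at 2/year (Poisson); records before onset
stay below 30, at/after onset are ≥ 30; with `documentation_only` the
event surfaces at the first post-onset encounter, giving realistic
documentation delay. PRS: dosage-derived, standardized, with 0.2 loadings
on the first two PCs so residualization is non-trivial. Covariate
marginals approximate a middle-aged volunteer cohort (age ~N(50,13),
27% male, 23% cancer, 3% CAD, SBP ~N(125,15), 98% alcohol, education
78/18/4%, 32% smoking, baseline BMI ~N(25.5, 2)). Missingness is MCAR at
5% per eligible covariate by default, with an optional age-dependent (MAR)
mode for SBP. Monitoring starts on calendar-month boundaries so the
generator's person-month hazard intervals coincide with calendar-month
aggregation; continuous covariates enter the true hazard centred (age−50,
SBP−125, BMI−25), which only shifts the baseline.

What the generator does not emulate: LD structure or genotype-level QC,
device-brand artifacts beyond the wear/step filters, seasonal or weekday
activity patterns, BMI measurement drift, informative missingness beyond
the MAR option, competing risks. Passing tests therefore demonstrate the
statistical machinery under the assumed model, not robustness to these
real-data features.

## Parameter-recovery frames

`analysis_frames` builds the analytic cohort directly from the generator's
ground truth (event = latent onset, exposure = true monthly means),
bypassing the record-level observation layer. Recovery and calibration
studies use it because their estimand is the generating model; the
observation layer (daily filters, encounter-driven documentation) is
exercised separately by the curation tests, which verify, among other
things, that documented events never precede latent onsets.

## Problem sizes and numerical choices

Simulation studies in the suite and acceptance script run at n = 1000–5000
persons over 5 years with 30–100 replicates — sizes chosen to put Monte
Carlo error comfortably inside the tested tolerances while keeping a full
run in minutes on one core. Other constants: Newton max 50 iterations;
logistic fits (Nagelkerke) via maximum likelihood with tolerance 1e-10,
max 100 iterations, with exact collinearity of the PRS detected by rank
and returning a zero increment; OLS for residualization via least squares
with rank-deficiency reported by column; percentiles are averaged ranks
scaled to (0, 100).

## Known limitations

Documentation delay makes the observed event time a lagged version of
onset; coefficients remain interpretable but absolute incidence is shifted
toward documentation. The Grambsch–Therneau implementation uses the
Breslow-style risk-set mean in the residuals (exact under no ties). The
profile CI from band inversion is pointwise, not simultaneous. Carried-
forward exposure during gap months assumes activity did not change when
the device was off — the same assumption the 15-valid-day rule already
makes within months.
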