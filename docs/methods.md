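# Methods

This note documents the models and conventions implemented in `spanlife`,
the choices made where the methodology was genuinely open, and what the
synthetic-data generator does and does not emulate.

## 1. Exposure preparation

**Winsorisation.** Each exposure (sleep h/day, MVPA min/day, DQS 0–100) is
winsorised at its 2.5/97.5 percentiles: values outside are replaced by the
percentile values, keeping the full sample. Percentiles use linear
interpolation between order statistics (the numpy default); this convention
is load-bearing — the winsorised extremes become the printed tertile-range
endpoints and the score-mapping floors — so it is fixed and tested. Exact
idempotence does not hold under interpolated percentiles (re-winsorising can
move the bound within one order-statistic gap); this is documented rather
than patched. Tukey fences (`Q1 − k·IQR`, `Q3 + k·IQR`, `k = 1.5`) are the
sensitivity alternative.

**Tertiles and the joint variable.** Tertiles are cut at the 33.33/66.67
percentiles of the *winsorised* values, sexes pooled; ties on a cut go to
the lower tertile (deterministic). The 27-category joint variable indexes
the 3×3×3 grid as `9·sleep + 3·MVPA + diet + 1` on 0-based levels, so
category 1 is the all-low reference and 27 is all-high; the mapping
round-trips exactly.

**Exclusions** run in a fixed order (data-validity → death-window →
health-status) purely for log attribution; the final analytic set does not
depend on the order. The default rule drops deaths within the first year of
follow-up (reverse-causation guard).

## 2. Hazard models

The joint model is a Cox proportional-hazards fit (lifelines backend, Efron
ties) of the 26 non-reference category indicators plus covariates (age, sex,
smoking, deprivation, alcohol, discretionary screen time, light-intensity
activity in the synthetic cohort). Categories with zero events are dropped
from the risk set and reported as missing HRs rather than divergent
estimates. 95% CIs are `exp(β ± 1.96·SE)`.

Dose-response curves use a restricted cubic spline (Harrell basis: linear
term plus truncated-cubic terms scaled by `(t_k − t_1)²`, linear beyond the
boundary knots), 4 knots at the 5/35/65/95 percentiles by default (the knot
count is configuration, not doctrine). Curves are centred so the log hazard
is 0 at the 5th percentile of the exposure; pointwise CIs come from the
delta method on the basis-contrast. The curve **nadir** is the argmin of the
fitted log hazard *within the knot span*: beyond the boundary knots the
spline is linear extrapolation, so an extremum there reflects tail-slope
noise, not curvature.

Proportional hazards are checked with rank-transformed Schoenfeld-residual
tests per term; the global test combines per-term p-values by the Šidák rule,
which is conservative under correlated terms. Functional form is summarised
by martingale-residual correlations against continuous covariates.

## 3. Lifespan: the period life table

A Chiang period life table with mid-interval separation factor `a = 0.5`
for all closed intervals (the cohort starts in mid-adulthood, so no
infant-mortality correction is needed):

    q = w·m / (1 + w·(1−a)·m),  L = w·(l_next + a·d),  open interval L = l/m,
    T = reverse cumulative L,   e = T/l,  radix 100,000.

Each identity holds to machine precision by construction and is asserted in
tests; with a single open interval `e = 1/m` exactly.

A category's mortality schedule is `m(x)·HR` — the HR applied uniformly
across ages (proportional hazards carried into the life table; the analysis
estimates no age-varying HR). Two readings of the baseline schedule are
provided: `calibration="none"` treats it as reference-category rates
(default), `"population"` rescales by the prevalence-weighted mean HR so the
category mix reproduces the population rates exactly. Years gained are
`e(start | HR) − e(start | 1)` at start age 64 (the cohort median,
configurable). Because `e` is strictly decreasing in HR, gain CIs come from
substituting the HR confidence limits — the simplest convention that is
exactly monotone-consistent; a delta-method alternative would differ only at
the third decimal at these effect sizes.

## 4. Healthspan: the disease-free extension

Leaving the disease-free state is modelled as a combined first-event
process: death or first incidence of any of CVD, cancer, type II diabetes,
COPD, dementia, with no return. The exit rate per age interval is
`HR_m·m(x) + Σ_c HR_c·i_c(x)`; the pipeline uses the mortality-model HR for
`m` and the HR from a Cox fit of the combined disease-free exit for all
incidence terms (per-condition joint-category fits are unstable at
desk-scale event counts — dementia contributes a few hundred events — so a
single exit model is the stable default; per-condition HRs are accepted by
the API).

Starting prevalence enters in one of two modes, both implemented because the
published construction is ambiguous at this level: `radix` (default) scales
the starting cohort by `1 − prevalence_any(start)`, reporting disease-free
years per person alive at the start age; `sullivan` weights each interval's
person-years by the age-specific disease-free proportion. Prevalence of
"any" condition assumes independence across conditions
(`1 − Π(1 − p_c)`).

**Monte Carlo uncertainty.** Incidence rates are sampled log-normally
(`SD = se/i` on the log scale), prevalences logit-normally, and — beyond the
published prevalence-only propagation, switchable — the HR log-normally from
its CI. Each iteration recomputes the DFLE gain against the HR = 1 reference
with shared rate draws; the CI is the 2.5/97.5 percentile of the iteration
distribution and the point estimate uses central values. Note a property of
percentile intervals: their width estimates the *fixed* spread of the
sampling distribution and does not shrink as iterations grow; what shrinks
as `1/√n` is the Monte Carlo standard error of the mean, which is reported
alongside (`mc_se_of_mean`). Default 10,000 iterations in study-scale runs;
the pipeline default is 2,000, which puts the Monte Carlo noise on the CI
endpoints well below the rate uncertainty itself.

## 5. Synergy indices

Behaviours are dichotomised (default: top two tertiles favourable) into 8
joint states with the all-unfavourable state as reference. The three-way
joint forms are used — one index per outcome, not a full interaction
decomposition:

    RERI = HR₁₁₁ − HR₁₀₀ − HR₀₁₀ − HR₀₀₁ + 2
    AP   = RERI / HR₁₁₁
    S    = (HR₁₁₁ − 1) / [(HR₁₀₀ − 1) + (HR₀₁₀ − 1) + (HR₀₀₁ − 1)]

All are exactly null (0, 0, 1) under additivity, and `AP·HR₁₁₁ ≡ RERI`.
With this orientation protective behaviours give HRs below 1, so a positive
RERI means super-additive joint benefit; the sign flips if the orientation
flips, which is why the orientation is fixed and documented. S is reported
missing (with the reason) when its denominator is ≤ 0, which is common in
the protective regime.

CIs are percentile bootstrap over participants (default B = 2,000; BCa was
considered and rejected for reproducibility simplicity). Two estimators of
the 8-state HRs are available: `cox` (covariate-adjusted partial likelihood,
the pipeline default) and `rate` (the occurrence/exposure estimator
`log HR_k = log(d_k/T_k) − log(d_0/T_0)`, the exact MLE under exponential
event times and orders of magnitude faster for unadjusted resampling
studies). Resamples with an empty or zero-event state are dropped and
counted; more than 20% dropped aborts with advice to enlarge the cohort.

## 6. Composite score and minimum doses

Each behaviour contributes a piecewise-linear subscore on [0, 100/3] —
transparent and exactly invertible, which the dose decomposition requires;
any smooth alternative would change Table-style outputs only through the
unknown standardisation function, which is not recoverable from the source:

* sleep: U-shaped, 100/3 at the 7.5 h nadir, 0 at both winsorised extremes
  (side-specific slopes when the extremes are asymmetric about the nadir);
* MVPA: linear from the winsorised minimum to the ~50 min/day dose-response
  optimum, flat beyond;
* DQS: linear from the winsorised minimum to the winsorised maximum.

The composite score is the plain sum (equal nominal weighting: 0 at
all-floor, 100 at all-optimal). Hazard-derived weights are used only to
*allocate* a score increment across behaviours: behaviour `b`'s marginal
span is the mean |log HR difference| between its high and low tertiles
across the other two behaviours' 3×3 combinations, normalised to sum to 1.
An increment `Δ` allocates `Δ·w_b` subscore points to behaviour `b`,
inverted to native units along the increasing branch from the 5th-percentile
reference; allocations exceeding a behaviour's remaining headroom spill over
to the others in weight proportion (logged). The round-trip
`score(ref + increments) − score(ref) = Δ` holds to 1e-6 and is enforced.

Minimum-dose tables search the composite-score gain curve (0.5-point grid,
finer than any increment reported) for the first score whose gain CI
excludes 0, then for the smallest score reaching each integer years-gained
target; each row is decomposed into native-unit increments, and
single-behaviour equivalents are solved on each behaviour's own
dose-response curve, reported missing with a reason when the target is
unreachable in isolation. The heatmap grid evaluates two behaviours over
their winsorised ranges (third at its median) through the composite-score
curve, zero at the 5th-percentile reference corner.

## 7. The synthetic cohort generator

The source of truth for this package's analyses is observational, so there
is no generative model to copy; `synthgen` defines a stand-in with the
structure the analysis assumes. **Every distributional choice is a declared
stand-in, not an estimate of any real cohort.**

* **Exposures**: Gaussian copula with modest positive correlations
  (0.10–0.15); normal sleep (7.6 ± 0.93 h — implied tertile cuts 7.2/8.0 h
  and winsorised bounds ≈5.8/9.4 h), lognormal MVPA (log-scale 3.44 ± 0.70 —
  tertile cuts ≈23/42 min/day, right-skewed like device-measured activity),
  normal DQS (53.75 ± 8.7, clipped to [0, 100] — cuts ≈50/57.5).
* **Mortality**: exponential event times with log hazard = baseline +
  0.065·(sleep − 7.5)² − 0.015·min(MVPA, 50) − 0.004·(DQS − 50) + covariate
  terms (age 0.09/y, male 0.35, smoking 0.5). The sleep quadratic is derived
  from the reported sleep dose-response (≈3.4 years gained at the nadir vs
  the ≈5.5 h 5th percentile ⇒ HR ≈ 1.30 over a 2 h deviation ⇒
  ln(1.30)/4 ≈ 0.065); the MVPA slope and knot reproduce a J-shape peaking
  near 50 min/day; the DQS slope is deliberately modest. Baseline
  0.006/person-year at the covariate reference matches a death rate of
  ≈4% over 8 years; recovery experiments raise it (0.02–0.03) so that a
  20,000-person cohort carries the study-scale ≈2,500 events.
* **Diseases**: five independent exponential first-incidence processes given
  the covariates, sharing the exposure effects at 0.5 attenuation, censored
  by death and follow-up. Incidence levels (CVD 0.024 … dementia 0.0012 per
  person-year) mirror the relative event frequencies of the five conditions.
* **Censoring**: administrative at 9 years with half the cohort censored
  uniformly between 4.5 and 9 years (staggered entry), giving a median
  follow-up near 8 years; optional exponential dropout.

What this does **not** emulate: measurement error and its regression
dilution, the ~5-year lag between diet and device measurements, dependence
between disease processes, age-varying hazards within follow-up, informative
censoring, and real national mortality. Passing tests therefore demonstrate
that the *estimators and tables recover a known truth of the assumed form* —
not that the substantive effect sizes generalise to any real cohort.

The rate schedules in `spanlife.rates` are likewise synthetic national-style
curves (Gompertz mortality anchored at m(65) ≈ 0.011/y, exponentially rising
incidence, logistic prevalence), generated programmatically and labelled as
such; real schedules can be supplied as CSV by path.

## 8. Numerical conventions and problem sizes

* One global seed spawns fixed per-stage substreams, so toggling one stage
  never shifts another's draws; identical (config, seed) runs are
  byte-identical.
* Degenerate inputs fail loudly: zero rate in the open life-table interval
  (infinite expectancy), constant exposure series, non-PSD correlation
  matrices, prevalence ≥ 1, mismatched age grids.
* The test suite and the analysis scripts run at reduced problem sizes
  chosen so each stochastic check has comfortable power at desk scale:
  n = 20,000 cohorts (≈2,500–4,300 events) for recovery checks, 200
  replicates for CI-coverage studies, 100 experiments × B = 500 for
  bootstrap calibration, 2,000-iteration Monte Carlo in the pipeline. The
  nadir-recovery check averages 6 replicate cohorts because a single
  replicate's argmin has sampling sd ≈ 0.2 h at that event count.
* The 27-category model needs ≥ 1 event per category; small cohorts run
  with the zero-event-drop behaviour and are flagged in the run report.

## 9. Known limitations

* No competing-risks subdistribution modelling; death censors disease
  incidence (the combined-exit framing makes this explicit for healthspan).
* No multistate recovery/remission; disease-free exit is absorbing.
* No multiple imputation (complete-case only), no time-varying coefficients,
  no frailty.
* The Šidák global PH test is conservative; a score-type global test would
  be sharper.
* Sullivan vs radix prevalence handling changes DFLE levels (not gains) by
  design; neither is asserted to be "the" published construction.
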