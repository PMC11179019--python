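# Methods

## The estimand and the data structure

The unit of analysis is the 1-year interval survival rate `r(s, c)`: the
probability that a patient of diagnosis cohort `c` who is alive `s − 1`
years after diagnosis survives one further year. Cohorts are mid-year
blocks — cohort `y` covers diagnoses from July 1 of `y` through June 30 of
`y + 1` — and follow-up is organised in whole-year blocks from the cohort,
not from each patient's own anniversary: a patient survives interval `s`
if still alive on December 31 of calendar year `c + s` (the mean of the
cohort's diagnosis dates is ~December 31 of `c`, so each interval tracks
one year of mean follow-up). A cell `(s, c)` is *observed* once follow-up
reaches that date; with cohorts 1997–2017 and death ascertainment through
2018-12-31 this yields the triangular observed region of 95 cells (70 with
period ≤ 2013, 25 with period 2014–2018). An alternative `mid_year` rule —
anniversaries at June 30 of `c + s + 1`, guaranteeing every patient a full
`s` years of potential follow-up — is available behind the
`anniversary_rule` switch; it shrinks the observed region because the
latest periods are no longer complete. The default is the rule that
reproduces the published cell geometry.

Censoring other than the administrative follow-up end is not modelled:
registries linked to national death records lose essentially nobody, so a
patient alive at the follow-up end survives every complete interval. Cells
with nobody at risk are flagged degenerate and excluded from fitting.
Cohort-approach 5-year survival is the product of the five interval rates;
a cohort's product is labelled all-observed, mixed, or all-predicted by
the provenance of its factors.

## The SPC model

Counts `n_survived(s,c)` out of `n_at_risk(s,c)` are modelled binomially
with a logit link (a complementary log-log option exists):

    logit r(s,c) = a_s + δ·(c − c̄) + g_p(p) + g_c(c),     p = c + s.

Because `p = c + s` exactly, the three linear trends are collinear — the
survival analogue of the age-period-cohort identification problem. The
package resolves it the standard way: only *estimable* quantities are
interpreted. The survivorship intercepts are saturated (one per level), a
single linear term carries the **net drift** (the sum of the period and
cohort slopes; which axis it is attached to is the identification
constraint, `drop-period-linear` by default), and `g_p`, `g_c` are
**curvatures**: restricted-cubic-spline bases whose columns are projected
off `{1, axis}` by least squares over the observed cells, so they carry no
constant and no slope. The projection coefficients are frozen at design
time and re-applied wherever the basis is later evaluated; since
subtracting an affine function preserves the spline's tail linearity, the
curvature functions are exactly linear beyond their boundary knots.
Extrapolation therefore means: survivorship intercepts persist, the net
drift continues at its fitted value, and curvature flattens to its
boundary slope. Both constraints span the same column space, so fitted and
predicted rates are constraint-invariant; the suite checks ≤ 1e-8 on the
logit scale, and a brute-force maximum-likelihood optimizer reproduces the
IRLS deviance to 1e-6 on small grids.

Knots default to 5 per axis at equally spaced quantiles of the observed
cell values (Harrell's convention), configurable per axis; `n_knots = 0`
drops an axis's curvature entirely (drift-only model, useful for tiny or
saturated designs). Fitting is iteratively reweighted least squares via a
binomial GLM, converged when the relative deviance change falls below
1e-10 (cap 100 iterations). All-survivor or all-death cells would push
coefficients to infinity; by default such cells receive a Haldane
continuity correction (+0.5 success and +0.5 failure, logged prominently);
`separation="none"` disables it.

## Validation and uncertainty

Holdout validation refits the model on cells with period ≤ a split year
(default 2013) and forecasts the later cells, scoring with the symmetric
mean absolute percentage error in its divide-by-mean form,
`(100/n) Σ |F−A| / ((|A|+|F|)/2)`, bounded in [0, 200] and zero for a
perfect forecast. The variant name is recorded in every report because
sMAPE definitions differ across the forecasting literature.

Confidence intervals come from a percentile bootstrap (2.5th/97.5th
percentiles across B replicates, default B = 10,000; studies in the test
suite and acceptance script run B = 200–500, scaled down). The default
resampling unit is the aggregate cell: each replicate redraws
`n_survived(s,c) ~ Binomial(n_at_risk, r_obs)` sequentially down each
cohort so that the redrawn survivors of interval `s` become the at-risk
count of interval `s + 1`, preserving the grid invariant; the model is
refitted and the targets (5-year products with observed factors from the
resampled grid, predicted factors from the refit) recomputed. This works
on deidentified aggregate data. A patient-level unit (resampling records
with replacement within each cohort) is available when records are
supplied. Replicates share the original cell coordinates, so the design
matrix is built once and reused. A simulation study (200 replicates at
B = 500 on the default scenario) puts empirical 95% CI coverage for the
2020-cohort forecast in the low-to-mid 90s percent; everything is
reproducible bit for bit under a fixed seed.

## Relative survival

Expected survival uses the Ederer II convention: for each interval, the
at-risk patients (those actually alive at the interval start) are matched
to a population life table `q(age, sex, year)` with ages advanced one year
per survivorship step from the age at diagnosis (age-group midpoints 50,
60, 70, 80 when only broad groups are recorded) and calendar year equal to
the interval's period. The interval relative rate is `r/e`; the 5-year
relative survival is the product of the five ratios, identically
`(Π r)/(Π e)`. Ratios may exceed 1 (patients outliving the matched
population), in which case the logit link is inapplicable and the SPC
design is refitted by weighted least squares of `log(ratio)` with at-risk
weights; the grid flags this condition. Ederer I and Hakulinen estimators
are not implemented.

## The synthetic generator

The generator exists so that every pipeline stage can be tested against a
known truth. Its ground truth is itself an SPC surface: survivorship
intercepts `a_s`, a net drift per cohort year, and pure-curvature
functions built from detrended restricted cubic splines (zero mean and
slope over the generation range, linear beyond their knots). The default
surface was calibrated once, by least squares against a realistic
trajectory: first-year survival ~0.42 sagging to ~0.40 around a 2003–04
changepoint and climbing to ~0.69 by the 2020 cohort, implying 5-year
survival of roughly 0.10 at the dip, 0.26 for 2013 and 0.44 for 2020 —
the shape of a registry in which screening and targeted therapy bend the
trend upward mid-series. Its curvature knots end in 2011, so the true
cohort effect is linear over the extrapolation region; this is the regime
in which "slopes continue, curvature flattens" extrapolation is unbiased,
and a 25-replicate study at registry scale recovers the true 2020-cohort
5-year survival with a median absolute error well under one percentage
point.

The default scenario mirrors a national lung-cancer registry: cohorts
1997–2017 with sizes ramping linearly from 5,762 to 14,529 diagnoses per
year, follow-up through 2018-12-31, and stratum mixes (sex, age group,
histology, stage) drifting linearly between published start and end shares
— adenocarcinoma 38.2% → 70.4%, male 70.1% → 55.1%, stage I rising to
29.3% of staged patients. By default the stratum labels drift without
shifting survival, so the pooled truth *is* the surface exactly; additive
logit shifts per label switch on stratum-specific survival, and the
mixture-exact truth (at-risk-weighted across strata, interval by interval)
is then available from `exact_grid` / `true_overall_s5`. Patient diagnosis
dates are uniform over the cohort block; deaths within a failed interval
are dated uniformly inside it (immaterial to interval counts). Population
life tables are deterministic Gompertz-style surfaces: hazard rising
exponentially with age, a male excess factor, and a mild secular
improvement per calendar year.

What the generator does **not** emulate: loss to follow-up, within-stratum
heterogeneity beyond the additive logit shifts, dependence between stratum
dimensions (they are drawn independently), period effects such as registry
practice changes (the default truth has no period curvature, though the
surface supports one), or calibration to any real registry's exact rates.
Passing tests therefore demonstrate correctness of the machinery under the
model's own assumptions — not that real registry data satisfy them.

## Numerical and design choices

- Grid counts are stored as floats; exact (expectation) grids and
  continuity-corrected counts are non-integer by construction.
- The observed-region rule, link, constraint, knots, separation handling,
  horizons (cohort 2020 / period 2025 by default) and bootstrap unit are
  all `ModelConfig`/function arguments, not globals.
- The 5-year product is computed in linear space; the log-additivity
  identity is tested to 1e-12.
- Whether a counterfactual fixed-mix series uses cohort-approach or
  period-style yearly stage series is up to the caller: the operation is
  defined generically over any aligned yearly series, since published
  stage-specific detail varies; the identity (fixed mix = factual mix
  year by year reproduces the factual series) pins the semantics.
- Default stratum weights for weighted forecasts come from the bundled
  2017 diagnosis-year counts, overridable.
- Problem sizes in the test suite and acceptance script (registry-scale
  recovery at 25 replicates; coverage at 200 × B=500) were chosen as the
  smallest studies that estimate the quantities of interest stably.

## Known limitations

- Lead-time bias is not corrected; earlier detection inflates survival
  without necessarily postponing death, and stage-mix counterfactuals
  only partially separate the two.
- Extrapolation inherits the linearity-beyond-knots assumption; a true
  trend break after the data end is invisible by construction.
- The relative-survival log-scale fit is weighted least squares, not a
  full likelihood, and its bootstrap is not wired up.
- Patient-level bootstrap rebuilds grids per replicate and is orders of
  magnitude slower than the aggregate unit.
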