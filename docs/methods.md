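# Methods

This note documents the statistical procedure the package implements, the
choices that were genuinely open, and what the synthetic-data experiments
do and do not demonstrate.

## Indicators from microdata

A woman is a user if she (or her partner) reports at least one current
contraceptive method. When several methods are reported, the method of
choice is the most effective: the ten modern methods in effectiveness
order (female sterilisation, male sterilisation, IUD, injections,
implants, pill, condom, diaphragm, emergency contraception, other modern),
then the four traditional methods in listing order (LAM, rhythm,
withdrawal, other traditional). Every modern method outranks every
traditional one; the ordering within the traditional block is a
convention, since only a rough effectiveness prioritisation is defined for
them.

Need among non-users has two branches. A woman who is pregnant or
post-partum amenorrhoeic is classified by that branch alone: she has need
iff she had wanted to delay or prevent that pregnancy. Any other non-user
has need iff she is exposed (partnered women are always considered
exposed; unpartnered women must have been sexually active in the past 4
weeks), fecund, and does not want a child within two years. Treating the
pregnancy branch as overriding, rather than as a pure logical disjunction
with the exposure branch, follows DHS-style practice: fecundity and
short-term fertility desire are not meaningfully defined during pregnancy
or post-partum amenorrhoea. Users are classified by their reported method
even if pregnant or amenorrhoeic (the user branch wins).

Cell estimates are survey-weighted proportions. Standard errors are
binomial on the Kish effective sample size n_eff = (Σw)²/Σw². At a
boundary estimate (0 or 1) the SE uses the continuity-shrunken proportion
p̃ = (x + 0.5)/(n_eff + 1), because a zero SE would give an observation
infinite weight downstream. Estimates are invariant to rescaling all
weights in a survey.

## Crosswalk for missing need items

Four questionnaire items can be absent survey-wide: fecundity, desire for
a child within two years, pregnancy/post-partum-amenorrhoea status, and
pregnancy wantedness. A survey missing an item still yields a need-share
estimate under permissive defaults — missing fecundity counts as fecund,
missing fertility desire as not wanting a child, missing pregnancy status
or wantedness skips the pregnancy branch. These defaults *define* what an
incomplete survey can compute; the crosswalk then removes the resulting
bias.

On complete surveys the need share is computed twice per survey-age
(-marital) cell, with the full rule and with the item withheld; the mean
paired difference (with-item minus without-item) per age group is the bias
delta, with delta_se = sd/√n_pairs. An incomplete survey's estimate is
shifted by the summed deltas of its missing items and clipped to [0,1];
its variance grows by the summed delta variances, so adjustment never
shrinks uncertainty. Age groups with fewer than two pairs fall back to the
pooled all-age bias; a component with no usable bias drops the estimate
with a logged reason.

The adjustment is additive on the proportion scale by default — the mean
difference is measured on that scale — with a logit-scale variant behind
the `scale` switch for users who prefer boundedness over interpretability.

## The three-stage estimator

All modelling happens on the logit scale. Estimates are clipped to
[0.001, 0.999] before transform, with delta-method SE conversion
se_logit = se/(p(1−p)); weights are 1/se_logit².

**Stage 1 — mixed-effects prior.** Weighted least squares of the
transformed estimates on a covariate suite plus an intercept per age band,
followed by method-of-moments empirical-Bayes nested random intercepts:
group means of residuals are shrunken by σ̂²_level/(σ̂²_level + σ²_e/n)
top-down (super-region, then region, then location), with the
between-group variance estimated by moments and floored at zero. Two
covariate suites are fitted — (a) mean years of female education and log
10-year lag-distributed income per capita, (b) SDI — and the suite with
the smaller in-sample RMSE on the transformed scale wins (ties go to
suite a). Predictions for locations with no data use a zero location
effect and inherit their region and super-region intercepts. A weighted
mixed model was implemented directly because the observation variances are
known (survey SEs), which off-the-shelf mixed-model routines here do not
accept; with random-effect variances of zero it reduces exactly to WLS.

**Stage 2 — space–time–age smoothing.** Residuals from the prior are
smoothed by locally weighted linear regression in year (degree
configurable, 0 or 1), with multiplicative weights:

* time: tricube in |Δyear|/h with half-window h = lambda_t × (year span);
  default lambda_t = 0.5, i.e. half the span. Smaller values localise; as
  lambda_t → 0 the trend passes through each observed year's
  residual-corrected value.
* age: exp(−omega × |Δage band|), default omega = 1.
* geography: observations from the same location get weight ∝ zeta, same
  region (1−zeta)·zeta, same super-region (1−zeta)²·zeta, otherwise
  (1−zeta)³; default zeta = 0.9, so a location's own data dominate
  wherever they exist.

The trend is the prior plus the smoothed residual. Targets whose effective
time design is single-year fall back to the weighted mean (the local line
is unidentified there).

**Stage 3 — Gaussian process.** Per location–age series over the year
grid, an exact GP with the stage-2 trend as mean function, Matérn-5/2
kernel (length-scale 10 years), and observation noise se_logit² on the
diagonal. The posterior mean and covariance are computed in closed form
and 1000 joint draws are taken per series; draws are inverse-logit
transformed, so every draw lies in (0,1). Series without data return the
prior GP around the trend. Cholesky factorisation escalates jitter
(0, 1e−10…1e−4 of the mean diagonal) and fails loudly naming the series if
the covariance is still not positive definite.

*Amplitude calibration.* The kernel amplitude is set per series from the
median absolute deviation (×1.4826) of the residuals against the *stage-1
prior*, floored at 0.3 on the logit scale. Both choices were made by a
coverage-calibration study on well-specified synthetic worlds: because the
stage-2 trend is itself fitted to the data, conditioning the GP tightly
around it double-counts the data and produces overconfident intervals
(~84% coverage of a nominal 95% interval with a 0.1 floor measured against
stage-2 residuals; ~96% with the adopted rule, with unchanged point
error). Both knobs are exposed in `StGprConfig`
(`amplitude_from`, `amplitude_floor`).

*Sequencing of dependent models.* Unmet-need models take the modelled CPR
posterior mean (logit scale) as an extra covariate; every unpartnered
model takes the corresponding partnered indicator's posterior mean.
Partnered models therefore run before unpartnered, and CPR before the
need-share model; the pipeline refuses violations of that order.

*Reproducibility.* Each GP series draws from a named substream derived by
hashing (location, age) into a `SeedSequence` with the global seed, so
results are independent of evaluation order. Substreams are per series
rather than per year-cell because the draws within a series are jointly
multivariate normal across years.

## Draw-level consistency

Nothing constrains independently modelled quantities to nest, so per draw:
the 14 method prevalences are multiplied by cpr/Σmethods (raking; if all
methods are zero with positive CPR, the mass is spread uniformly and
logged); mCPR is the raked modern total, hence mCPR ≤ CPR by construction;
unmet = need share × (1 − CPR), hence CPR + unmet ≤ 1; demand satisfied =
mCPR/(CPR + unmet), defined as 0 when no demand exists. Derived-quantity
intervals always come from the derived draws — transforming interval
endpoints is wrong whenever the map is non-linear or multivariate, and a
test demonstrates the difference on skewed draws.

## Aggregation and reporting

All-women values are π·partnered + (1−π)·unpartnered per draw, with π the
partnered proportion; derived indicators are recomputed *after*
aggregation of their components (aggregating demand satisfied directly is
incorrect and a test constructs the counterexample). Age aggregation uses
population weights; age standardisation uses the global age structure of
the reference year (2019), frozen thereafter. Location aggregation is
population-weighted and associative. Changes over 1970–2019 are
within-draw differences ×100 (percentage points); sharing draw indices
across years preserves temporal correlation and narrows change intervals
relative to independent endpoints, which is the intended behaviour. User
counts are prevalence × population summed per draw; FP2020 accounting
reports additional modern users between 2012 and 2019, the shortfall
against the 120-million goal, and each country's annualised mCPR change
against a user-supplied target schedule within ±0.2 percentage points.
Report tables print percentages at one decimal with half-up rounding.

SDI categories: low [0, 45.5), low-middle [45.5, 60.8), middle
[60.8, 69.0), high-middle [69.0, 80.5), high [80.5, 100].

## SDI meta-regression

Expected-value curves of mCPR or demand satisfied against SDI per age band
use a weighted (1/se²) cubic B-spline with a second-difference roughness
penalty (default 1.0) and least-trimmed-squares robustness: fit, drop the
⌈γn⌉ observations with the largest weighted absolute residuals, refit, and
iterate to a fixed inlier set (cap 100 iterations, flagged if not
reached). Interior knots default to the SDI category boundaries
{45.5, 60.8, 69.0, 80.5}, tying the spline's flexibility to the scale's
own partition; default γ = 0.1. With γ = 0 the estimator is exactly
ordinary weighted penalized-spline regression, which a test verifies
against an independently coded solver. This is a deliberate simplification
of a full Bayesian regularised-trimmed meta-regression: same response,
predictor, weighting and trimming semantics, no ensemble splines or
priors, and no posterior uncertainty for the curve. An optional monotone
constraint projects the fitted curve onto non-decreasing curves by
pool-adjacent-violators.

## Synthetic data generator

The generator is the package's ground truth, not a fixture: logit-linear
prevalence surfaces in the same covariate suites the model uses (so the
stage-1 model is well-specified by default, making parameter recovery
attributable), nested location/region/super-region random intercepts
(SDs 0.25/0.15/0.15), and a smooth sinusoidal temporal wiggle (amplitude
0.12 logit, period 15–30 years) so the truth is not exactly linear in
time; a `misspecify` switch adds a covariate-free sinusoid for robustness
tests. Method mix is a Dirichlet-weighted split of CPR per location whose
log-weights drift linearly in time (modern up, traditional down),
emulating the traditional-to-modern transition and exercising the raking.
Survey weights are lognormal(0, 0.25) normalised within survey; 5% of
users report a second, lower-priority method. Need components are drawn
so the cell's true need share among non-users is matched in expectation
(the need indicator is drawn first, then flags consistent with it);
missingness is assigned survey-wide. Components of users are drawn
independently of the method, a simplification with no downstream effect
since the user branch dominates classification.

What the generator does *not* emulate: cluster/stratified sampling designs
(single-stage weighted sampling only), non-additive or
covariate-dependent missing-item effects, reporting/recall error in the
method question, subnational geographies, and demographic feedback between
prevalence and population. Passing recovery tests therefore demonstrate
internal correctness of the estimator under its own assumptions, not
performance on real surveys.

## Validation experiments and problem sizes

* Full-pipeline CPR recovery: 20 locations (2 super-regions × 2 regions ×
  5), 50 years (1970–2019), 7 age bands, 2 marital strata, one survey per
  location every 5 years with n = 2000 per age–marital cell, 1000 draws;
  50 independent worlds in the test suite (10 in the reproduction
  script). Scored by the pooled median absolute error of the posterior
  mean (percentage points) and 95% UI coverage of the truth.
* Crosswalk recovery: an installed wants-child component effect of 0.05 on
  the need share, 20 complete surveys of n = 1500 per cell; the pooled
  with-minus-without delta must sit within 3 delta_se of −0.05.
* Trimming: 120 points from a smooth quadratic truth, 10% gross outliers
  (±0.4–0.8), γ = 0.1; success means the trimmed set equals the corrupted
  set exactly, over 100 replicates.

## Numerical choices

* Logit link with clipping at [0.001, 0.999]; delta-method SE conversion.
* Suite tie-break: suite a. Singular stage-1 designs fail naming the
  collinear columns; fewer observations than fixed effects fail.
* Local-linear smoother falls back to the weighted mean when
  den/(S0·S2) < 1e−8 (effectively single-year support).
* GP jitter escalation as above; draws generated per series substream.
* Raking of an all-zero method vector with positive CPR spreads uniformly.
* Quantiles use linear interpolation of order statistics (numpy default);
  the point estimate is the draw mean.
* Report rounding is decimal half-up at one decimal.

## Known limitations

* Standard errors are binomial with the Kish effective sample size; no
  Taylor-linearised cluster-robust SEs.
* ST-GPR hyperparameters (lambda_t, omega, zeta, kernel length-scale,
  amplitude rule) are fixed defaults exposed in config, not selected by
  cross-validation.
* The stage-2/stage-3 data reuse is handled by amplitude calibration, not
  by a joint model; coverage guarantees are empirical, on the synthetic
  design above.
* The crosswalk assumes additive, age-specific, survey-independent item
  effects.
* The meta-regression reports no curve uncertainty.
* Marital aggregation takes the partnered proportion as an input series
  (optionally modelled by the same machinery); the default pipeline uses
  the generator's surface.
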