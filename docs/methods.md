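# Methods

## Skin-tone quantification

Each patient contributes several (by default four) spectrophotometer
readings of CIE L*, a*, b* from the dorsal hand. The individual typology
angle is computed from the per-patient **median L\* and median b\***, then
the angle — not the median of per-reading angles — via the two-argument
arctangent, so the value stays defined for non-positive b* (range
(−180°, 180°]) while agreeing with arctan((L*−50)/b*)·180/π on the
physiological domain b* > 0. The within-patient standard error is the
sample SD of the per-reading angles divided by √n (zero when n = 1);
this is a conventional choice, made here because no standard estimator
is mandated for this quantity. Even-count medians are midpoints of the
two central order statistics. a* is carried through I/O but enters no
computation: ITA deliberately excludes the erythema axis most affected
by cutaneous blood flow.

Category boundaries (very light ≥55°, light [41°, 55°), intermediate
[28°, 41°), tan [10°, 28°), brown [−30°, 10°), dark <−30°) are half-open
with the lower bound inclusive, so e.g. −30° is brown and 55° is very
light.

## The model suite

All seven metrics share one covariate structure: pulse-oximeter model
(categorical, first level in sort order as reference), ITA, SaO₂ and
haemoglobin as restricted cubic splines, device × ITA and device × SaO₂
interactions, an ITA × SaO₂ interaction, and site fixed effects.
Design choices where the field offers several conventions:

- **Splines.** Harrell-parameterised restricted cubic splines, 4 knots
  by default at the 5/35/65/95% sample quantiles. Four knots balance
  flexibility against the ~10 800-observation scale; the count and
  explicit knot locations are configurable (`DesignSpec`). Quantile
  placement concentrates knots where the data are; when the clinically
  critical range lies in a thin tail (low SaO₂ for the threshold
  models), explicit tail-covering knots fit that region better — this is
  exposed as an option, not the default.
- **Spline × spline interaction** (ITA × SaO₂) is the tensor product of
  the two restricted bases, the standard realisation.
- **Fraction scale.** Saturations are divided by 100 before fractional
  modelling so squared deviations and squared differences also lie in
  [0, 1]; outputs are converted back to percentage points.

**Fractional probit** (bias, precision, A_RMS): E[y|x] = Φ(x′β) fitted
by Bernoulli quasi-ML — a binomial GLM with probit link applied to
fractional outcomes (statsmodels' IRLS). Covariance is the cluster
sandwich with patient-level score aggregation, robust to arbitrary
within-patient correlation; with every observation its own cluster it
reduces to the heteroskedasticity-robust estimator up to the usual
finite-sample factor. The precision model regresses the squared
deviation of the observed fraction from the bias model's fitted mean;
the A_RMS model the squared SpO₂−SaO₂ difference; both surfaces are
reported as 100·√(prediction).

**Random-intercept logistic** (FNR/FPR, occult): y_ij ~
Bernoulli(expit(x′β + u_i)), u_i ~ N(0, σ²) per patient; sites enter as
fixed effects (a single-level approximation of patients within sites).
The marginal likelihood uses adaptive Gauss–Hermite quadrature — nodes
recentred and rescaled at each patient's posterior mode and curvature —
with 15 nodes by default (≥7 enforced; doubling nodes moves the
log-likelihood by <1e−4 on recovery datasets). Maximisation is L-BFGS-B
on (β, log σ) with the analytic gradient; log σ is bounded in
[log 1e−3, log 20] so the no-heterogeneity boundary is reachable.
The covariance is the inverse observed information (central finite
differences of the analytic gradient). No installed Python package
provides this estimator; the implementation is cross-checked in the
test suite against R's lme4::glmer with nAGQ = 15, agreeing to ~3
decimals in coefficients, SEs and the random-effect SD. Predictions are
population-averaged: expit is integrated over the random-effect
distribution by Gauss–Hermite (21 nodes).

**Marginal standardisation.** A grid point fixes device/ITA (and SaO₂
for the three-way surfaces); haemoglobin, site and any unfixed covariate
come from each row of a standardisation sample (all complete
observations by default; a seeded subsample where runtime matters).
Predictions are averaged on the response scale; the delta method
propagates the parameter covariance through the average (including
d/d log σ for random-intercept models); 95% limits are Wald on the link
scale transformed back, so probabilities stay in [0, 1]. FNR surfaces
marginalise 1 − P(SpO₂ ≤ t) over the hypoxaemic stratum (SaO₂ ≤ 92),
FPR surfaces P(SpO₂ ≤ t) over the non-hypoxaemic stratum, occult
hypoxaemia P(SpO₂ > 92) over the severe stratum (SaO₂ < 88). Grid
points outside the fitted covariate range are flagged as extrapolation.

**ROC regression.** Cases are observations with SaO₂ ≤ 92. Each case's
placement value is the fraction of same-device controls with lower SpO₂
(ties counted half). The binormal model ROC(u) = Φ(a + b·Φ⁻¹(u)) is fit
as a probit GLM on case pseudo-observations 1{PV ≤ u} over the FPR grid
u ∈ {0.02, …, 0.98}, with intercept terms in device, linear ITA (a
spline is optional) and device × ITA; AUC = Φ(a/√(1+b²)). Haemoglobin
and site are deliberately absent from this model. Confidence limits are
percentile intervals from a patient-level (cluster) bootstrap, 200
resamples by default. A class floor of 10 observations per class per
device guards against degenerate placement distributions.

**Skin-tone contrasts** are evaluated at ITA −44° vs 46° (representative
dark and light tones). For model-backed surfaces the difference uses the
stored prediction gradients and the full parameter covariance, so the
correlation between the two points is respected; rate metrics add a
ratio with limits on the log scale. The bootstrap-based AUC surface
falls back to an independence approximation.

## The synthetic-data generator

The generator emulates a multicentre ICU accuracy study; it is the test
bed for every model above, and its defaults are the study conditions.

- **Structure:** 900 patients over 24 sites; each site is allocated a
  fixed pair from the five device models; 6 arterial samples per patient,
  each read by both devices → 10 800 pairs.
- **Skin tone:** category mixture 12.3 / 15.4 / 21.9 / 33.8 / 16.6 %
  (light + very light, intermediate, tan, brown, dark), uniform within
  bands, the dark band truncated at −60°. Spectrophotometer readings are
  synthesised on the CIELAB plane at a radius of 16–30 units from
  (L* = 50, b* = 0) with isotropic reading noise (SD 2.7 units) tuned so
  the median within-patient ITA standard error is ≈3°.
- **SaO₂:** patient-level deficit from a two-component lognormal mixture
  (a majority healthier and a minority sicker component) plus a
  stationary AR(1) within-patient process (ρ = 0.5), clipped to
  [80, 100]. The six constants were calibrated once, by least squares
  against the intended marginal — rounded bands <88%: 1.7%, 88–92%:
  14.1%, 93–94%: 16.6%, >94%: 67.6%; median 96 (IQR 94–97) — and then
  frozen as defaults.
- **Haemoglobin:** lognormal with median 101 g/L, IQR 86–117.
- **Devices:** mean reading = SaO₂ + slope·(tipping point − SaO₂) +
  gradient·(46° − ITA)/90° + patient effect, plus Gaussian noise
  (SD 2.0 pp), rounded to integers and clipped to [70, 100] as fingertip
  devices report. The five default profiles span tipping points 91–97%
  and tone gradients 0.6–1.5 pp per 90° of ITA. The patient random
  effect (SD 1.5 pp) and the noise SD are this package's assumptions —
  chosen as plausible for low-cost fingertip devices — since no
  published values exist for them.

What the generator does **not** emulate: perfusion and motion artefacts,
temperature effects, device drift, informative site differences,
correlation between skin tone and illness severity, and non-Gaussian
reading noise. Passing tests therefore demonstrate that the estimators
recover known truth under a realistic but idealised error structure, not
that any particular clinical dataset would show these effect sizes.

Note that rounding adds ≈1/12 pp² of variance and clipping at 100
materially reduces reading variance at high SaO₂ (at SaO₂ = 96 several
percent of draws clip). The package's validation uses exact Monte-Carlo
truths computed from the generator primitives rather than the naive
closed forms, which ignore censoring.

## Power simulation

The planning design: per replicate, 900 patients × 12 pairs with the
device SaO₂-dependence active but all tone gradients replaced by one
linear term scaled so the bias difference between ITA 28° and −30°
equals the effect size; measured skin-tone noise is omitted (its ~3°
SE attenuates a ~30° between-patient SD by ≈1%, negligible). The test
is a two-sided Wald test of the linear ITA coefficient in a fractional
probit of SpO₂/100 on device, a restricted cubic spline in SaO₂, and
ITA, with patient-clustered errors, at α = 0.05. Power is the rejection
fraction over 200 replicates with a Wilson interval. At the design
effect of 1.5 pp the estimated power is 100%; at effect 0 the rejection
rate is consistent with the nominal 5% within two Monte-Carlo standard
errors (cluster-robust Wald tests are mildly anti-conservative in finite
samples).

## Numerical conventions and degenerate inputs

- Random draws all flow from a single seeded generator
  (`numpy.random.default_rng`); the default seed is 20220601, every
  stochastic routine accepts an explicit one, and replicate seeds are
  spawned through `SeedSequence` (kept below 2³¹).
- Rounding of synthetic readings is half-away-from-zero, matching the
  descriptive-table convention offered for SaO₂ (`round_sao2=True` in
  the threshold diagnostics; unrounded comparison is the default).
- Undefined empirical rates (empty strata) are NaN with a warning,
  never silently zero. Occult hypoxaemia defaults to observation level;
  a per-patient variant (any qualifying pair) is available.
- Rank-deficient designs raise with the offending columns named;
  non-convergence is flagged on the result, not raised.
- Problem sizes in the analysis scripts and tests (grid steps, subsample
  sizes, replicate counts, bootstrap draws) are chosen to keep each run
  in minutes on a single core while leaving Monte-Carlo error well below
  the effects being demonstrated.

## Known limitations

- The FNR/FPR/occult marginalisation is only as good as the logistic
  tail: in the severe-hypoxaemia stratum (SaO₂ < 88, ~2% of data) the
  population-averaged logistic flattens relative to the true
  probit-normal process, so model-based occult rates sit above raw
  stratum frequencies (both small); `overall_occult_rate` documents and
  quantifies this directly.
- Site effects in the logistic models are fixed, not a second random
  level; crossed or nested random structures are out of scope.
- The ROC bootstrap refits the placement-value GLM per resample; its
  cost grows with the case count, so bootstrap replicates are the main
  runtime dial for large datasets.
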