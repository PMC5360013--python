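# Methods

This note documents the models, defaults and numerical choices behind
each stage of the pipeline, what the synthetic world does and does not
emulate, and the known limitations.

## Solar geometry

Declination and the equation of time use the compact Meeus formulation
(geometric mean longitude/anomaly, equation of centre, corrected
obliquity); zenith angles follow from the hour angle without refraction.
Accuracy is ~0.01° in declination and a few seconds in the equation of
time over the tag era — negligible against minutes-scale twilight noise.
Twilight times invert the day-length equation iteratively so declination
and the equation of time are evaluated at the event itself; this matters
at high latitude, where within-day declination drift moves the raw
sunrise/sunset midpoint by several minutes (≈1° of longitude).

## Synthetic world

The generator is the ground truth for every recovery test.

* **Weather** — deterministic structure (latitudinal temperature
  gradient −0.5 °C/°lat, 10 °C seasonal cycle, 3 °C diel cycle,
  level-dependent zonal winds) plus AR(1)-in-time (coefficient 0.8),
  Gaussian-smoothed-in-space anomalies on a 2.5° grid, 6-hourly. This is
  the cheapest field with non-trivial space-time autocorrelation; it has
  no orography, fronts or cloud radiation, so environmental covariates
  are smoother than reality.
* **Agent** — each stopover evening the bird departs with probability
  logit⁻¹(β·x) on z-scored sunset covariates (fixed standardisation
  constants define the z-scale); flight nights draw log10 nightly
  distance from a linear model (intercept 2.45 → ≈280 km/night, residual
  SD 0.15), capped by 10 h at 13 m/s airspeed, moving along the great
  circle to the goal. Travel bouts persist with probability 0.45 per
  night. The defaults were calibrated once so that cohort-level schedule
  statistics (≈45% of bird-days on travel, ≈280 km per flight night, a
  zonal-then-southward descent from a 65.6° N breeding site, terminal
  arrival at the wintering site) match the published field statistics
  for this system; they are study conditions, not free parameters.
* **Light** — the light response is logistic in solar elevation,
  calibrated so the 1.35 threshold is crossed exactly at the configured
  zenith (96.8°), which makes the threshold method exactly invertible in
  the noise-free limit. Shading draws an independent log-normal delay
  per twilight (meanlog 2.2, sdlog 1.0, minutes) that delays apparent
  sunrise and advances apparent sunset — strictly one-sided, as physical
  shading must be. Logger cadence is 5 min, bounding the discretisation
  error at ±2.5 min. Real shading is temporally correlated (weather,
  habitat); the generator's independence assumption makes the noise
  *harder* to smooth than correlated noise of the same magnitude, so
  recovery results are conservative in that respect, but passing tests
  say nothing about clock drift, sensor degradation or habitat-specific
  biases absent from the generator.

## Twilight detection and editing

Crossings of the threshold are linearly interpolated between bracketing
samples. Editing follows the standard >30-min rule: each event is
compared against a robust local trend (Theil–Sen line through the 5
nearest same-type neighbours, in time-of-day space, which removes the
seasonal and travel drift). Deviations beyond the limit are snapped to
the trend when the neighbourhood is *stable*, and discarded otherwise.
Stability is operationalised as "at most one gross outlier among the
neighbours" (second-largest |residual| ≤ limit): the naive reading
(neighbour range ≤ 30 min) is almost never satisfied under the fitted
shading model itself — the range of five log-normal(2.2, 1.0) draws
typically exceeds 30 min — and would silently disable the rule, while a
purely robust spread never triggers the discard branch. The chosen form
reproduces all three observed behaviours: smooth series untouched, a
single displaced event adjusted, a displaced multi-day block discarded.
Events within half a window of the series ends are kept unflagged.

## Threshold positions and calibration

Longitude comes from apparent solar noon versus 12:00 UTC corrected by
the equation of time; latitude solves the day-length equation at the
calibrated zenith, by closed form plus a Newton polish on the predicted
event times. Roots pinned at the poles or failing the residual check are
reported missing (the equinox degeneracy), with longitude still valid.

Calibration at a known site estimates the zenith as the angle at which
the median predicted twilight matches the observations — exact in the
noise-free limit. The twilight-error model (meanlog/sdlog of the
one-sided errors, floored at 0.1 min before taking logs) is fitted
relative to a reference zenith; because median-matching absorbs the
median shading delay into the zenith, the error model should be fitted
against the known light-threshold zenith when one is available (the
`zenith=` argument), mirroring the field practice of pooling the error
model across individuals while fitting the zenith per individual.

## Bayesian track refinement

State: one location per sunrise–sunset pair (the midday position).
Log-posterior per state: log-normal densities of the two one-sided
twilight errors (computed exactly in the time domain from per-event
declination/equation-of-time constants), gamma log-densities of the
great-circle speeds to the neighbouring states, and the log mask weight
(land:sea 4:1 by default; weights only matter up to scale). The speed
denominator is half the elapsed time between midday states
(`flight_fraction = 0.5`): a nocturnal migrant covers the inter-state
displacement within the overnight window, and the gamma prior
(shape 0.7, **rate** 0.05 h/km — mean 14 km/h, monotone decreasing
density, consistent with a ≈50 km/h airspeed tail) is calibrated on
twilight-to-twilight speeds. The "scale 0.05" sometimes quoted for this
prior is the R `dgamma` *rate* argument; read as a scale it would put
all mass below 1 km/h.

Sampling is Metropolis-within-Gibbs with a checkerboard (even/odd)
update so each sweep is fully vectorised; Gaussian proposals carry
separate latitude/longitude scales (their posterior widths differ by
almost an order of magnitude near equinoxes), adapted during burn-in to
a 20–40% acceptance rate. Each sweep also proposes a few contiguous
block translations (random run of states moved by a common offset,
adapted step): stopover clusters are bound together by the movement
prior, and per-state updates alone cannot slide a cluster along a
weakly constrained direction such as the equinox latitude. Defaults: 2 chains, 5,000 burn-in, 15,000
kept, thin 5; recovery tests use shorter chains (3,000/6,000/5), which
we verified agree between chains to <0.1° per state. Non-finite
initial states fall back to threshold positions with equinox gaps
interpolated. On a three-state toy problem the sampler's marginals match
a brute-force lattice posterior to <0.1°; the lattice comparison uses a
shape-2 movement model because the default gamma's integrable
singularity at zero speed cannot be represented on a lattice.

Under the full shading model a 40-day autumn migration is recovered with
posterior-median RMS error ≈150–220 km depending on the noise
realization (pooled 190 km over three realizations), at the upper edge
of the 100–200 km envelope conventionally quoted for the method — as
expected, since the fitted shading distribution is itself conservative.
Within ±10 days of an equinox, day length carries no latitude
information — and a long stopover spanning an equinox inherits the
degeneracy, because its latitude rests on a handful of edge days with a
one-sided (hence skewed) error model. The pipeline reports this through
inflated posterior latitude SDs, which downstream models use as inverse
weights; positional accuracy claims therefore apply to the days the
pipeline itself declares well-determined (latitude SD below ~3°).

## Schedule

Changepoint probabilities: per same-type series, each event's first
difference against its predecessor is scored as a two-segment versus
one-segment mean comparison at the minimal window and pushed through its
null distribution, with the null noise scale estimated robustly from the
global median absolute first difference (stationary stretches dominate
the median). The minimal window is deliberate: a wider window absorbs
earlier steps of a multi-night travel run into the null segment and goes
blind exactly where sensitivity is needed. Day-level evidence combines
the bird-day's two events (sunrise + following sunset, *not* the UTC
date, which splits a western-hemisphere pair) by Fisher's method —
latitude and longitude displacements can partly cancel in one event but
rarely in both — and is attributed to the previous evening, the
departure evening. Days above the 0.75 quantile of day evidence are
movement; quiet runs of ≥2 days are stationary periods; consecutive
periods within 200 km merge iteratively to a fixed point (day-weighted
mean locations, circular-mean longitudes).

Season rules: autumn onset is the start of the flight run preceding the
first stationary site >2° of longitude from the breeding area (or the
last day of the subsequent flight run when all stopovers are closer);
autumn termination is the first day of the wintering period, generalised
to the longest stationary period away from the breeding region; spring
onset is the flight run preceding the first period 200 km from the
wintering ground; spring termination truncates at the last estimable
location when polar daylight ends the track. Within phenology metrics,
days inside a stationary period take the period's mean location, so
positional jitter at a fixed site is not counted as distance travelled;
the identity total speed × duration = total distance holds exactly by
construction.

## Environmental annotation

Interpolation is bilinear in space and linear in time (no time
extrapolation; out-of-hull queries raise, naming the axis).
Precipitation is the 7-point hourly sum of the interpolated rate over
±3 h around local sunset. Flow assistance uses the airspeed formulation
with z = 13 m/s and the initial great-circle bearing to the seasonal
goal as the preferred direction (wind "blowing toward" = atan2(u, v));
it is missing when the crosswind exceeds the airspeed at all four
pressure levels, and the best (maximum) level is used otherwise. For
travel days the covariate is the mean of hourly best-level flow along
the great-circle path to the next location (8 hourly steps from one
hour after sunset), interpolated in space and time so no grid-cell
discontinuities occur. Stopover rows use the stopover location; the
departure response is 1 only on a stopover's last evening. Rows with
missing flow assistance are flagged and dropped listwise at fit time,
with the count reported.

## Mixed models

Numeric covariates are z-transformed (scaling stored for
back-transformation); VIFs are computed as 1/(1−R²) from regressing
each predictor on the rest, iteratively dropping the worst until all
fall below 2 (exact ties drop the later-listed predictor).

The departure model is a logistic regression with one random intercept,
fitted by maximum likelihood with adaptive Gauss–Hermite quadrature
(15 nodes; per-group modes by Newton iteration, vectorised across
groups). The likelihood matches direct numerical integration to <1e-6.
Coefficient covariance is the inverse numeric Hessian; when the variance
sits at its boundary the flat log-σ direction is profiled out rather
than inverted. A Pearson dispersion scale and variance-partition
marginal/conditional R² (logit residual variance π²/3) are reported.
Complete separation is detected as runaway coefficients (|β| > 8 on the
z-scale) and raised as an error; fewer than two groups falls back to a
fixed-intercept fit with a warning.

The travel-speed and total-speed models are linear mixed models with one
random intercept and optional observation weights (inverse latitude SD),
fitted by REML with the variance ratio profiled — the Woodbury identity
reduces each evaluation to weighted sums, so the optimisation is
one-dimensional and exact fits (σ² → 0) are handled by flooring the log.
The unweighted fit agrees with the standard mixed-model implementation
in statsmodels to 1e-5 in coefficients, SEs and variance components.

Uncertainty uses the flat-prior posterior simulation convention: 2,000
draws — σ² from its scaled inverse-χ², coefficients from the
multivariate normal around the estimates (scaled by the σ draw for
gaussian fits; the asymptotic covariance on the link scale for
binomial) — with the 2.5/50/97.5% quantiles as interval and estimate.
Empirical 95% interval coverage, pooled over coefficients across 200
replicate fits at n = 5,000 with 30 groups, is 0.93 (binomial) and 0.94
(gaussian). With very few groups (the two-deployment-year situation) the
intercept undercovers — a property of the asymptotic method itself, not
of this implementation, which matches lme4's estimates and standard
errors to four decimals; slope coverage is unaffected.

Effect displays summarise an interaction's two variables into five
equal-count categories (category value = within-bin mean), hold the
other covariates at their means, and suppress cells without joint
observed support rather than extrapolate.

## Problem sizes in the test-suite and acceptance script

Recovery and coverage studies run at sizes chosen to make the checks
sharp but repeatable on a single CPU: the 40-day refinement recovery
pools three shading realizations; schedule recovery uses 100 (tests) or
60 (script) seeded stopover/travel patterns with 3-min twilight jitter
(the regime of an edited series — segmentation quality under full
uncorrected shading is governed by the refinement results above);
mixed-model coverage uses 200 (tests) or 100–200 (script) replicates at
n = 5,000. The end-to-end check simulates a 6-bird cohort through the
complete pipeline and verifies the generator's departure coefficients
on the raw (per-unit) scale, where the generator's fixed
standardisation and the fit's sample standardisation are commensurable.

## Known limitations

* The twilight-error and movement priors are treated as known in the
  refinement recovery tests; with tag data they must come from the
  calibration stage, adding (quantified) uncertainty.
* The changepoint probabilities are an explicit, testable statistic;
  they are not numerically identical to any external package's internal
  scores, and equivalence is claimed only at the level of recovered
  schedules.
* Latitude near equinoxes is unidentifiable from day length; the
  pipeline flags it, inflates latitude SDs and truncates spring tracks
  at polar daylight, but cannot conjure the missing information.
* The synthetic weather has no fronts or mesoscale structure, so the
  flow-assistance signal is smoother than over real terrain; model
  recovery under rougher covariates would have wider intervals but the
  estimators are unchanged.
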