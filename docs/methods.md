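# Methods

This note documents the models, estimators and numerical choices behind
`marshwave`, what the synthetic-data generators do and do not emulate, and
the known limitations of each statistic.

## 1. Degree days and the spring-onset statistic

**Daily GDD.** One sine period is fitted to each day's `(tmin, tmax)` and
the area above the base temperature (default 10 °C, the minimum for
*Spartina* growth) integrated analytically.  With mean
`m = (tmin+tmax)/2` and amplitude `a = (tmax−tmin)/2`:

* `tmin ≥ base` → `m − base`;
* `tmax ≤ base` → `0`;
* otherwise `((m−base)(π/2−θ) + a·cosθ)/π`, `θ = arcsin((base−m)/a)`.

The implementation agrees with adaptive quadrature of
`max(0, T(t)−base)` to better than 1e-6 degree-day and satisfies the
closed form `a/π` when `m = base`.  No upper cutoff is applied.

**Climatologies.** Dates are handled as (year, day-of-year), 1-based,
with leap days dropped so every year has 365 points.  Gaps of ≤ 3 days in
station records are filled by linear interpolation of `tmin`/`tmax` (with
a warning); longer gaps are an error.  A climatology is the pointwise
multi-year mean of per-year cumulative series.

**Jerk and onset.** The cumulative curve is smoothed by a centred moving
average of halfwidth `h` (a `GDDConfig` parameter), then differenced with
the 5-point third central difference at 1-day spacing
(`(s[d+2] − 2s[d+1] + 2s[d−1] − s[d−2])/2`, exact for cubics); the first
and last `3+h` days are undefined.  Spring onset is the argmax of the
jerk within day-of-year 1–181 (ties → earliest), excluding autumn
deceleration features.  Onset shifts between two averaging periods are
tested with the classical matched-pairs t test on per-station onset
differences (identical inputs report t = 0, p = 1).

*Numerical behaviour worth knowing.*  The single-sine daily GDD, viewed
as a function of the daily mean at fixed amplitude, has integrable
curvature singularities where the mean crosses `base ± diurnal_range/2`.
On a perfectly smooth sinusoidal climate this puts **two** near-equal
spring peaks in the jerk, roughly `diurnal_range / |dT/dd|` days apart; a
moving-average halfwidth wide enough to span that separation (25 days for
the default generator climate) merges them into a single spring peak and
makes the onset monotone in latitude.  Conversely, the third difference
amplifies noise severely: under realistic day-to-day temperature
variability the estimator is noise-dominated even for 30-year
climatologies.  The statistic is therefore meaningful on climatological
*normals* (smooth multi-year means), which is how the pipeline uses it
(noise-free generator climate, halfwidth 25); `GDDConfig` itself defaults
to halfwidth 7 for smoother, pre-averaged inputs.  This is a property of
jerk-peak onset detection generally, not of this implementation.

## 2. Geolocator event detection

**Twilights.** Rises/sets are upward/downward crossings of a light
threshold (default 1 on the 0–64 logger scale), linearly interpolated
between samples.  The outlier rule removes an event whose clock time
deviates > 35 min from the median clock time of same-kind events within
±2 days (single pass; clock comparison unwrapped on a circular 24 h
scale).

**Positions.** Longitude from equation-of-time-corrected local solar noon
(the rise/set midpoint): `lon = (720 − noon_utc_min − eqtime)/4`.
Latitude solves the sunrise equation for the observed day length at a
configurable zenith (default 96°, civil twilight), via bracketed root
finding in [−89.5°, 89.5°]; latitude is NaN when day length is within 15
min of 12 h or no root exists, and is additionally suppressed within ±40
days of each equinox (longitude is kept).  Zenith calibration is out of
scope; the solar ephemeris is the standard low-precision NOAA expansion
(~1 min accuracy in event times).

**Flights.** Maximal runs of consecutive dry conductivity samples with
duration ≥ `min_dry_hours` (default 20 h).  Sedentary wet/dry texture
produces only sub-hour dry runs, while sustained migratory flights last
about 1–4 days, so the threshold separates cleanly; the value is a
declared parameter, not an empirical estimate.  Run boundaries are first
dry sample → one sample past the last, so an isolated scripted flight is
recovered to within one sampling interval.

**Incubation.** A sitting bird shades the leg sensor, producing dark
periods in daylight.  Daylight spans are built by splitting the
*unfiltered* twilight sequence at set→rise gaps of ≥ 4 h ("true nights")
and taking the first rise to the last set of each solar day — grouping by
UTC calendar date fails on the US east coast, where sunset falls past UTC
midnight in summer, and the 35-min filter would strip exactly the
shading-induced crossings that carry the signal.  A bout is a dark run of
≥ 1 h strictly inside a span; nest initiation is the first day opening
≥ 3 consecutive days with a bout, which prevents single shading artefacts
from defining a nest.

**Event tables.** Flights separated by < 30 days (stopovers) are grouped
into one migration.  A migration is northbound if the median longitude in
the 6-day window after its last flight moved ≥ 5° closer to the
deployment site than the window before its first flight, southbound if it
moved away; spring departure / breeding arrival / fall departure / winter
arrival are the group boundaries' days-of-year, and durations are exact
differences of their bounding events (wintering wraps the year end).
Missing phases stay `None`.

## 3. The green-wave stage model

**Standardization.** Within each study(-year), stage =
`biomass_mean / max(biomass_mean)` — "percent of total seasonal biomass"
with the seasonal total read as the within-study maximum of mean standing
biomass, which makes stage a bounded green-up fraction and the model
scale-free (any rescaling of a study's absolute biomass cancels).  Stage
SEs scale the same way; weights are `1/stage_se²`.  Stages may exceed 1
under noise and are deliberately not clipped.

**Estimation.** The mean model
`stage = β₀ + β_d·doy + β_l·lat + β_dl·doy·lat` (identity link, fraction
scale) is fitted by iterated GLS under a block-diagonal working
covariance `V_s = D_s R(ρ) D_s` per study (`D_s` = diag of stage SEs,
`R(ρ)` = AR(1) by visit order), alternating with Liang–Zeger moment
re-estimation of ρ from lag-1 standardized residuals, to a max
coefficient change < 1e-8 (≤ 50 iterations; non-convergence raises with
the last iterate attached).  Repeated measures are ordered by visit, not
calendar spacing.  Robust (sandwich) SEs use the Mancl–DeRouen
small-sample correction — with ~8 study clusters the uncorrected sandwich
under-covers badly (≈ 83 % for a nominal 95 % interval in simulation;
≈ 92–94 % with the correction).  Model-based SEs are retained on the
fitted object.

**Working correlation choice.** `working="ar1"` is the default and is
what the coverage simulations exercise.  The pipeline's calibration fit
uses `working="independence"` (ρ ≡ 0, i.e. weighted least squares with
cluster-robust errors): the linear surface is an approximation to sigmoid
green-up curves, and a moment-estimated ρ then absorbs the systematic
lack of fit (ρ̂ ≈ 0.8), turning the GLS into near-differencing and
destabilizing the date slope — the standard argument for a conservative
working correlation under mean-model misspecification.

**Stage dates and stage at events.** `stage_date` inverts the linear
predictor in closed form; it errors when the date slope
`β_d + β_dl·lat` vanishes.  `stage_at_events` predicts the stage at each
individual's nest date, reports per-site means, and tests homogeneity
across sites with a Kruskal–Wallis rank test.  In pipeline outputs the
*target* stage for indicator dates is recomputed as the mean predicted
stage over all nests (the same way a "29.5 % of seasonal biomass" figure
is derived from data), which cancels the common offset a linear fit
carries relative to curved truth.

## 4. Timing inference

**Marginal means.** `doy = site + individual + ε`, with the individual
random intercept absorbing repeated tracking.  REML is profiled down to
the variance ratio `λ = σ²_u/σ²_e` and minimized by bounded scalar search
on log λ (tolerance 1e-10, bounds e^±25/e^12, boundary λ = 0 detected
explicitly); site cell means are the marginal means, with SEs from
`σ̂²_e (XᵀV⁻¹X)⁻¹`.  The fit matches statsmodels' MixedLM (fully
converged) to < 1e-6 days.  Note that duplicating records is *not* a
no-op for this model — cluster sizes double and the variance ratio
re-balances — so sufficiency-style invariances should not be expected.

**Regressions.** Timing-vs-latitude is ordinary least squares on site
marginal means (≥ 3 sites); slope homogeneity between two event series is
the category × latitude interaction t-test in a pooled regression.

**Arrival estimators.** Tail alignment: estimate =
`earliest_reported + (mean − min)` of a reference sample (the "left tail"
is the reference minimum; an alternative percentile-based tail is a
one-line change, and the reference span is reported as a diagnostic).
The cumulative rule: per latitude bin and year, arrival is the first
day-of-year whose cumulative count reaches ≥ 2 % (configurable) of the
within-window seasonal total; yearly estimates are averaged with an
across-year SE.  The estimator is invariant to scaling all counts.

**Maxstat.** Candidate cutpoints are midpoints between sorted unique
latitudes leaving ≥ `min_prop` (default 0.1) of points on each side.  At
each cut the standardized linear statistic `T = (S − E)/√V` is computed
for the left-group sum under the permutation distribution
(`E = n_L ȳ`, `V = n_L n_R Σ(y−ȳ)²/(n(n−1))`); `T_max` is the maximum
|T|, ties broken toward smaller latitude.  The p value is the
plus-one-corrected fraction of seeded permutations reaching the observed
`T_max` — exact at small n and verified against brute-force enumeration;
no asymptotic improved-Bonferroni approximation is provided.  Constant
responses return `T_max = 0`, p = 1.  Note the natural estimand of a step
recovery is the between-site boundary midpoint, which is what the
statistic returns.

## 5. Synthetic data: what it emulates, and what it does not

All generators are pure functions of their parameter blocks (each block
carries a seed) and emit their ground truth alongside the data.

**Climate** — `tmean(d) = 12.5 − 0.9(lat − 39.2) + 11·cos(2π(d−201)/365)
+ N(0, σ)` °C, `tmin/tmax = tmean ∓ 4`: US Atlantic coast numbers (mean
annual 12.5 °C at the New Jersey reference latitude, ~0.9 °C cooling per
degree north, warmest day ~Jul 20, 8 °C diurnal range).  Default σ = 2 °C
for daily records; the pipeline's onset computation uses σ = 0
(climatological normals) for the reason in §1.

**Biomass** — eight studies at the latitudes of the real productivity
literature (31.3–45.3°).  True standing biomass rises logistically from
an overwintering standing crop (15 % of the seasonal maximum — marshes
retain standing dead and, southward, green shoots) to the maximum, at
rate 0.04 d⁻¹ (green-up over ~110 days) and midpoints shifting ~4 d per
degree latitude.  Reported means/SEs come from 15 replicate draws with
multiplicative CV 0.15 plus an additive floor of 2 % of the seasonal
maximum (a plot-to-plot error floor; purely multiplicative error would
give near-zero winter biomass absurdly large inverse-variance weight).
Sampling is every 3 weeks from late winter to early autumn, with each
study's window shifted to its local season as real field campaigns are.

**Tracks** — a scripted annual cycle rendered to a 10-min light series
(clipped-linear in solar elevation above −6°; positions follow great
circles during flight legs, via a South-Atlantic-coast stopover each way)
and a wet/dry series (Bernoulli wet 0.8 by day / 0.75 by night at
stationary sites — roosting waders stay largely wet — and continuously
dry in flight).  Daily incubation shading bouts (1–3 per day, 1.5–3 h,
mid-day local) run for 26 days from nest initiation.  The light
template's threshold-1 crossing sits at elevation −5.875° while positions
assume −6°, a deliberate small calibration mismatch of the kind real tags
have (worth < 0.3° latitude).  Not emulated: weather shading, habitat
shading outside incubation, sensor drift, equinox-dependent latitude
error beyond the geometry itself — so event-recovery rates here are an
upper bound on real-data performance, and the positions are only as good
as clean threshold geolocation ever is.

**Observation ramps** — per two-degree latitude bin, reporting frequency
follows a logistic ramp whose midpoint is solved (by root finding) so the
noise-free cumulative-2 % day equals the scripted arrival; daily counts
are Poisson around `effort × frequency` for 10 seasons.  Effort trends,
observer behaviour and spatial clumping are not modelled.

## 6. The coupled end-to-end study

`pipeline.run_all` wires the generators together so the green-wave
hypothesis is *true by construction*, then checks the analysis recovers
it: spring onset is computed per site from the climate generator, a line
`onset ~ latitude` is fitted through the three deployment sites, biomass
midpoints are calibrated so the true stage curve reaches the target stage
(0.295) exactly on that line, and nests are scripted on it with
individual-level jitter (individual SD 2 d, within-individual year SD
1.5 d; other events hang off the nest date at the field-plausible lags).
Per site 4–21 individuals are tracked, a subset for two years.  Every
stage of the detection and modelling chain then runs from the raw series
only.  All randomness flows from one config seed through spawned
`SeedSequence` streams; rerunning a config reproduces every result table
byte for byte (the manifest's timestamp differs).  A stage failure aborts
with the stage name, preserving completed outputs.

Default problem sizes (30-station grid, 34 individuals + 11 repeat
years, 8 studies × 11 visits, 10 000 permutations in the standalone
cutpoint analysis) keep a full run under ~10 s.

## 7. Known limitations

* The jerk-peak onset statistic needs smooth climatologies (§1); it is
  not robust to interannual noise and its level depends on the smoothing
  halfwidth, so only *relative* onset comparisons (across latitude or
  between periods computed identically) are meaningful.
* The green-wave model is a linear approximation to sigmoid growth; its
  predicted stages carry a window-dependent offset, handled by
  recomputing the target stage from data (§3) — absolute stage values
  should be read with that in mind.
* Threshold geolocation latitude is unreliable near equinoxes and is
  masked rather than modelled; longitude-only information drives
  migration classification.
* The mixed model assumes a single residual variance across sites;
  marginal means are cell means, with no covariate adjustment.
* The permutation p for `T_max` does not account for selecting
  `min_prop`, and the cutpoint's sampling distribution is discrete on
  between-site midpoints.
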