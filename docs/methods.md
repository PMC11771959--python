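# Methods

This note documents the models, conventions and numerical choices behind
`aeroforage`, and what the simulation-based tests do and do not demonstrate.

## Study system and units

A colony of small aerial insectivores is tracked with a reverse-GPS array;
fixes are planar east/north coordinates in meters relative to a local frame
with the colony near the origin.  Insect prey abundance aloft is measured by
a vertically pointing conical-beam radar as the movement traffic rate
(MoTR, insects·km⁻¹·hr⁻¹): the number of insects crossing a 1 km transect
per hour.  All timestamps are UTC; local time is a fixed configured offset
(no daylight-saving modeling — every analysis window is defined relative to
sunrise/sunset, which are offset-invariant).

## Filter chain

Order: daylight restriction (closed interval `[sunrise, sunset]`, NOAA solar
geometry with the standard −0.833° zenith), then speed → StdLoc fence → NBS
→ jump → minimum-tags-per-day.  Attrition fractions are reported against the
post-daylight ("raw") count.

* **Speed and jump rules** are iterative: the *later* fix of the
  worst-offending consecutive pair is dropped and kinematics recomputed
  until no pair exceeds the threshold (strict `>`; a pair at exactly
  30 m/s or exactly 500 m survives).  Implemented as a lazy max-heap over
  violating pairs with a doubly linked survivor list (O(n log n)); ties pop
  the earliest pair.  Rationale: gross TDOA errors are isolated displaced
  fixes, for which this rule removes exactly the bad fix.  Limitation: the
  rule can never remove the first fix of a track, and a *genuine* long gap
  whose bounding fixes are > 500 m apart triggers removal of good fixes
  until the track re-approaches the stuck fix.  Consequently the sampling
  interval must satisfy `2·v·dt ≪ max_step` (at 8 m/s cruise and 500 m,
  dt ≤ ~20 s) for single-fix dropouts not to open spurious holes.
* **StdLoc fence** = Q3 + 1.5·IQR of the StdLoc values pooled over the whole
  post-speed-filter dataset (a single global fence, matching the single
  published limit).  Quantiles use linear interpolation between order
  statistics (configurable).  A Tukey fence recomputed on its own output
  always tightens, so the chain is idempotent only with the fence held at
  its first-pass value; `run_filter_chain` accepts a precomputed fence for
  that purpose and the property test freezes it explicitly.
* **NBS** threshold is inclusive (NBS = 4 is retained); **minimum tags** is
  4 active tags (≥ 1 retained fix) per local day, dropping whole days.
* Duplicate timestamps within one tag are an input error (named in the
  exception), never silently deduplicated.
* `jump_mode="segment"` implements the alternative reading in which a
  tag-day containing any over-long step is discarded wholesale.

## Behavioral metrics

* **Visits**: the colony building blocks tag reception, so a visit is a
  reception gap ≥ 60 s (inclusive) whose bounding fixes both lie within the
  colony radius (default 100 m ≈ 10× localization accuracy — the radius is
  a package convention, since entry is inferred from signal loss).  Entry =
  last fix before the gap, exit = first fix after.
* **Daily route**: sum of step distances excluding visit gaps, reported only
  for tag-days with span ≥ 10 h and no non-visit gap > 15 min ("consistent
  activity" is operationalized by those two numbers; only the 10 h figure is
  externally fixed).  Exclusion is a reported missing value, not an error.
* **Foraging duration** = activity span (first to last fix) minus time
  inside the colony; **net foraging duration** = day length − foraging
  duration.  A switch (`exclude_visit_time`) restores the span-only variant.
* **Roost timing**: evening arrival is the tag-day's last fix when it is
  near-colony and within ±60 min of sunset (minutes after sunset, negative
  = before); morning departure analogous around sunrise.  Non-qualifying
  events are missing values, and roost duration pairs day *d*'s arrival with
  day *d+1*'s departure per tag.
* **Inter-individual distance**: per-bird mean position in 5-min bins
  aligned to the local clock (hh:00, hh:05, …; alignment fixed for
  reproducibility), bins with < 4 birds dropped, mean of all pairwise
  Euclidean distances per bin, averaged over bins.
* Day-level values are unweighted means over qualifying tags.

## Radar MoTR

Each retained echo (class "insect", RCS ≥ 3 mm², altitude 50–700 m)
contributes `1000 m / w(a)` with beam width `w(a) = 2·a·tan(θ/2)`; the
default opening angle is 105°, the midpoint of the instrument's nominal
90–120° cone.  Hourly MoTR is the sum of contributions in a clock hour;
daily MoTR is the arithmetic mean over the 15-hour local window
(05:00–20:00).  Window hours with zero retained echoes count as 0 (absence
of insects is a measurement); hours flagged non-operational are excluded
from the mean.  An altitude-dependent detection-probability correction is
deliberately not applied by default (the instrument's detectability declines
with altitude, but no published correction is fixed); the normalization is
the simplest one consistent with counting insects across a 1 km
cross-section.

## Inference

GLM fitting is delegated to statsmodels (IRLS maximum likelihood).
Conventions:

* Gamma models default to the **log link** (multiplicative, interpretable
  effects); inverse link available.  Reports always state the link.
* The parameter count `k` in AICc includes the dispersion/scale parameter
  for both families, so intercept + 2 slopes + scale gives k = 4 — verified
  against the worked AICc examples.
* Wald `t = estimate/SE`; default two-tailed p-values use the t distribution
  with `n − n_coef` df (normal-reference p-values are also reported).
  Two-tailed, α = 0.05 throughout.
* All-subsets model selection ranks every predictor subset (including
  intercept-only) by AICc; Akaike weights are normalized over *all*
  candidates; averaged coefficients use the **full average** (absent
  coefficient = 0) over the Δ < 2 set with renormalized weights; the
  conditional average is also computed.
* A constant response cannot be fitted (the Gaussian likelihood is
  unbounded); it returns a flagged degenerate result with zero slopes.
* Family choice fits gamma and normal by maximum likelihood and takes the
  lower AIC (≥ 5 observations required).

The ten-prediction battery regresses: mean and max colony distance, daily
route, foraging duration, visit frequency (with mean distance as a second
predictor, plus an all-subsets Δ<2 averaging table), flight speed, evening
arrival (MoTR only), departure (previous-day MoTR; previous-day arrival;
same-day MoTR) and inter-individual distance (with mean distance as a
second predictor) on daily MoTR, with families as in the study design
(gamma for positive skewed responses, Gaussian otherwise).  Route and
foraging-duration models use only route-qualified days.

## Synthetic-data generator

The generator is first-class, tested code; its defaults *are* the study
conditions:

* **Daily MoTR**: gamma rejection-truncated to [164.4, 2518.9], with base
  parameters moment-calibrated (closed-form truncated-gamma moments + root
  solve) so the truncated draws have mean 1207.7 and SD 566.7.
* **Days**: 31 days, 6 tags/day, fixes every 8 s, ~10 m Gaussian noise.
* **Trips**: straight out-and-back legs at a constant 8 m/s cruise (a
  degenerate correlated walk — correlation 1 within legs, independent
  headings between trips), with all event times on the fix-interval grid so
  zero-noise runs recover truth exactly.  Trip apogee is lognormal with
  log-median `log(6000 m) + β_dist·MoTR` (β_dist = −5·10⁻⁴), trip-level
  spread 0.35 and a shared day-level spread 0.3 (weather/patch variation —
  without it daily distance is near-deterministic in MoTR, which is neither
  realistic nor compatible with the observed effect magnitudes).
* **Visits** are reception gaps (no emitted fixes) of 90–600 s at rate
  `0.5 + 4·10⁻⁴·MoTR` per hour; **evening arrival** offset is
  `−28 + β_arr·(MoTR − mean) + N(0, 8)` minutes relative to sunset
  (β_arr = −0.01), clipped to [−55, −2] so arrivals precede sunset — the
  daylight restriction would otherwise censor post-sunset arrivals at 0 and
  destroy the timing structure; **morning departure** is N(10, 5) min after
  sunrise.  **Heading concentration** around a shared daily patch direction
  tightens with MoTR (spread 2.5 − 8·10⁻⁴·MoTR rad, floor 0.3), giving the
  inter-individual distance a direct abundance effect beyond the one
  mediated by trip distance.
* **Measurement defects** are isolated single-fix events placed with a
  minimum separation: gross outliers (10% of fixes, displaced 0.7–2.5 km
  within 60° of the track direction so the incoming step always exceeds the
  outgoing one and later-fix removal deletes exactly the outlier), StdLoc
  contamination (10%, 30–100 m against a lognormal ~8 m background) and
  low-NBS fixes (4%, NBS = 3 against 4–14).  Isolation is what makes the
  attrition dial exact: removing one defect can never open a hole longer
  than two sampling steps.  Real TDOA quality defects are temporally
  autocorrelated; that regime is deliberately not emulated (see
  limitations).
* **Echoes**: per local window hour, Poisson counts with intensity
  `true MoTR / E[1000/w(A)]` (altitude uniform in the band, so the
  transect-normalized estimator is unbiased by construction), plus
  configurable sub-threshold-RCS insects and non-insect targets to exercise
  the selection filters.

The truth record stores per-day MoTR, per-tag-day apogees, visit intervals,
arrival/departure offsets, route length and the injected outlier row
indices.

What passing tests therefore show: the pipeline's filters remove exactly
the defect classes they target, metrics recover a known foraging schedule
to fix-interval resolution, the MoTR estimator is consistent, and the GLM
battery is calibrated under the null and recovers the built-in effect
directions.  What they do not show: robustness to autocorrelated quality
dropouts, wind drift, curved flight paths, spatially structured prey
patches, multi-colony movement, or classification errors in the radar's
target classes.

## Problem sizes in the simulation studies

Replicate-world studies (effect recovery, sign structure) use 31 days ×
6 tags at a 30 s fix interval with measurement-defect injection off and
filtering skipped — they probe the generator → metrics → inference chain;
filter behavior is probed separately (fixture track, attrition dial at the
native 8 s interval with all defects on, zero-noise round trip).  100
replicate worlds are used, sharing one simulation per seed across checks.
Null calibration uses 1000 replicates of direct n = 31 draws.

## Known limitations

* The later-fix removal rule cannot flag an erroneous *first* fix.
* Attrition accounting attributes each fix to the first stage that removes
  it; stages are order-dependent by design (speed before the pooled fence).
* The jump rule interacts with sampling sparser than ~20 s at realistic
  flight speeds (see above); for such data `jump_mode="segment"` or a larger
  `max_step_m` is advisable.
* Gamma log-likelihoods use the statsmodels scale estimate; absolute AICc
  values can differ by a constant bookkeeping choice from other software,
  without affecting rankings computed within one toolchain.
* The generator's "null" responses (route length, foraging duration, flight
  speed, departure timing) are only approximately null: schedule mechanics
  (day-filling final trips, visit-step exclusion) couple them weakly to
  MoTR.  Calibration of the tests themselves is checked against a pure
  zero-effect generator instead.
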