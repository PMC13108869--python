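# Methods

`divekin` turns raw whale-borne tag records (tri-axial accelerometer,
gyroscope and magnetometer plus a pressure-derived depth channel) into
dive-level behavioral inference: which dives were feeding dives, and what
kinematic signature separates feeding from traveling. This note describes
the processing model, the statistical models, the synthetic-data generator
used for validation, and the numerical choices made where the design was
genuinely open.

## Signal model

Tag acceleration is treated as the sum of a *static* component (gravity
rotated into the whale frame, i.e. body orientation) and a *dynamic*
component (propulsion and other fast movement). The two are separated by a
zero-phase (forward-backward) 2nd-order Butterworth low-pass at **0.08 Hz**,
applied with `sosfiltfilt`. Zero phase matters because stroke timing is read
off filtered signals; the forward-backward pass squares the magnitude
response, so the effective attenuation is that of a 4th-order filter. Edge
padding is set to 16 periods of the lowest corner frequency — with the
default corners that is ~200 s of padding — because shorter padding leaves
edge transients large enough to break the zero-lag (time-reversal) property
that downstream peak-timing logic relies on.

Orientation (pitch, roll, heading) is recomputed from the low-passed
accelerometer and magnetometer. Axis convention: x forward, y left, z up,
right-handed; a level whale reads static acceleration (0, 0, −1) g. Pitch is
−asin of the normalized surge component; roll is atan2 of the sway/heave
components; heading tilt-compensates the magnetic vector into the local
level frame (declination is a configuration field, default 0). Heading is
undefined (NaN) at |pitch| = 90°.

Scalar kinematics:

- **Jerk** (m/s³): `‖Δa‖ · 9.81 · fs`, the norm of the first difference of
  tri-axial acceleration converted to SI per unit time. Dimensional analysis
  requires dividing the difference by the sampling *interval* (equivalently,
  multiplying by `fs`); the package does so and documents it here because
  the quantity is only meaningful in m/s³. Jerk spikes flag brief events —
  for a ram-filtering whale, candidate mouth closures.
- **VeDBA** (m/s²): the norm of the dynamic (static-removed) acceleration
  over all three axes, × 9.81. An energy-expenditure proxy.
- **Speed** (m/s): the tag-jiggle proxy. Jiggle is the sliding-window RMS
  (0.5 s window) of the acceleration norm high-passed at 10 Hz at the native
  rate. It is calibrated per deployment against orientation-corrected depth
  rate, OCDR = |d(depth)/dt| / |sin(pitch)|, using only samples with
  |pitch| ≥ 30° (OCDR is not a valid speed reference in level swimming), by
  least squares on log(OCDR) vs log(jiggle) (log-log by default; linear axes
  are a config option). Predictions below **0.9 m/s** — the minimum
  detectable jiggle speed — are retained but flagged unreliable. If fewer
  than 30 steep-pitch samples exist, calibration fails and speed stays
  missing rather than being extrapolated.

## Dive segmentation

A dive is a maximal excursion with depth > **5 m** lasting ≥ **10 s**,
terminated by a surface interval (depth < 1 m) longer than **10 s**;
excursions separated by shorter surface time are merged into one dive, and
time spent between 1 and 5 m without surfacing does not split a dive either.
Phases: the bottom phase is the maximal span with depth ≥ 0.8 × maximum
depth (an automated, reproducible stand-in for manual bottom-phase picking;
a manual interval can be supplied and overrides the heuristic), descent runs
from the dive start to the bottom start, ascent from the bottom end to the
dive end. The nominal 3 m descent/ascent boundary lies outside the detected
> 5 m interval, so phases are clipped to the dive; a phase of non-positive
duration is recorded absent, which genuinely happens for shallow, short
dives. Shape classes from the bottom fraction *f* of dive duration:
V (*f* ≤ 0.20), U (0.20 < *f* < 0.50), Square (*f* ≥ 0.50). The boundary
*f* = 0.50 is assigned to Square so ties are deterministic.

## Fluke strokes

The gyroscope y (pitch-rate) axis is band-passed to **0.08–0.2 Hz**, the
stroke band of a large balaenid. Because rotation rate leads pitch by a
quarter cycle, upward zero-crossings of the band-passed signal mark stroke
peaks. Detection gates each candidate cycle on peak amplitude (default
5 deg/s) so sensor noise cannot mint strokes, applies a numerical deadband
of 0.1% of the gate around zero (floating-point dust must not create
crossings), and interpolates crossing times linearly between samples.

Stroke frequency over a window is the reciprocal of the mean inter-peak
interval; the rolling fluke rate is the stroke count in a centered 30-s
half-open window. A *per-stroke* frequency (reciprocal of the preceding
interval) lets strokes be pooled across deployments and binned by depth
(1-m bins). The depth-strata analysis z-standardizes per-stroke frequency
within deployment, removes |z| > 3 outliers, splits at **23 m**, and fits a
linear mixed model (standardized frequency ~ stratum, random intercept by
hour-of-day bin) via `statsmodels` MixedLM, reporting the deep-vs-shallow
contrast and per-stratum medians on the raw Hz scale. The hour-bin random
intercept is the concrete rendering of "time of day as a random effect" — a
continuous random effect is not identifiable here.

## Behavior labeling

Audited video events carry one of three labels: Feeding, PotentialForaging,
Travel. Each dive and each phase receives one label hierarchically: any
positive Feeding overlap wins outright, regardless of duration; otherwise
the label with the longest overlapped duration wins, with exact ties broken
Feeding > PotentialForaging > Travel for determinism; a scope with zero
video coverage is labeled NoVideo (partial coverage still uses the observed
events). Overlapping same-label events are merged before durations are
compared, so double-annotation cannot bias the competition. The assignment
is order-independent and idempotent, and adding a Feeding event can only
move a label toward Feeding — both properties are tested.

## Per-dive features and the feeding classifier

Per phase: mean speed, pitch, roll, VeDBA; heading variance computed as
angular variance 2(1−R) (R = mean resultant length) in deg² — arithmetic
variance is meaningless across the 0/360° wrap; stroke frequency and mean
rolling fluke rate; descent/ascent vertical rate. Around the bottom-phase
jerk argmax (earliest index on ties): peak jerk = max − median over the
phase (removing each animal's baseline), roll at the peak, and the
before/after change in mean speed and fluke rate over ±20 s windows clipped
to the phase and excluding the peak sample itself (so the transient does not
contaminate both windows). Dive start time enters as
cos(2πh/24) + sin(2πh/24), a single scalar bounded by ±√2 with extrema at
03:00 and 15:00; it is not invertible (two clock times share each value),
so the two components are also available separately for sensitivity checks.

The classifier is a binomial-logit mixed model: Feeding (1) vs Travel (0),
kinematic fixed effects, and a per-deployment random intercept absorbing
individual, tag-placement and year differences. Dives labeled
PotentialForaging or NoVideo are excluded from fitting but kept in outputs.
The marginal likelihood is maximized directly with **Gauss–Hermite
quadrature** (25 nodes) over the random intercept — the same likelihood
`lme4::glmer` maximizes, and the implementation agrees with `glmer`
(nAGQ = 25) to ~1e-3 in coefficients, random-effect SD and log-likelihood
on test data. Continuous fixed effects are standardized internally for
conditioning and back-transformed, so reported estimates are on the input
scale. Standard errors come from the inverse numerical Hessian of the full
parameter vector; profile-likelihood intervals are available and preferred
when the group count is small or the random-effect variance estimate sits
near zero, where Wald intervals are optimistic. AIC counts the variance as
one parameter (k = p + 1); model comparison drops rows missing *any*
candidate's features before every fit so likelihoods are computed on
identical observations, and ΔAIC is quoted against the intercept-plus-
random-intercept null. Complete separation is flagged (extreme
coefficients), a single-valued response raises an error, and a
near-zero random-effect variance is flagged as singular.

Numerical defaults: L-BFGS-B, ftol 1e-8, max 500 iterations; GLM fit
without the random effect supplies starting values.

## Synthetic deployments

The generator builds complete deployments with known truth so every stage is
testable without field data. Depth profiles are trapezoids with half-cosine
ramps (smooth corners keep phases unambiguous for truth tables while still
exercising the 0.8 × max bottom heuristic); all truth times are derived from
realized sample counts, so planned and detectable boundaries agree to one
sample at zero noise. Defaults are the study conditions the analysis
targets:

- dives mostly < 60 m (log-normal maxima, median ~18–20 m), durations
  ~1–11 min, surface intervals 30–120 s;
- fluke oscillation on gyro-y at **0.192 Hz above 23 m and 0.151 Hz below**
  (phase-integrated so the gait switch is smooth), amplitude 15 deg/s;
- behavior mix 0.5; bottom speed **1.24 ± 0.191 m/s** feeding vs
  **1.64 ± 0.542 m/s** non-feeding; pitch **−6.2°** feeding vs 0°; roll
  −5.4° feeding vs 0°; ramps at ±45° pitch so OCDR is a valid reference;
- during feeding bottom phases, a jerk transient (0.3 g, one native sample)
  every 60 s with a coincident +0.3 m/s speed step lasting 20 s;
- accelerometer jiggle simulated as broadband noise with SD proportional to
  true speed (0.02 g per m/s), making the speed-calibration stage
  exercisable end to end; independent Gaussian sensor noise per channel;
- native rate 50 Hz, working rate 10 Hz; identical seed ⇒ identical output.

Speed-step, pitch and roll values where no published figure exists
(speed-change magnitudes, roll SD, jiggle coefficient, noise SDs) were
chosen once as field-plausible values and are configuration fields.

What the generator does **not** emulate: tag slip, sensor drift and
calibration error, surface wave noise on the pressure channel, gliding and
stroke pauses, conspecific bumps, or any hydrodynamics. Passing closed-loop
tests therefore demonstrates that the pipeline recovers the structure it
assumes, not that real deployments satisfy those assumptions.

A feature-level generator (`simulate_dive_features`) draws per-dive
predictors directly from the same behavior-conditional signatures, with
feeding probability following a logistic model in the circular time-of-day
encoding plus a deployment random intercept. Classifier studies (coverage,
model selection) run on it at n = 200–400 dives × 50 replicates in seconds;
sensor-level realism is exercised separately by the full generator at
smaller n. Problem sizes used by the shipped studies: 10–24 dives per
full-sensor deployment, 50 replicates for the stochastic suites.

## Known limitations

- The bottom-phase heuristic needs a plateau; genuinely V-shaped dives get
  a short bottom around the apex by construction.
- OCDR calibration requires steep-pitch swimming; deployments without it
  have no absolute speed scale, only missing speed.
- The quadrature GLMM supports a single random intercept — the only
  structure the analysis calls for; crossed or nested effects are out of
  scope.
- Heading variance uses the angular-variance convention; other circular
  dispersion measures would scale differently.
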