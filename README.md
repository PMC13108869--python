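# divekin

Dive segmentation, fluke-stroke analysis and mixed-effects feeding
classification for whale-borne inertial tag data.

`divekin` is for movement ecologists working with high-resolution biologging
tags on large whales — records combining a tri-axial accelerometer,
gyroscope and magnetometer with a pressure-derived depth channel, plus
interval-annotated behavioral observations from an onboard camera. It was
built around the question of what distinguishes confirmed ram-filtration
feeding from travel in a sub-Arctic bowhead whale (*Balaena mysticetus*)
deployment, where prey layers are shallow, tidally driven and variable, and
where classic dive-shape heuristics over-call feeding.

## What it computes

From a raw tag "diary" the pipeline produces, per dive and dive phase
(descent / bottom / ascent):

- **Dives and shapes** — rule-based detection (depth > 5 m, duration ≥ 10 s,
  post-dive surface interval > 10 s) and V / U / Square classification by
  the bottom-phase fraction of dive duration (≤ 20% / 20–50% / ≥ 50%).
- **Kinematics** — zero-phase Butterworth separation of static and dynamic
  acceleration; pitch / roll / heading; jerk `‖Δa‖·9.81·fs` (m/s³); VeDBA
  (m/s²); forward speed from tag jiggle calibrated against
  orientation-corrected depth rate (OCDR).
- **Fluke strokes** — upward zero-crossings of the 0.08–0.2 Hz band-passed
  gyroscope pitch axis; stroke frequency (1 / mean inter-peak interval),
  rolling 30-s stroke counts, and a depth-strata linear mixed model testing
  the gait switch between shallow (≤ 23 m) and deep strata.
- **Behavior labels** — hierarchical assignment of audited Feeding /
  PotentialForaging / Travel intervals to dives and phases (Feeding always
  wins; otherwise longest duration; NoVideo when nothing overlaps).
- **Feeding classifier** — a binomial-logit mixed model
  P(feeding) = logit⁻¹(Xβ + u_deployment), u ~ N(0, σ²), fit by
  Gauss–Hermite-quadrature maximum likelihood (agrees with `lme4::glmer`
  to ~1e-3), with AIC / log-likelihood model comparison against a null
  model and profile-likelihood intervals.

A synthetic deployment generator (`divekin.simulate`) produces complete
fake deployments — sensor series, truth dive tables and event logs — with
the statistical structure the analysis assumes, so every stage is testable
end to end without field data. See `docs/methods.md` for the models,
defaults and their rationale.

## Worked example

```python
import divekin
from divekin.simulate import preset_config, simulate_deployment

cfg = preset_config("mixed", seed=7, n_dives=12)     # dives spanning 23 m
diary, truth, events = simulate_deployment(cfg)
res = divekin.run_pipeline(diary, events)

from divekin.dives import dive_table
print(dive_table(res.dives)[["dive_id", "max_depth_m", "duration_min",
                             "bottom_fraction", "shape"]].head(5))
print("speed calibration r =", round(res.speed.r, 3))

strata = divekin.depth_strata_model(res.stroke_table)
print(strata.group_medians, strata.n_strokes)
```

prints

```
 dive_id  max_depth_m  duration_min  bottom_fraction  shape
       0        23.93          7.41             0.94 Square
       1        20.73          7.63             0.95 Square
       2        24.78          3.45             0.86 Square
       3         8.93          6.94             0.99 Square
       4        17.37          5.89             0.95 Square
speed calibration r = 0.96
shallow median 0.192 Hz (n=806), deep median 0.151 Hz (n=71)
```

The simulator programmed fluke strokes at 0.192 Hz above 23 m and 0.151 Hz
below; the detector, per-stroke depth binning and mixed model recover both
medians exactly, and the jiggle speed calibration correlates at r = 0.96
with the OCDR reference. Fitting candidate feeding models on a simulated
feature table:

```python
from divekin.models import ModelSpec, compare_models
from divekin.simulate import simulate_dive_features

feats = simulate_dive_features(n_dives=200, seed=7)
table = compare_models(feats, [
    ModelSpec("NULL", ()),
    ModelSpec("1", ("bottom_mean_speed",)),
    ModelSpec("4", ("bottom_mean_speed", "bottom_peak_jerk", "speed_change",
                    "bottom_mean_roll", "bottom_mean_pitch", "tod")),
])
print(table[["model", "AIC", "logLik", "dAIC"]].round(1))
```

```
model   AIC  logLik  dAIC
 NULL 272.8  -134.4   NaN
    1 228.5  -111.2  44.3
    4  53.6   -18.8 219.1
selected: 4
```

Bottom speed alone already beats the null (ΔAIC 44.3), and the full
kinematic model — speed, peak jerk with its coincident speed change, pitch,
roll and circular time of day — is selected decisively, mirroring how these
predictors behave on real deployments.

There is also a CLI for shell use: `divekin simulate`, `divekin ingest`,
`divekin analyze`, `divekin strata`, `divekin compare` (see `--help`).

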