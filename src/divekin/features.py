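"""Per-dive, per-phase kinematic predictors for the feeding classifier.

For each dive phase the pipeline summarises speed, body orientation, VeDBA
and fluking; around the bottom-phase jerk peak (candidate mouth closure) it
measures the before/after change in speed and fluke rate; and the dive start
time is folded into a single cyclical time-of-day scalar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dives import Dive
from .fluke import FlukeStrokeSet, rolling_fluke_rate, stroke_frequency
from .signal import KinematicSeries, OrientationSeries

__all__ = [
    "encode_time_of_day",
    "extract_phase_features",
    "peak_jerk_deltas",
    "feature_table",
]

PHASES = ("descent", "bottom", "ascent")


def encode_time_of_day(when) -> float:
    """Fold clock time into cos(2*pi*h/24) + sin(2*pi*h/24).

    ``when`` may be a timestamp or decimal hours in [0, 24).  The sum of the
    two circular components is a single scalar bounded by +/-sqrt(2)
    (maximum at 03:00, minimum at 15:00); it is 24-h periodic but not
    invertible — two clock times share each value.  The two components can
    be obtained separately via ``encode_time_of_day_components``.
    """
    h = _decimal_hours(when)
    ang = 2 * np.pi * h / 24.0
    return float(np.cos(ang) + np.sin(ang))


def encode_time_of_day_components(when) -> tuple[float, float]:
    """(cos, sin) circular components of time of day, for sensitivity checks."""
    h = _decimal_hours(when)
    ang = 2 * np.pi * h / 24.0
    return float(np.cos(ang)), float(np.sin(ang))


def _decimal_hours(when) -> float:
    if isinstance(when, (int, float, np.floating)):
        return float(when) % 24.0
    ts = pd.Timestamp(when)
    return ts.hour + ts.minute / 60.0 + ts.second / 3600.0 + ts.microsecond / 3.6e9


def circular_variance_deg2(angles_deg) -> float:
    """Angular variance of directional data, in squared degrees.

    2 * (1 - R) with R the mean resultant length, converted from rad^2 to
    deg^2.  Arithmetic variance is meaningless for headings near the
    0/360 wrap; this statistic is wrap-free and zero for constant heading.
    """
    a = np.radians(np.asarray(angles_deg, dtype=float))
    a = a[np.isfinite(a)]
    if len(a) == 0:
        return float("nan")
    R = np.hypot(np.mean(np.sin(a)), np.mean(np.cos(a)))
    return float(2.0 * (1.0 - R) * (180.0 / np.pi) ** 2)


def _phase_mask(t, phase):
    return (t >= phase.t_start) & (t <= phase.t_end)


def _nanmean(x):
    x = np.asarray(x, dtype=float)
    return float(np.nanmean(x)) if np.isfinite(x).any() else float("nan")


def extract_phase_features(
    dive: Dive,
    kin: KinematicSeries,
    orient: OrientationSeries,
    strokes: FlukeStrokeSet,
    depth=None,
) -> dict:
    """Per-phase means plus descent/ascent vertical rates.

    Returns a flat dict with keys ``{phase}_{feature}``; phases absent from
    the dive yield missing (NaN) features.  Descent/ascent rate is the depth
    change across the phase divided by its duration (m/s); fluke frequency
    is the inverted mean inter-peak interval within the phase and the fluke
    rate the mean rolling 30-s stroke count.
    """
    out: dict = {}
    t = kin.t
    for name in PHASES:
        phase = getattr(dive, name)
        prefix = name
        if phase is None or phase.duration_s <= 0:
            for feat in ("mean_speed", "mean_pitch", "mean_roll", "heading_variance",
                         "mean_vedba", "fluke_frequency", "fluke_rate_mean"):
                out[f"{prefix}_{feat}"] = float("nan")
            continue
        m = _phase_mask(t, phase)
        out[f"{prefix}_mean_speed"] = _nanmean(kin.speed[m])
        out[f"{prefix}_mean_pitch"] = _nanmean(orient.pitch[m])
        out[f"{prefix}_mean_roll"] = _nanmean(orient.roll[m])
        out[f"{prefix}_heading_variance"] = circular_variance_deg2(orient.heading[m])
        out[f"{prefix}_mean_vedba"] = _nanmean(kin.vedba[m])
        out[f"{prefix}_fluke_frequency"] = stroke_frequency(
            strokes, (phase.t_start, phase.t_end)
        )
        grid = t[m]
        out[f"{prefix}_fluke_rate_mean"] = (
            float(np.mean(rolling_fluke_rate(strokes, grid))) if len(grid) else float("nan")
        )

    if depth is not None:
        depth = np.asarray(depth, dtype=float)
        for name, key in (("descent", "descent_rate"), ("ascent", "ascent_rate")):
            phase = getattr(dive, name)
            if phase is None or phase.duration_s <= 0:
                out[key] = float("nan")
                continue
            m = _phase_mask(t, phase)
            dz = abs(depth[m][-1] - depth[m][0]) if m.any() else float("nan")
            out[key] = dz / phase.duration_s
    return out


def peak_jerk_deltas(
    dive: Dive,
    kin: KinematicSeries,
    orient: OrientationSeries,
    strokes: FlukeStrokeSet,
    halfwidth_s: float = 20.0,
) -> dict:
    """Bottom-phase jerk peak and the before/after speed and fluke-rate change.

    The jerk peak is the argmax of jerk within the bottom phase (earliest
    index on ties); ``bottom_peak_jerk`` is that maximum minus the median
    jerk over the phase, which removes the individual's baseline jerk level.
    Speed change is mean(speed in (peak, peak+20 s]) minus mean(speed in
    [peak-20 s, peak)) — the peak sample itself excluded so the transient
    does not dominate both windows — and the fluke-rate change is the
    analogous difference of the rolling 30-s stroke count.  Windows are
    clipped to the bottom phase.
    """
    out = {
        "bottom_peak_jerk": float("nan"),
        "speed_change": float("nan"),
        "fluke_rate_change": float("nan"),
        "roll_at_peak_jerk": float("nan"),
    }
    phase = dive.bottom
    if phase is None:
        return out
    t = kin.t
    m = _phase_mask(t, phase)
    idx = np.flatnonzero(m)
    if len(idx) < 2:
        return out
    jerk = kin.jerk[idx]
    k = int(np.argmax(jerk))  # np.argmax takes the earliest max
    t_peak = float(t[idx[k]])
    out["bottom_peak_jerk"] = float(jerk.max() - np.median(jerk))
    out["roll_at_peak_jerk"] = float(orient.roll[idx[k]])

    lo = max(phase.t_start, t_peak - halfwidth_s)
    hi = min(phase.t_end, t_peak + halfwidth_s)
    before = m & (t >= lo) & (t < t_peak)
    after = m & (t > t_peak) & (t <= hi)
    if before.any() and after.any():
        out["speed_change"] = _nanmean(kin.speed[after]) - _nanmean(kin.speed[before])
        rate = rolling_fluke_rate(strokes, t)
        out["fluke_rate_change"] = float(np.mean(rate[after]) - np.mean(rate[before]))
    return out


def feature_table(
    dives: list[Dive],
    kin: KinematicSeries,
    orient: OrientationSeries,
    strokes: FlukeStrokeSet,
    depth=None,
    labels: pd.DataFrame | None = None,
    start_time_utc=None,
) -> pd.DataFrame:
    """Model-ready table: one row per dive with phase features, jerk-peak
    deltas, cyclical time of day, duration, shape and (optionally) the
    dive-scope behavior label."""
    rows = []
    for d in dives:
        row = {
            "dive_id": d.dive_id,
            "deployment_id": d.deployment_id,
            "t_start": d.t_start,
            "duration_min": d.duration_min,
            "max_depth_m": d.max_depth,
            "shape": d.shape,
        }
        row.update(extract_phase_features(d, kin, orient, strokes, depth))
        row.update(peak_jerk_deltas(d, kin, orient, strokes))
        if start_time_utc is not None:
            dive_start = pd.Timestamp(start_time_utc) + pd.to_timedelta(d.t_start, unit="s")
            row["tod"] = encode_time_of_day(dive_start)
            row["start_time_utc"] = dive_start
            row["tod_linear"] = _decimal_hours(dive_start)
        rows.append(row)
    df = pd.DataFrame(rows)
    if labels is not None:
        dive_labels = labels[labels["scope"] == "dive"][["dive_id", "label"]]
        df = df.merge(dive_labels, on="dive_id", how="left")
    return df
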