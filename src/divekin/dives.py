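"""Rule-based dive detection, phase segmentation and shape classification.

A dive is a depth excursion deeper than 5 m lasting at least 10 s and
followed by more than 10 s at the surface; shorter surface gaps merge the
flanking excursions into one dive.  Each dive is split into descent, bottom
and ascent phases, and classified V / U / Square by the fraction of its
duration spent in the bottom phase (<=20%, 20-50%, >=50%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DiveRules",
    "Phase",
    "Dive",
    "detect_dives",
    "segment_phases",
    "classify_shape",
    "dive_table",
]


@dataclass(frozen=True)
class DiveRules:
    """Thresholds defining a dive.

    depth_threshold_m : excursion must exceed this depth (5 m).
    min_duration_s : excursion must last at least this long (10 s).
    min_surface_s : a post-dive surface interval must exceed this (10 s);
        shorter surface gaps merge consecutive excursions.
    surface_m : depth below which the whale counts as "at the surface" (1 m).
    phase_boundary_m : descent starts / ascent ends at this depth (3 m),
        clipped to the detected dive interval.
    bottom_coef : auto bottom phase = maximal span with
        depth >= bottom_coef * max_depth (0.8).
    """

    depth_threshold_m: float = 5.0
    min_duration_s: float = 10.0
    min_surface_s: float = 10.0
    surface_m: float = 1.0
    phase_boundary_m: float = 3.0
    bottom_coef: float = 0.8


@dataclass
class Phase:
    t_start: float
    t_end: float

    @property
    def duration_s(self) -> float:
        return self.t_end - self.t_start

    @property
    def duration_min(self) -> float:
        return self.duration_s / 60.0


@dataclass
class Dive:
    """One detected depth excursion with optional phases and shape class."""

    dive_id: int
    t_start: float
    t_end: float
    max_depth: float
    descent: Phase | None = None
    bottom: Phase | None = None
    ascent: Phase | None = None
    shape: str | None = None  # "V" | "U" | "Square"
    deployment_id: str = ""
    provenance: str = "auto"  # "auto" | "manual"
    extras: dict = field(default_factory=dict)

    @property
    def duration_s(self) -> float:
        return self.t_end - self.t_start

    @property
    def duration_min(self) -> float:
        return self.duration_s / 60.0

    @property
    def bottom_fraction(self) -> float | None:
        if self.bottom is None or self.duration_s <= 0:
            return None
        return self.bottom.duration_s / self.duration_s


def _check_uniform(t: np.ndarray) -> float:
    dt = np.diff(t)
    if len(dt) == 0 or np.any(dt <= 0):
        raise ValueError("depth series must have a strictly increasing time base")
    med = np.median(dt)
    if np.any(np.abs(dt - med) > 0.01 * med):
        raise ValueError("depth series must be uniformly sampled")
    return float(med)


def detect_dives(depth, t=None, fs=None, rules: DiveRules | None = None,
                 deployment_id: str = "") -> list[Dive]:
    """Find dives in a uniformly sampled depth trace.

    Candidate excursions are maximal runs with depth above the 5 m
    threshold.  Consecutive excursions whose intervening surface time
    (depth < ``rules.surface_m``) does not exceed ``rules.min_surface_s``
    are merged — the whale never completed a post-dive surface interval, so
    the excursions are one dive.  Excursions shorter than
    ``rules.min_duration_s`` after merging are discarded.  Dive start/end
    are the threshold crossings of the merged run.
    """
    rules = rules or DiveRules()
    depth = np.asarray(depth, dtype=float)
    if t is None:
        if fs is None:
            raise ValueError("provide either t or fs")
        t = np.arange(len(depth)) / fs
    else:
        t = np.asarray(t, dtype=float)
        _check_uniform(t)

    deep = depth > rules.depth_threshold_m
    if not deep.any():
        return []
    edges = np.diff(deep.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)  # exclusive
    if deep[0]:
        starts.insert(0, 0)
    if deep[-1]:
        ends.append(len(depth))
    runs = list(zip(starts, ends))

    dt = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    at_surface = depth < rules.surface_m

    # merge runs separated by insufficient surface time
    merged: list[tuple[int, int]] = []
    for s, e in runs:
        if merged:
            ps, pe = merged[-1]
            surf_time = float(np.sum(at_surface[pe:s])) * dt
            if surf_time <= rules.min_surface_s:
                merged[-1] = (ps, e)
                continue
        merged.append((s, e))

    dives = []
    for s, e in merged:
        if (e - s) * dt < rules.min_duration_s:
            continue
        dives.append(
            Dive(
                dive_id=len(dives),
                t_start=float(t[s]),
                t_end=float(t[e - 1] + dt),
                max_depth=float(depth[s:e].max()),
                deployment_id=deployment_id,
            )
        )
    return dives


def segment_phases(dive: Dive, depth, t, rules: DiveRules | None = None,
                   manual_bottom: tuple[float, float] | None = None) -> Dive:
    """Set descent/bottom/ascent phases on a detected dive.

    Auto method: bottom phase is the maximal span with depth >=
    ``bottom_coef * max_depth`` (first to last crossing); descent runs from
    the dive start (the 3 m boundary lies outside the detected >5 m
    interval, so phases are clipped to the dive) to the bottom start, ascent
    from the bottom end to the dive end.  A phase of non-positive duration
    is recorded absent — shallow, short dives may genuinely lack a distinct
    descent or ascent.

    ``manual_bottom`` overrides the heuristic with a hand-picked interval,
    mirroring audit-style bottom-phase selection; it must lie within the
    dive.
    """
    rules = rules or DiveRules()
    depth = np.asarray(depth, dtype=float)
    t = np.asarray(t, dtype=float)
    sel = (t >= dive.t_start) & (t <= dive.t_end)
    td, dd = t[sel], depth[sel]
    if len(td) < 2:
        raise ValueError("dive interval contains fewer than 2 samples")

    if manual_bottom is not None:
        b0, b1 = manual_bottom
        if not (dive.t_start <= b0 < b1 <= dive.t_end):
            raise ValueError(
                f"manual bottom interval {manual_bottom} outside dive "
                f"[{dive.t_start}, {dive.t_end}]"
            )
        dive.provenance = "manual"
    else:
        thresh = rules.bottom_coef * dive.max_depth
        idx = np.flatnonzero(dd >= thresh)
        b0, b1 = float(td[idx[0]]), float(td[idx[-1]])
        if b1 <= b0:  # single-sample apex: give the bottom one sample width
            b1 = b0 + float(np.median(np.diff(td)))
        dive.provenance = "auto"

    dive.bottom = Phase(b0, min(b1, dive.t_end))
    # descent begins once past the phase boundary depth, clipped to the dive
    desc_start = dive.t_start
    asc_end = dive.t_end
    dive.descent = Phase(desc_start, b0) if b0 > desc_start else None
    dive.ascent = Phase(dive.bottom.t_end, asc_end) if asc_end > dive.bottom.t_end else None
    return dive


def classify_shape(dive: Dive) -> str:
    """V / U / Square from the bottom-phase fraction of dive duration.

    <= 0.20 -> V; 0.20 < f < 0.50 -> U; >= 0.50 -> Square.  The 0.50
    boundary is assigned to Square so ties are deterministic.
    """
    f = dive.bottom_fraction
    if f is None:
        raise ValueError(f"dive {dive.dive_id} has no bottom phase; segment first")
    if f <= 0.20:
        shape = "V"
    elif f < 0.50:
        shape = "U"
    else:
        shape = "Square"
    dive.shape = shape
    return shape


def dive_table(dives: list[Dive]) -> pd.DataFrame:
    """Tabulate dives (durations in minutes, two-decimal convention)."""
    rows = []
    for d in dives:
        rows.append(
            {
                "dive_id": d.dive_id,
                "deployment_id": d.deployment_id,
                "t_start": d.t_start,
                "t_end": d.t_end,
                "max_depth_m": d.max_depth,
                "duration_min": round(d.duration_min, 2),
                "descent_min": round(d.descent.duration_min, 2) if d.descent else np.nan,
                "bottom_min": round(d.bottom.duration_min, 2) if d.bottom else np.nan,
                "ascent_min": round(d.ascent.duration_min, 2) if d.ascent else np.nan,
                "bottom_fraction": d.bottom_fraction,
                "shape": d.shape,
                "provenance": d.provenance,
            }
        )
    return pd.DataFrame(rows)
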