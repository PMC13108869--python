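"""Hierarchical assignment of audited behavior events to dives and phases.

Video audits yield labeled intervals (Feeding, PotentialForaging, Travel).
Each dive — and each of its phases — receives a single label: Feeding wins
whenever any feeding overlap exists, regardless of duration; otherwise the
label with the longest overlapped duration wins; scopes with no video
coverage at all are labeled NoVideo.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .dives import Dive
from .io import BehaviorEvent

__all__ = ["DiveLabel", "assign_behavior", "label_table"]

NO_VIDEO = "NoVideo"
#: Tie precedence when overlap durations are exactly equal (no Feeding case).
PRECEDENCE = ("Feeding", "PotentialForaging", "Travel")


@dataclass(frozen=True)
class DiveLabel:
    dive_id: int
    scope: str                 # "dive" | "descent" | "bottom" | "ascent"
    label: str                 # behavior label or NoVideo
    coverage_fraction: float   # fraction of the scope overlapped by any event


def _merge_intervals(intervals):
    """Union of possibly overlapping [lo, hi) intervals."""
    out = []
    for lo, hi in sorted(intervals):
        if out and lo <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], hi))
        else:
            out.append((lo, hi))
    return out


def _label_scope(dive_id, scope, t0, t1, events) -> DiveLabel:
    duration = t1 - t0
    per_label: dict[str, list] = {}
    for e in events:
        lo, hi = max(e.t_start, t0), min(e.t_end, t1)
        if hi > lo:
            per_label.setdefault(e.label, []).append((lo, hi))

    # overlapping same-label events are merged, not an error
    overlaps = {
        lab: sum(hi - lo for lo, hi in _merge_intervals(ivs))
        for lab, ivs in per_label.items()
    }
    covered = sum(
        hi - lo
        for lo, hi in _merge_intervals([iv for ivs in per_label.values() for iv in ivs])
    )
    coverage = covered / duration if duration > 0 else 0.0

    if not overlaps:
        return DiveLabel(dive_id, scope, NO_VIDEO, 0.0)
    if "Feeding" in overlaps:
        # feeding priority, independent of time spent feeding
        return DiveLabel(dive_id, scope, "Feeding", coverage)
    best = max(overlaps.values())
    for lab in PRECEDENCE:  # deterministic tie-break
        if overlaps.get(lab) == best:
            return DiveLabel(dive_id, scope, lab, coverage)
    raise AssertionError("unreachable")


def assign_behavior(dive: Dive, events: list[BehaviorEvent]) -> dict[str, DiveLabel]:
    """Label a dive and each present phase from audited events.

    Returns a mapping scope -> :class:`DiveLabel` for "dive" plus every
    phase the dive has.  Events entirely outside a scope are ignored for
    that scope; the result is independent of event ordering.
    """
    scopes = {"dive": (dive.t_start, dive.t_end)}
    for name in ("descent", "bottom", "ascent"):
        phase = getattr(dive, name)
        if phase is not None:
            scopes[name] = (phase.t_start, phase.t_end)
    return {
        scope: _label_scope(dive.dive_id, scope, t0, t1, events)
        for scope, (t0, t1) in scopes.items()
    }


def label_table(dives: list[Dive], events: list[BehaviorEvent]) -> pd.DataFrame:
    """Long-format label table (one row per dive x scope)."""
    rows = []
    for d in dives:
        for scope, lab in assign_behavior(d, events).items():
            rows.append(
                {
                    "dive_id": lab.dive_id,
                    "deployment_id": d.deployment_id,
                    "scope": scope,
                    "label": lab.label,
                    "coverage_fraction": lab.coverage_fraction,
                }
            )
    return pd.DataFrame(rows)
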