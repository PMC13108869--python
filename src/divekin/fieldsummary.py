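"""Published summary numbers from the Cumberland Sound bowhead tagging
campaign the synthetic presets emulate, plus the arithmetic derived from
them.

These are campaign-level summary statistics (per-deployment dive counts,
dive-shape tallies, audited behavior tallies); the underlying sensor records
are not deposited, which is why the package ships a simulator instead of a
data loader for them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "DEPLOYMENT_DIVE_COUNTS",
    "SHAPE_COUNTS",
    "SHAPE_COUNTS_BY_BEHAVIOR",
    "summarize_dive_counts",
    "shape_proportions",
    "wave_drag_cessation_depth",
]

#: Number of analyzed dives per tag deployment (15 deployments, summer
#: 2023-2024).
DEPLOYMENT_DIVE_COUNTS = pd.Series(
    {
        "av230803-180a": 4,
        "av230803-P48_a": 1,
        "av230803-P48_b": 16,
        "av230803-P49": 15,
        "av230805-P46_a": 2,
        "av230805-P46_b": 23,
        "av230805-P49_a": 12,
        "av230805-P49_b": 5,
        "av230806-P48": 114,
        "av230806-P49_a": 11,
        "av230806-P49_b": 8,
        "av230810-P46": 17,
        "av240809-68": 3,
        "av240809-P47": 62,
        "av240812-P48": 3,
    },
    name="n_dives",
)

#: Dive-shape tallies over all analyzed dives.
SHAPE_COUNTS = {"Square": 258, "U": 31, "V": 7}

#: Shape tallies within the video-validated behavior classes.
SHAPE_COUNTS_BY_BEHAVIOR = {
    "Feeding": {"Square": 40, "U": 7, "V": 3},
    "NonFeeding": {"Square": 15, "U": 6, "V": 3},
}


def summarize_dive_counts(counts: pd.Series | None = None) -> dict:
    """Total, mean and sample SD of per-deployment dive counts."""
    c = (counts if counts is not None else DEPLOYMENT_DIVE_COUNTS).to_numpy(float)
    return {
        "total": int(c.sum()),
        "mean": float(c.mean()),
        "sd": float(np.std(c, ddof=1)),
        "n_deployments": len(c),
    }


def shape_proportions(counts: dict | None = None) -> dict:
    """Percentage of dives per shape class."""
    c = counts or SHAPE_COUNTS
    total = sum(c.values())
    return {shape: 100.0 * n / total for shape, n in c.items()}


def wave_drag_cessation_depth(body_diameter_m: float = 4.8) -> float:
    """Depth (m) below which surface wave drag ceases to act on a swimmer.

    Wave drag falls off with submergence and becomes negligible at about
    three body diameters; for a subadult bowhead of ~4.8 m girth-equivalent
    diameter that is 3 x 4.8 = 14.4 m.
    """
    return 3.0 * body_diameter_m
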