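"""Reading, validation and resampling of tag diary series and behavior event logs.

A *diary* is the merged multi-sensor record written by an animal-borne tag:
tri-axial acceleration (g, whale frame: x forward, y left, z up), tri-axial
rotation rate (deg/s), tri-axial magnetic field (arbitrary consistent units)
and pressure-derived depth (m, positive down), all on a common uniform time
base.  The on-disk dialect is a headered CSV with an ISO-8601 ``timestamp``
column plus named sensor columns; tag-frame to whale-frame rotation is assumed
already applied upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "DiarySeries",
    "BehaviorEvent",
    "BEHAVIOR_LABELS",
    "SchemaError",
    "DataError",
    "read_diary",
    "write_diary",
    "read_events",
    "write_events",
    "resample_diary",
]

#: Closed vocabulary of audited behavior labels.
BEHAVIOR_LABELS = ("Feeding", "PotentialForaging", "Travel")

DIARY_COLUMNS = (
    "timestamp",
    "ax", "ay", "az",
    "gx", "gy", "gz",
    "mx", "my", "mz",
    "depth",
)


class SchemaError(ValueError):
    """A required column is missing or has the wrong dtype."""


class DataError(ValueError):
    """The file parses but violates a data invariant (time base, gaps)."""


@dataclass
class DiarySeries:
    """Time-aligned multi-sensor tag record at a uniform sampling rate.

    Attributes
    ----------
    deployment_id : str
        Identifier of the tag deployment.
    t : ndarray, shape (n,)
        Seconds since deployment start; strictly increasing, step ``1/fs``.
    accel : ndarray, shape (n, 3)
        Acceleration in g (x surge, y sway, z heave, whale frame).
    gyro : ndarray, shape (n, 3)
        Rotation rate in deg/s.
    mag : ndarray, shape (n, 3)
        Magnetic field in arbitrary consistent units.
    depth : ndarray, shape (n,)
        Depth in meters, positive down.
    fs : float
        Sampling rate in Hz.
    start_time_utc : pandas.Timestamp
        Absolute time of ``t == 0``.
    """

    deployment_id: str
    t: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    mag: np.ndarray
    depth: np.ndarray
    fs: float
    start_time_utc: pd.Timestamp = field(default_factory=lambda: pd.Timestamp(0, tz="UTC"))

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.mag = np.asarray(self.mag, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        n = len(self.t)
        for name in ("accel", "gyro", "mag"):
            arr = getattr(self, name)
            if arr.shape != (n, 3):
                raise DataError(f"{name} must have shape ({n}, 3), got {arr.shape}")
        if self.depth.shape != (n,):
            raise DataError("depth length does not match time base")
        if n > 1 and np.any(np.diff(self.t) <= 0):
            raise DataError("time base must be strictly increasing")
        if np.any(self.depth < -0.5):
            raise DataError("depth below -0.5 m; check pressure calibration")

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        """Return the series as a diary-dialect DataFrame."""
        ts = self.start_time_utc + pd.to_timedelta(self.t, unit="s")
        return pd.DataFrame(
            {
                "timestamp": ts,
                "ax": self.accel[:, 0], "ay": self.accel[:, 1], "az": self.accel[:, 2],
                "gx": self.gyro[:, 0], "gy": self.gyro[:, 1], "gz": self.gyro[:, 2],
                "mx": self.mag[:, 0], "my": self.mag[:, 1], "mz": self.mag[:, 2],
                "depth": self.depth,
            }
        )


@dataclass(frozen=True)
class BehaviorEvent:
    """One audited behavioral interval on the diary clock."""

    label: str
    t_start: float
    t_end: float
    deployment_id: str = ""

    def __post_init__(self) -> None:
        if self.label not in BEHAVIOR_LABELS:
            raise SchemaError(
                f"label {self.label!r} not in {BEHAVIOR_LABELS}"
            )
        if not self.t_start < self.t_end:
            raise DataError("event must have t_start < t_end")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def _infer_fs(t_seconds: np.ndarray) -> float:
    """Infer sampling rate from timestamps; reject jittery time bases.

    Jitter above 10% of the median step means either gaps or irregular
    sampling, both of which break the uniform-sampling assumption of the
    downstream filters.
    """
    dt = np.diff(t_seconds)
    if len(dt) == 0:
        raise DataError("need at least 2 samples to infer sampling rate")
    med = float(np.median(dt))
    if med <= 0:
        raise DataError("non-monotone timestamps")
    if np.any(np.abs(dt - med) > 0.10 * med):
        raise DataError(
            "sampling-interval jitter exceeds 10% of the median step; "
            "gaps or irregular sampling are not supported"
        )
    return 1.0 / med


def read_diary(
    path,
    deployment_id: str = "",
    attach_start_s: float | None = None,
    attach_end_s: float | None = None,
    schema: dict[str, str] | None = None,
) -> DiarySeries:
    """Read a diary CSV into a validated :class:`DiarySeries`.

    Parameters
    ----------
    path : path-like or file-like
        Headered CSV with an ISO-8601 ``timestamp`` column and sensor columns
        ``ax ay az gx gy gz mx my mz depth``.
    deployment_id : str
        Identifier attached to the returned series.
    attach_start_s, attach_end_s : float, optional
        Attachment window in seconds relative to the first in-file sample.
        Rows outside the window (tag not on the animal) are dropped and the
        time base re-zeroed to the window start.
    schema : dict, optional
        Maps canonical column names to the names used in the file.

    Raises
    ------
    SchemaError
        Required column missing.
    DataError
        Non-monotone time, ambiguous sampling rate, or invariant violation.
    """
    df = pd.read_csv(path)
    colmap = {c: c for c in DIARY_COLUMNS}
    if schema:
        colmap.update(schema)
    missing = [canon for canon, col in colmap.items() if col not in df.columns]
    if missing:
        raise SchemaError(f"diary file is missing required column(s): {missing}")

    ts = pd.to_datetime(df[colmap["timestamp"]], utc=True, format="ISO8601")
    if ts.is_monotonic_increasing is False or ts.duplicated().any():
        raise DataError("timestamps must be strictly increasing")
    t = (ts - ts.iloc[0]).dt.total_seconds().to_numpy()

    keep = np.ones(len(df), dtype=bool)
    if attach_start_s is not None:
        keep &= t >= attach_start_s
    if attach_end_s is not None:
        keep &= t <= attach_end_s
    if not keep.any():
        raise DataError("attachment window excludes every sample")

    df = df.loc[keep].reset_index(drop=True)
    t = t[keep]
    start = ts.iloc[int(np.flatnonzero(keep)[0])]
    t = t - t[0]

    fs = _infer_fs(t)
    # snap to the exact uniform grid implied by fs (removes float jitter
    # from timestamp round-tripping)
    t = np.arange(len(t)) / fs

    def tri(prefix: str) -> np.ndarray:
        return np.column_stack(
            [df[colmap[prefix + ax]].to_numpy(dtype=float) for ax in "xyz"]
        )

    return DiarySeries(
        deployment_id=deployment_id,
        t=t,
        accel=tri("a"),
        gyro=tri("g"),
        mag=tri("m"),
        depth=df[colmap["depth"]].to_numpy(dtype=float),
        fs=fs,
        start_time_utc=start,
    )


def write_diary(series: DiarySeries, path) -> None:
    """Write a :class:`DiarySeries` to the diary CSV dialect."""
    df = series.to_frame()
    df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S.%f%z")
    df.to_csv(path, index=False, float_format="%.10g")


def read_events(path, deployment_id: str | None = None) -> list[BehaviorEvent]:
    """Read a behavior-event CSV (columns deployment_id,label,start_s,end_s)."""
    df = pd.read_csv(path)
    required = {"deployment_id", "label", "start_s", "end_s"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"event file is missing required column(s): {sorted(missing)}")
    if deployment_id is not None:
        df = df[df["deployment_id"] == deployment_id]
    return [
        BehaviorEvent(
            label=row.label,
            t_start=float(row.start_s),
            t_end=float(row.end_s),
            deployment_id=str(row.deployment_id),
        )
        for row in df.itertuples(index=False)
    ]


def write_events(events: list[BehaviorEvent], path) -> None:
    pd.DataFrame(
        {
            "deployment_id": [e.deployment_id for e in events],
            "label": [e.label for e in events],
            "start_s": [e.t_start for e in events],
            "end_s": [e.t_end for e in events],
        }
    ).to_csv(path, index=False)


def resample_diary(series: DiarySeries, target_fs: float) -> DiarySeries:
    """Anti-alias low-pass and decimate every channel to ``target_fs``.

    Tag sensors record at rates far above the body-movement band of a large
    whale; analysis runs at a common working rate (10 Hz here, matching the
    depth channel's native rate).  Decimation uses a zero-phase 8th-order
    Chebyshev anti-aliasing filter (``scipy.signal.decimate``) so that slow
    kinematic content is preserved without phase distortion.

    Raises
    ------
    ValueError
        If ``target_fs`` exceeds the native rate (upsampling unsupported) or
        is not an integer divisor of it.
    """
    if target_fs > series.fs:
        raise ValueError(
            f"upsampling not supported (native {series.fs} Hz < target {target_fs} Hz)"
        )
    ratio = series.fs / target_fs
    q = int(round(ratio))
    if abs(ratio - q) > 1e-6:
        raise ValueError(
            f"native rate {series.fs} Hz is not an integer multiple of {target_fs} Hz"
        )
    if q == 1:
        return replace(series)

    # zero-phase Butterworth anti-alias (unity DC gain, so constants and
    # slow signals pass unchanged), then pick every q-th sample
    sos = sps.butter(8, 0.45 * target_fs, btype="lowpass", fs=series.fs,
                     output="sos")

    def dec(x: np.ndarray) -> np.ndarray:
        padlen = min(x.shape[0] - 1, int(4 * series.fs / target_fs) * 10)
        return sps.sosfiltfilt(sos, x, axis=0, padlen=padlen)[::q]

    n_out = int(np.ceil(len(series) / q))
    return DiarySeries(
        deployment_id=series.deployment_id,
        t=np.arange(n_out) / target_fs,
        accel=dec(series.accel),
        gyro=dec(series.gyro),
        mag=dec(series.mag),
        depth=dec(series.depth),
        fs=float(target_fs),
        start_time_utc=series.start_time_utc,
    )
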