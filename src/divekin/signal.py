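"""Filtering, body orientation and kinematic scalar series.

Separates the *static* (gravity/orientation) from the *dynamic* (propulsive)
component of tag acceleration with zero-phase Butterworth filters, recomputes
pitch/roll/heading from the static component, and derives the movement
scalars used to characterise feeding: jerk, VeDBA and a jiggle-calibrated
forward-speed proxy.

Axis convention (whale frame, right-handed): x forward (surge), y left
(sway), z up (heave).  A level, motionless whale reads static acceleration
(0, 0, -1) g.  Pitch is positive nose-up, roll positive right-side-down,
heading in compass degrees [0, 360).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "OrientationSeries",
    "KinematicSeries",
    "SpeedConfig",
    "SpeedResult",
    "CalibrationError",
    "butterworth_zero_lag",
    "compute_orientation",
    "compute_jerk",
    "compute_vedba",
    "estimate_speed",
]

GRAVITY = 9.81  # m/s^2 per g

#: Low-pass corner separating body orientation from propulsive movement (Hz).
STATIC_CUTOFF_HZ = 0.08
#: Band containing fluke-stroke oscillation of a large balaenid (Hz).
FLUKE_BAND_HZ = (0.08, 0.2)


class CalibrationError(RuntimeError):
    """Speed calibration impossible (too few steep-pitch reference samples)."""


@dataclass
class OrientationSeries:
    """Pitch/roll/heading (degrees) on a uniform time base."""

    pitch: np.ndarray
    roll: np.ndarray
    heading: np.ndarray
    t: np.ndarray
    fs: float


@dataclass
class KinematicSeries:
    """Per-sample kinematic scalars driving dive-level feature extraction.

    ``speed`` may contain NaN where no calibration was possible;
    ``speed_reliable`` is False below the minimum detectable jiggle speed.
    """

    jerk: np.ndarray            # m/s^3, >= 0
    vedba: np.ndarray           # m/s^2, >= 0
    speed: np.ndarray           # m/s, NaN when uncalibrated
    speed_reliable: np.ndarray  # bool mask
    gyro_y_band: np.ndarray     # deg/s, fluke-band-passed pitch-axis rotation
    t: np.ndarray
    fs: float


def butterworth_zero_lag(x, fs, kind="lowpass", fc=STATIC_CUTOFF_HZ, order=2):
    """Forward-backward (zero-phase) Butterworth filter.

    Applied forward then backward (``filtfilt``) so the pass band suffers no
    phase shift — peak times of slow oscillations are preserved, which the
    fluke-stroke zero-crossing detector depends on.  The effective magnitude
    response is the squared response of the underlying ``order``-th order
    filter.

    Parameters
    ----------
    x : array, shape (n,) or (n, k)
        Uniformly sampled series; filtering runs along axis 0.
    fs : float
        Sampling rate (Hz).
    kind : {"lowpass", "bandpass"}
    fc : float or (float, float)
        Corner frequency, or band edges for ``kind="bandpass"``.
    order : int
        Order of the underlying one-pass filter (default 2).
    """
    x = np.asarray(x, dtype=float)
    nyq = fs / 2.0
    fc_arr = np.atleast_1d(np.asarray(fc, dtype=float))
    if np.any(fc_arr <= 0) or np.any(fc_arr >= nyq):
        raise ValueError(f"cutoff {fc} outside (0, Nyquist={nyq}) Hz")
    if kind == "lowpass":
        sos = sps.butter(order, fc_arr[0], btype="lowpass", fs=fs, output="sos")
    elif kind == "bandpass":
        if fc_arr.size != 2:
            raise ValueError("bandpass needs two corner frequencies")
        sos = sps.butter(order, fc_arr, btype="bandpass", fs=fs, output="sos")
    else:
        raise ValueError(f"unknown filter kind {kind!r}")
    min_len = 9 * (2 * sos.shape[0] + 1)
    if x.shape[0] <= min_len:
        raise ValueError(
            f"series too short ({x.shape[0]} samples) for the filter's "
            f"effective impulse length"
        )
    # edge padding must cover the filter's settling time (set by the lowest
    # corner) or forward and reversed runs disagree near the edges
    padlen = min(x.shape[0] - 1, int(16 * fs / fc_arr.min()))
    return sps.sosfiltfilt(sos, x, axis=0, padlen=padlen)


def static_dynamic_split(accel, fs, fc=STATIC_CUTOFF_HZ, order=2):
    """Split acceleration into static (low-passed) and dynamic components."""
    static = butterworth_zero_lag(accel, fs, "lowpass", fc, order)
    return static, accel - static


def compute_orientation(
    accel_static, mag_static, t, fs, declination_deg=0.0
) -> OrientationSeries:
    """Recover pitch, roll and tilt-compensated heading from static sensors.

    The low-passed accelerometer is gravity-dominated, so its direction is
    the body-frame "down" vector, giving pitch and roll; the magnetic vector
    rotated into the local level frame gives heading (plus declination).

    A calibration warning (``UserWarning``) is raised when the static
    acceleration magnitude leaves [0.5, 1.5] g for more than 10% of samples —
    a sign the low-pass left dynamic content in, or the accelerometer scale
    is off.
    """
    a = np.asarray(accel_static, dtype=float)
    m = np.asarray(mag_static, dtype=float)
    norm = np.linalg.norm(a, axis=1)
    bad = (norm < 0.5) | (norm > 1.5)
    if bad.mean() > 0.10:
        import warnings

        warnings.warn(
            f"|static accel| outside [0.5, 1.5] g for {bad.mean():.0%} of "
            "samples; orientation may be unreliable",
            UserWarning,
        )
    down = a / np.where(norm > 0, norm, 1.0)[:, None]  # unit down, body frame

    pitch = -np.degrees(np.arcsin(np.clip(down[:, 0], -1.0, 1.0)))
    roll = np.degrees(np.arctan2(-down[:, 1], -down[:, 2]))

    # level frame: z up, x = horizontal projection of body-forward
    up = -down
    ex = np.zeros_like(down)
    ex[:, 0] = 1.0
    xh = ex - (np.sum(ex * up, axis=1))[:, None] * up
    xh_norm = np.linalg.norm(xh, axis=1)
    # degenerate at |pitch| = 90 deg; heading undefined there
    xh = xh / np.where(xh_norm > 1e-9, xh_norm, 1.0)[:, None]
    yh = np.cross(up, xh)  # horizontal body-left
    m_fwd = np.sum(m * xh, axis=1)
    m_left = np.sum(m * yh, axis=1)
    # at heading psi the north field decomposes as cos(psi)*forward + sin(psi)*left
    heading = (np.degrees(np.arctan2(m_left, m_fwd)) + declination_deg) % 360.0
    heading = np.where(xh_norm > 1e-9, heading, np.nan)

    return OrientationSeries(
        pitch=pitch, roll=roll, heading=heading,
        t=np.asarray(t, dtype=float), fs=float(fs),
    )


def compute_jerk(accel, fs):
    """Norm of the first difference of tri-axial acceleration, in m/s^3.

    jerk[i] = sqrt(dax^2 + day^2 + daz^2) * 9.81 * fs, with jerk[0] = 0.
    The difference of consecutive g-valued samples is converted to SI by the
    9.81 m/s^2 factor and divided by the sampling interval (i.e. multiplied
    by fs) to give a rate of change of acceleration.  Spikes in jerk flag
    small rapid events — for a filter-feeding whale, candidate mouth
    closures.
    """
    a = np.asarray(accel, dtype=float)
    if a.shape[0] < 2:
        raise ValueError("need at least 2 samples to difference")
    d = np.diff(a, axis=0)
    jerk = np.sqrt(np.sum(d * d, axis=1)) * GRAVITY * fs
    return np.concatenate([[0.0], jerk])


def compute_vedba(accel_dynamic):
    """Vectorial dynamic body acceleration (m/s^2), an energy-expenditure proxy.

    The norm of the dynamic (static-removed) acceleration across the three
    axes, converted from g to m/s^2.
    """
    a = np.asarray(accel_dynamic, dtype=float)
    return np.sqrt(np.sum(a * a, axis=1)) * GRAVITY


@dataclass
class SpeedConfig:
    """Tuning of the jiggle speed proxy.

    jiggle = RMS of the high-passed acceleration norm in a sliding window;
    it scales with the flow-induced vibration of the tag and hence with
    speed through the water.  It is calibrated per deployment against
    orientation-corrected depth rate (OCDR), which is a valid speed reference
    only at steep pitch.
    """

    highpass_hz: float = 10.0        # jiggle band lower corner at native rate
    window_s: float = 0.5            # RMS window length
    pitch_min_deg: float = 30.0      # OCDR validity threshold
    min_speed: float = 0.9           # minimum detectable jiggle speed (m/s)
    min_calibration_samples: int = 30
    log_log: bool = True             # regress log(OCDR) on log(jiggle)


@dataclass
class SpeedResult:
    speed: np.ndarray          # m/s on the working grid
    reliable: np.ndarray       # False where predicted speed < min_speed
    r: float                   # calibration correlation coefficient
    coef: tuple[float, float]  # (intercept, slope) of the calibration fit
    n_calibration: int


def jiggle_amplitude(accel_native, fs_native, n_out, cfg: SpeedConfig | None = None):
    """Windowed RMS of the high-passed acceleration norm, on a coarse grid.

    Returns the jiggle series evaluated at ``n_out`` evenly spaced window
    centers (the working-rate grid).
    """
    cfg = cfg or SpeedConfig()
    a = np.asarray(accel_native, dtype=float)
    if cfg.highpass_hz >= fs_native / 2:
        raise ValueError("jiggle high-pass corner must be below Nyquist")
    sos = sps.butter(2, cfg.highpass_hz, btype="highpass", fs=fs_native, output="sos")
    hp = sps.sosfiltfilt(sos, a, axis=0)
    mag = np.linalg.norm(hp, axis=1)
    half = max(1, int(round(cfg.window_s * fs_native / 2)))
    centers = np.linspace(0, len(mag) - 1, n_out).round().astype(int)
    out = np.empty(n_out)
    for k, c in enumerate(centers):
        lo, hi = max(0, c - half), min(len(mag), c + half + 1)
        out[k] = np.sqrt(np.mean(mag[lo:hi] ** 2))
    return out


def estimate_speed(
    accel_native,
    fs_native,
    depth,
    pitch_deg,
    fs_working,
    cfg: SpeedConfig | None = None,
) -> SpeedResult:
    """Calibrate tag jiggle against OCDR and predict forward speed.

    OCDR (orientation-corrected depth rate) = |d(depth)/dt| / |sin(pitch)|
    is an absolute speed reference wherever the animal moves steeply
    (|pitch| >= ``cfg.pitch_min_deg``).  Jiggle is regressed on OCDR over
    those reference samples (log-log by default) and the fit is inverted to
    predict speed everywhere from jiggle alone.  Predictions below
    ``cfg.min_speed`` (the minimum detectable jiggle speed, ~0.9 m/s) are
    kept but flagged unreliable.

    Raises
    ------
    CalibrationError
        Fewer than ``cfg.min_calibration_samples`` qualifying samples.
    """
    cfg = cfg or SpeedConfig()
    depth = np.asarray(depth, dtype=float)
    pitch = np.asarray(pitch_deg, dtype=float)
    n = len(depth)
    jig = jiggle_amplitude(accel_native, fs_native, n, cfg)

    ddt = np.gradient(depth) * fs_working
    sinp = np.abs(np.sin(np.radians(pitch)))
    steep = np.abs(pitch) >= cfg.pitch_min_deg
    with np.errstate(divide="ignore", invalid="ignore"):
        ocdr = np.where(steep, np.abs(ddt) / np.where(sinp > 0, sinp, np.nan), np.nan)

    ok = np.isfinite(ocdr) & (ocdr > 0) & (jig > 0)
    if ok.sum() < cfg.min_calibration_samples:
        raise CalibrationError(
            f"only {int(ok.sum())} steep-pitch calibration samples "
            f"(need {cfg.min_calibration_samples}); speed unavailable"
        )

    if cfg.log_log:
        X, y = np.log(jig[ok]), np.log(ocdr[ok])
    else:
        X, y = jig[ok], ocdr[ok]
    slope, intercept = np.polyfit(X, y, 1)
    r = float(np.corrcoef(X, y)[0, 1])
    if cfg.log_log:
        with np.errstate(divide="ignore"):
            pred = np.exp(intercept + slope * np.log(np.where(jig > 0, jig, np.nan)))
    else:
        pred = intercept + slope * jig
    pred = np.where(np.isfinite(pred) & (pred > 0), pred, np.nan)
    reliable = np.isfinite(pred) & (pred >= cfg.min_speed)
    return SpeedResult(
        speed=pred,
        reliable=reliable,
        r=r,
        coef=(float(intercept), float(slope)),
        n_calibration=int(ok.sum()),
    )


def compute_kinematics(
    diary,
    orientation: OrientationSeries | None = None,
    speed: SpeedResult | None = None,
) -> KinematicSeries:
    """Assemble the per-sample kinematic scalars for a working-rate diary.

    Jerk and VeDBA come from the working-rate acceleration; the fluke-band
    gyroscope-y series drives stroke detection.  Speed is taken from a
    jiggle calibration when supplied, else left NaN.
    """
    static, dynamic = static_dynamic_split(diary.accel, diary.fs)
    jerk = compute_jerk(diary.accel, diary.fs)
    vedba = compute_vedba(dynamic)
    gyro_y_band = butterworth_zero_lag(
        diary.gyro[:, 1], diary.fs, "bandpass", FLUKE_BAND_HZ
    )
    if speed is not None:
        sp, rel = speed.speed, speed.reliable
    else:
        sp = np.full(len(diary), np.nan)
        rel = np.zeros(len(diary), dtype=bool)
    return KinematicSeries(
        jerk=jerk, vedba=vedba, speed=sp, speed_reliable=rel,
        gyro_y_band=gyro_y_band, t=diary.t, fs=diary.fs,
    )
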