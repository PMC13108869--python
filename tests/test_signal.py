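import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from divekin.signal import (
    CalibrationError,
    SpeedConfig,
    butterworth_zero_lag,
    compute_jerk,
    compute_orientation,
    compute_vedba,
    estimate_speed,
    static_dynamic_split,
)

FS = 10.0


def sinusoid(freq, dur=400.0, fs=FS, amp=1.0):
    t = np.arange(int(dur * fs)) / fs
    return t, amp * np.sin(2 * np.pi * freq * t)


class TestButterworthZeroLag:
    def test_dc_passes_lowpass(self):
        x = np.full(2000, 3.7)
        y = butterworth_zero_lag(x, FS, "lowpass", 0.08)
        np.testing.assert_allclose(y, 3.7, rtol=1e-9)

    def test_bandpass_attenuates_out_of_band(self):
        # 0.01 Hz is a decade below the 0.08 Hz band edge; the squared
        # 2nd-order Butterworth response there is far below 10% amplitude
        t, x = sinusoid(0.01, dur=1000.0)
        y = butterworth_zero_lag(x, FS, "bandpass", (0.08, 0.2))
        core = slice(len(x) // 4, -len(x) // 4)
        assert np.max(np.abs(y[core])) < 0.10 * np.max(np.abs(x))

    def test_in_band_peaks_unshifted(self):
        t, x = sinusoid(0.15, dur=600.0)
        y = butterworth_zero_lag(x, FS, "bandpass", (0.08, 0.2))
        # cross-correlation peak at zero lag = no phase shift
        corr = np.correlate(y, x, mode="full")
        lag = int(np.argmax(corr)) - (len(x) - 1)
        assert lag == 0

    def test_time_reversal_symmetry(self, rng):
        x = rng.normal(size=3000)
        fwd = butterworth_zero_lag(x, FS, "bandpass", (0.08, 0.2))
        rev = butterworth_zero_lag(x[::-1], FS, "bandpass", (0.08, 0.2))[::-1]
        np.testing.assert_allclose(fwd, rev, atol=1e-8)

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError):
            butterworth_zero_lag(np.zeros(1000), FS, "lowpass", 5.0)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="short"):
            butterworth_zero_lag(np.zeros(10), FS, "lowpass", 0.08)


def pose_static_accel(pitch_deg, roll_deg, n=100):
    """Gravity reading for a pose, built independently with rotation matrices.

    Body-to-world rotation: roll about body x, then pitch about body y
    (x forward, y left, z up; pitch + nose-up, roll + right-side-down).
    The accelerometer static reading is the world down vector (0,0,-1)
    expressed in body coordinates.
    """
    R = (
        Rotation.from_euler("y", -pitch_deg, degrees=True)
        * Rotation.from_euler("x", roll_deg, degrees=True)
    )
    down_body = R.inv().apply([0.0, 0.0, -1.0])
    return np.tile(down_body, (n, 1))


class TestOrientation:
    def test_level_pose(self):
        a = pose_static_accel(0.0, 0.0)
        mag = np.tile([1.0, 0.0, 0.0], (len(a), 1))
        o = compute_orientation(a, mag, np.arange(len(a)) / FS, FS)
        np.testing.assert_allclose(o.pitch, 0.0, atol=1e-9)
        np.testing.assert_allclose(o.roll, 0.0, atol=1e-9)
        np.testing.assert_allclose(o.heading, 0.0, atol=1e-9)

    def test_nose_down_30deg(self):
        a = pose_static_accel(-30.0, 0.0)
        mag = np.tile([1.0, 0.0, 0.0], (len(a), 1))
        o = compute_orientation(a, mag, np.arange(len(a)) / FS, FS)
        np.testing.assert_allclose(o.pitch, -30.0, atol=1e-9)
        np.testing.assert_allclose(o.roll, 0.0, atol=1e-9)

    @pytest.mark.parametrize("pitch,roll", [(15.0, 0.0), (-30.0, 10.0),
                                            (45.0, -25.0), (-6.2, -5.4)])
    def test_inverse_consistency(self, pitch, roll):
        # rotating the measured static vector back through the recovered
        # pitch/roll must return (0, 0, -1) g
        a = pose_static_accel(pitch, roll, n=10)
        mag = np.tile([1.0, 0.0, 0.0], (10, 1))
        o = compute_orientation(a, mag, np.arange(10) / FS, FS)
        assert o.pitch[0] == pytest.approx(pitch, abs=1e-6)
        assert o.roll[0] == pytest.approx(roll, abs=1e-6)
        R = (
            Rotation.from_euler("y", -o.pitch[0], degrees=True)
            * Rotation.from_euler("x", o.roll[0], degrees=True)
        )
        restored = R.apply(a[0])
        np.testing.assert_allclose(restored, [0.0, 0.0, -1.0], atol=1e-6)

    def test_heading_from_declination_and_yaw(self):
        # a whale headed 90 deg (east) sees the north field along body-left
        a = pose_static_accel(0.0, 0.0)
        mag = np.tile([0.0, 1.0, 0.0], (len(a), 1))
        o = compute_orientation(a, mag, np.arange(len(a)) / FS, FS)
        np.testing.assert_allclose(o.heading, 90.0, atol=1e-9)
        o2 = compute_orientation(a, mag, np.arange(len(a)) / FS, FS,
                                 declination_deg=10.0)
        np.testing.assert_allclose(o2.heading, 100.0, atol=1e-9)

    def test_magnitude_warning(self):
        a = pose_static_accel(0.0, 0.0) * 2.0  # 2 g static: calibration off
        mag = np.tile([1.0, 0.0, 0.0], (len(a), 1))
        with pytest.warns(UserWarning, match="static accel"):
            compute_orientation(a, mag, np.arange(len(a)) / FS, FS)


class TestJerk:
    def test_constant_acceleration_zero(self):
        a = np.tile([0.3, -0.1, 0.9], (50, 1))
        np.testing.assert_allclose(compute_jerk(a, FS), 0.0, atol=1e-12)

    def test_single_axis_unit_step(self):
        a = np.zeros((10, 3))
        a[5:, 0] = 1.0  # 1 g step between samples 4 and 5
        jerk = compute_jerk(a, FS)
        assert jerk[5] == pytest.approx(1.0 * 9.81 * FS)
        assert jerk[4] == 0.0 and jerk[6] == 0.0

    def test_three_axis_step_vector_norm(self):
        a = np.zeros((10, 3))
        a[5:, :] = 1.0
        jerk = compute_jerk(a, FS)
        assert jerk[5] == pytest.approx(np.sqrt(3.0) * 98.1)

    def test_matches_finite_difference_oracle(self, rng):
        a = rng.normal(size=(200, 3))
        jerk = compute_jerk(a, FS)
        expected = np.linalg.norm(np.diff(a, axis=0), axis=1) * 9.81 * FS
        np.testing.assert_allclose(jerk[1:], expected)

    def test_offset_invariance(self, rng):
        a = rng.normal(size=(100, 3))
        np.testing.assert_allclose(
            compute_jerk(a, FS), compute_jerk(a + 0.73, FS), atol=1e-9
        )

    def test_too_short(self):
        with pytest.raises(ValueError):
            compute_jerk(np.zeros((1, 3)), FS)


class TestVedba:
    def test_zero_dynamic(self):
        np.testing.assert_allclose(compute_vedba(np.zeros((20, 3))), 0.0)

    def test_single_axis(self):
        a = np.zeros((5, 3))
        a[2, 0] = 0.1
        assert compute_vedba(a)[2] == pytest.approx(0.981)

    def test_three_axis_norm(self):
        a = np.full((5, 3), 0.1)
        np.testing.assert_allclose(
            compute_vedba(a), 0.981 * np.sqrt(3.0), rtol=1e-9
        )

    def test_invariant_to_offset_after_static_removal(self, rng):
        fs = 10.0
        t = np.arange(6000) / fs
        a = 0.05 * np.sin(2 * np.pi * 0.15 * t)[:, None] * np.ones(3)
        _, dyn1 = static_dynamic_split(a, fs)
        _, dyn2 = static_dynamic_split(a + 0.5, fs)
        core = slice(200, -200)
        np.testing.assert_allclose(
            compute_vedba(dyn1)[core], compute_vedba(dyn2)[core], atol=1e-6
        )


class TestEstimateSpeed:
    def test_recovers_speed_from_simulator(self, sim_deployment, sim_pipeline):
        _, (diary, truth, _) = sim_deployment
        res = sim_pipeline
        assert res.speed is not None
        assert res.speed.r > 0.8
        # on steep descents the prediction should track truth within ~10%
        feats = res.features.dropna(subset=["bottom_mean_speed"])
        merged = feats.merge(truth, left_on="dive_id", right_on="dive_id")
        rel_err = np.abs(merged["bottom_mean_speed"] - merged["bottom_speed"]) \
            / merged["bottom_speed"]
        assert np.median(rel_err) < 0.10

    def test_all_horizontal_raises_calibration_error(self, rng):
        n_native, fs_native, fs_work = 20000, 50.0, 10.0
        accel = rng.normal(0, 0.02, size=(n_native, 3))
        depth = np.full(n_native // 5, 10.0)
        pitch = np.zeros(n_native // 5)  # never steep: no OCDR reference
        with pytest.raises(CalibrationError):
            estimate_speed(accel, fs_native, depth, pitch, fs_work)

    def test_slow_predictions_flagged_unreliable(self, sim_pipeline):
        sp = sim_pipeline.speed
        slow = sp.speed < SpeedConfig().min_speed
        assert not np.any(sp.reliable[np.where(np.isfinite(sp.speed) & slow)])
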