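"""Inertial gait segmentation: filtering, event detection, features, sway."""

import numpy as np
import pytest

from frailsense.imu_gait import (
    GaitEvents,
    detect_events,
    imu_features,
    lowpass,
    sternum_excursion,
)
from frailsense.synth import render_imu


def butterworth_gain_squared(
    f_hz: float, fs: float = 100.0, cutoff: float = 5.0, order: int = 4
) -> float:
    """Closed-form double-pass magnitude response of the zero-phase filter.

    The digital filter comes from the bilinear transform, so frequencies are
    prewarped (w = tan(pi f / fs)); the forward-backward pass applies the
    squared one-pass magnitude, i.e. the Butterworth power response.
    """
    w = np.tan(np.pi * f_hz / fs)
    wc = np.tan(np.pi * cutoff / fs)
    return 1.0 / (1.0 + (w / wc) ** (2 * order))


class TestLowpass:
    def test_dc_gain_is_unity(self):
        x = np.full(500, 3.7)
        assert np.allclose(lowpass(x, fs=100.0), 3.7, atol=1e-9)

    @pytest.mark.parametrize("f,comparison", [(20.0, "stop"), (1.0, "pass")])
    def test_attenuation_matches_closed_form(self, f, comparison):
        fs, dur = 100.0, 20.0
        t = np.arange(0, dur, 1 / fs)
        y = lowpass(np.sin(2 * np.pi * f * t), fs)
        core = slice(int(2 * fs), int(-2 * fs))  # avoid edge transients
        # amplitude via RMS over whole cycles (a sampled 20 Hz tone at
        # 100 Hz never hits its crest exactly)
        measured = np.sqrt(2 * np.mean(y[core] ** 2))
        expected = butterworth_gain_squared(f)
        assert measured == pytest.approx(expected, rel=0.01)
        if comparison == "stop":
            assert measured <= 1e-4
        else:
            assert measured >= 0.999

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            lowpass(np.zeros(10), fs=100.0)
        with pytest.raises(ValueError, match="sampling rate"):
            lowpass(np.zeros(100), fs=8.0)


class TestDetectEvents:
    def test_planted_events_within_one_sample(self):
        # five identical noiseless strides: event recovery at sample accuracy
        from frailsense.synth import GaitGroundTruth, simulate_gait

        gt = GaitGroundTruth(
            seed=0, n_strides=5, stride_time_sd=0.0, swing_time_sd=0.0,
            imu_noise_dps=0.0,
        )
        sch = simulate_gait(gt)
        imu = render_imu(sch, gt)
        sig = lowpass(imu.foot_gyro("right"), imu.fs)
        ev = detect_events(sig, imu.fs, foot="right")
        assert ev.n_strides == 5
        assert np.abs(ev.to - sch.to["right"]).max() <= 0.01 + 1e-9
        assert np.abs(ev.hs - sch.hs["right"]).max() <= 0.01 + 1e-9

    def test_irregular_strides_recovered_closely(self, quiet_truth, quiet_schedule):
        # variable stride times: short swings tolerate 2 samples of filter skew
        imu = render_imu(quiet_schedule, quiet_truth)
        sig = lowpass(imu.foot_gyro("right"), imu.fs)
        ev = detect_events(sig, imu.fs, foot="right")
        assert ev.n_strides == quiet_truth.n_strides
        assert np.abs(ev.to - quiet_schedule.to["right"]).max() <= 0.02 + 1e-9
        assert np.abs(ev.hs - quiet_schedule.hs["right"]).max() <= 0.02 + 1e-9

    def test_all_zero_signal_yields_no_events(self):
        ev = detect_events(np.zeros(1000), 100.0)
        assert ev.n_strides == 0

    def test_sign_convention_flag(self, quiet_truth, quiet_schedule):
        imu = render_imu(quiet_schedule, quiet_truth)
        sig = lowpass(imu.foot_gyro("left"), imu.fs)
        a = detect_events(sig, imu.fs, foot="left")
        b = detect_events(-sig, imu.fs, foot="left", sign=-1)
        assert np.array_equal(a.to, b.to)
        assert np.array_equal(a.hs, b.hs)

    def test_few_strides_warns_and_returns_empty(self):
        t = np.arange(0, 3, 0.01)
        one_cycle = np.exp(-0.5 * ((t - 1.5) / 0.07) ** 2) * 200 - 100 * (
            np.exp(-0.5 * ((t - 1.3) / 0.04) ** 2) + np.exp(-0.5 * ((t - 1.7) / 0.04) ** 2)
        )
        with pytest.warns(UserWarning, match="fewer than 2"):
            ev = detect_events(one_cycle, 100.0)
        assert ev.n_strides == 0

    @pytest.mark.parametrize("shift_samples", [10, 157])
    def test_time_shift_equivariance(self, quiet_truth, quiet_schedule, shift_samples):
        imu = render_imu(quiet_schedule, quiet_truth)
        sig = lowpass(imu.foot_gyro("right"), imu.fs)
        base = detect_events(sig, imu.fs)
        shifted = detect_events(np.concatenate([np.zeros(shift_samples), sig]), imu.fs)
        dt = shift_samples / imu.fs
        assert np.allclose(shifted.to, base.to + dt, atol=1e-9)
        assert np.allclose(shifted.hs, base.hs + dt, atol=1e-9)


def make_events(foot, to, swing):
    to = np.asarray(to, dtype=float)
    return GaitEvents(foot=foot, to=to, hs=to + swing)


class TestImuFeatures:
    def test_stride_length_from_printed_formula(self):
        ev_r = make_events("right", np.arange(20) * 2.0, 0.5)
        ev_l = make_events("left", np.arange(20) * 2.0 + 1.0, 0.5)
        feats = imu_features(ev_r, ev_l, path_length=10.0)
        assert feats.right["GSTRDLR"] == pytest.approx(0.5)
        assert feats.right["GSTRDR"] == 20

    def test_constant_strides_have_zero_sd(self):
        ev_r = make_events("right", np.arange(10) * 2.0, 0.4)
        ev_l = make_events("left", np.arange(10) * 2.0 + 1.0, 0.4)
        feats = imu_features(ev_r, ev_l)
        assert feats.right["GSTRDTR"] == pytest.approx(2.0)
        assert feats.right["GSTRDTR_SD"] == 0.0
        assert feats.right["GSWTR"] == pytest.approx(0.4)

    def test_planted_stride_time_roundtrip(self, quiet_truth, quiet_schedule):
        imu = render_imu(quiet_schedule, quiet_truth)
        events = {}
        for foot in ("right", "left"):
            sig = lowpass(imu.foot_gyro(foot), imu.fs)
            events[foot] = detect_events(sig, imu.fs, foot=foot)
        feats = imu_features(events["right"], events["left"])
        planted = np.diff(quiet_schedule.to["right"]).mean()
        assert feats.right["GSTRDTR"] == pytest.approx(planted, abs=0.02)

    def test_zero_strides_errors_with_foot_name(self):
        ev_l = make_events("left", np.arange(5) * 2.0, 0.4)
        with pytest.raises(ValueError, match="right"):
            imu_features(GaitEvents(foot="right"), ev_l)

    @pytest.mark.parametrize("seed", range(5))
    def test_phase_conservation(self, seed):
        from frailsense.synth import GaitGroundTruth, simulate_gait

        gt = GaitGroundTruth(seed=seed)
        sch = simulate_gait(gt)
        imu = render_imu(sch, gt)
        events = {
            foot: detect_events(lowpass(imu.foot_gyro(foot), imu.fs), imu.fs, foot=foot)
            for foot in ("right", "left")
        }
        feats = imu_features(events["right"], events["left"])
        for s in ("R", "L"):
            total = feats.to_series()[f"GSWT{s}"] + feats.to_series()[f"GSTT{s}"]
            assert total == pytest.approx(feats.to_series()[f"GSTRDT{s}"], rel=0.02)


class TestSternumExcursion:
    def test_zero_rate_gives_zero_excursion(self):
        thetai, sd, _ = sternum_excursion(np.zeros(1000), 100.0, [1.0, 2.0, 3.0])
        assert thetai == 0.0

    def test_half_sine_closed_form(self):
        # per-step half-sine rate with analytic integral 2 degrees
        fs, step, n_steps = 100.0, 1.2, 12
        t = np.arange(0, step * n_steps, 1 / fs)
        hs = np.arange(n_steps + 1) * step
        omega = np.zeros_like(t)
        for k in range(n_steps):
            sel = (t >= hs[k]) & (t < hs[k + 1])
            amp = 2.0 * np.pi / (2 * step)
            omega[sel] = ((-1) ** k) * amp * np.sin(np.pi * (t[sel] - hs[k]) / step)
        thetai, _, per_step = sternum_excursion(omega, fs, hs)
        assert thetai == pytest.approx(2.0, abs=0.05)
        assert per_step.size == n_steps

    def test_step_count_equals_intervals(self):
        rng = np.random.default_rng(0)
        omega = rng.normal(0, 1, 2000)
        hs = [2.0, 5.0, 8.0, 11.0, 14.0]
        _, _, per_step = sternum_excursion(omega, 100.0, hs)
        assert per_step.size == len(hs) - 1

    def test_too_few_heel_strikes_rejected(self):
        with pytest.raises(ValueError):
            sternum_excursion(np.zeros(100), 100.0, [1.0])

    def test_planted_sway_roundtrip(self, quiet_truth, quiet_schedule):
        imu = render_imu(quiet_schedule, quiet_truth)
        hs = quiet_schedule.merged_hs()
        sig = lowpass(imu.sternum_yaw_rate(), imu.fs)
        thetai, _, _ = sternum_excursion(sig, imu.fs, hs)
        assert thetai == pytest.approx(quiet_truth.torso_sway_deg, abs=0.05)
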