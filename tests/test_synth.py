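"""Generator contracts: schedules, renderers, determinism, round-trips."""

import numpy as np
import pytest
from dataclasses import replace

from frailsense.grip import grip_features
from frailsense.synth import (
    GaitGroundTruth,
    leg_position,
    render_force,
    render_imu,
    render_laser,
    render_pose,
    sample_cohort,
    simulate_gait,
)


class TestSimulateGait:
    @pytest.mark.parametrize("seed", [0, 1, 11])
    def test_event_counts_and_alternation(self, seed):
        gt = GaitGroundTruth(seed=seed)
        sch = simulate_gait(gt)
        for foot in ("right", "left"):
            assert sch.to[foot].size == gt.n_strides
            assert sch.hs[foot].size == gt.n_strides
            # TO < HS within each stride, HS < next TO
            assert np.all(sch.hs[foot] > sch.to[foot])
            assert np.all(sch.to[foot][1:] > sch.hs[foot][:-1])

    def test_feet_offset_about_half_stride(self):
        sch = simulate_gait(GaitGroundTruth(seed=4))
        frac = (sch.to["left"] - sch.to["right"]) / sch.durations["right"]
        assert np.all((frac > 0.15) & (frac < 0.85))
        assert abs(np.median(frac) - 0.5) < 0.1

    def test_zero_variance_gives_equal_strides(self):
        gt = GaitGroundTruth(n_strides=5, stride_time_sd=0.0, seed=0)
        sch = simulate_gait(gt)
        assert np.allclose(sch.durations["right"], gt.stride_time_mean)
        assert np.allclose(np.diff(sch.to["right"]), gt.stride_time_mean)

    def test_same_seed_identical_schedule(self):
        gt = GaitGroundTruth(seed=99)
        a, b = simulate_gait(gt), simulate_gait(gt)
        for foot in ("right", "left"):
            assert np.array_equal(a.to[foot], b.to[foot])
            assert np.array_equal(a.hs[foot], b.hs[foot])

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"stride_time_mean": -1.0},
            {"stride_time_mean": 0.0},
            {"swing_fraction": 0.0},
            {"swing_fraction": 1.2},
            {"n_strides": 1},
            {"path_length": -5.0},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            simulate_gait(GaitGroundTruth(**kwargs))

    def test_planted_stride_mean_monte_carlo(self):
        # sample mean of drawn stride times vs the planted population mean
        mean, sd, n_seeds = 2.32, 0.53, 100
        means = []
        for seed in range(n_seeds):
            sch = simulate_gait(GaitGroundTruth(seed=seed))
            means.append(sch.durations["right"].mean())
        grand = np.mean(means)
        se = sd / np.sqrt(n_seeds * 20)
        assert abs(grand - mean) < 3 * se


class TestRenderLaser:
    def test_scan_count_matches_rate_times_duration(self, quiet_truth, quiet_schedule):
        scans = render_laser(quiet_schedule, quiet_truth)
        expected = quiet_schedule.t_end * 10.0
        assert abs(scans.t.size - expected) <= 1

    def test_noiseless_frames_show_two_clusters(self, quiet_truth, quiet_schedule):
        from frailsense.laser_gait import extract_leg_tracks

        scans = render_laser(quiet_schedule, quiet_truth)
        tr, tl = extract_leg_tracks(scans)
        assert tr.n_frames == scans.t.size
        assert tl.n_frames == scans.t.size

    def test_leg_position_extremes_at_events(self, quiet_truth, quiet_schedule):
        # generator bookkeeping: planted x is maximal at TO, minimal at HS
        amp = quiet_truth.path_length / quiet_truth.n_strides / 2.0
        for foot in ("right", "left"):
            x_to = leg_position(quiet_schedule, quiet_truth, foot, quiet_schedule.to[foot])
            x_hs = leg_position(quiet_schedule, quiet_truth, foot, quiet_schedule.hs[foot])
            assert np.allclose(x_to, 0.5 + amp, atol=1e-12)
            assert np.allclose(x_hs, 0.5, atol=1e-12)

    def test_determinism(self, default_truth, default_schedule):
        a = render_laser(default_schedule, default_truth)
        b = render_laser(default_schedule, default_truth)
        assert np.array_equal(a.ranges_mm, b.ranges_mm, equal_nan=True)

    def test_dropout_removes_one_leg(self):
        gt = GaitGroundTruth(seed=5, laser_dropout=0.3, laser_noise_mm=0.0)
        scans = render_laser(simulate_gait(gt), gt)
        n_returns = np.isfinite(scans.ranges_mm).sum(axis=1)
        assert (n_returns < n_returns.max() * 0.7).any()
        assert (n_returns > 0).all()


class TestRenderImu:
    def test_sample_count(self, quiet_truth, quiet_schedule):
        imu = render_imu(quiet_schedule, quiet_truth)
        assert abs(imu.t.size - quiet_schedule.t_end * 100.0) <= 1

    def test_planted_troughs_recoverable_noiseless(self, quiet_truth, quiet_schedule):
        imu = render_imu(quiet_schedule, quiet_truth)
        gy = imu.foot_gyro("right")
        for ev in np.concatenate([quiet_schedule.to["right"], quiet_schedule.hs["right"]]):
            i = int(round(ev * 100))
            window = gy[i - 5 : i + 6]
            assert np.argmin(window) in (4, 5, 6)  # trough within +-1 sample

    def test_zero_sway_sternum_is_noise(self):
        gt = GaitGroundTruth(seed=2, torso_sway_deg=0.0)
        sch = simulate_gait(gt)
        gz = render_imu(sch, gt).sternum_yaw_rate()
        assert abs(gz.mean()) < 0.05
        assert gz.std() < 3 * gt.imu_noise_dps

    def test_determinism(self, default_truth, default_schedule):
        a = render_imu(default_schedule, default_truth)
        b = render_imu(default_schedule, default_truth)
        assert a.data.equals(b.data)


class TestRenderPose:
    def test_level_shoulders_give_zero_theta(self):
        from frailsense.posture import shoulder_geometry

        gt = GaitGroundTruth(seed=1, shoulder_theta_deg=0.0, pose_noise_px=0.0)
        pose = render_pose(simulate_gait(gt), gt)
        thetas = [shoulder_geometry(f.people[0])[1] for f in pose.frames]
        assert np.allclose(thetas, 0.0, atol=1e-9)

    def test_planted_dis_roundtrip_within_one_pixel(self):
        from frailsense.posture import posture_features

        gt = GaitGroundTruth(seed=1)
        pose = render_pose(simulate_gait(gt), gt)
        feats = posture_features(pose)
        assert abs(feats.to_series()["DIS"] - gt.nose_neck_px) < 1.0

    def test_distractor_toggle(self):
        gt = GaitGroundTruth(seed=1)
        sch = simulate_gait(gt)
        solo = render_pose(sch, gt)
        assert all(len(f.people) == 1 for f in solo.frames)
        dual = render_pose(sch, replace(gt, pose_distractor=True))
        assert all(len(f.people) == 2 for f in dual.frames)

    def test_depth_spans_planted_range(self):
        gt = GaitGroundTruth(seed=1)
        pose = render_pose(simulate_gait(gt), gt)
        z = np.array([f.people[0].neck_depth_mm for f in pose.frames])
        assert z.min() == pytest.approx(gt.neck_depth_min_mm, abs=2.0)
        assert z.max() == pytest.approx(gt.neck_depth_max_mm, abs=2.0)


class TestRenderForce:
    def test_noiseless_plateau_equals_planted_total(self):
        gt = GaitGroundTruth(seed=0, grip_peak_right=80.0, force_noise_n=0.0)
        series = render_force(gt)
        right = series.forces.iloc[:, :8].sum(axis=1)
        assert right.max() == pytest.approx(80.0, abs=1e-9)

    def test_zero_grip_all_zero(self):
        gt = GaitGroundTruth(seed=0, grip_peak_right=0.0, grip_peak_left=0.0, force_noise_n=0.0)
        assert (render_force(gt).forces.to_numpy() == 0).all()

    def test_mfr_roundtrip_within_two_percent(self):
        gt = GaitGroundTruth(seed=0)  # defaults: 76.52 N plateau, 1 N noise
        feats = grip_features(render_force(gt))
        assert feats.MFR == pytest.approx(gt.grip_peak_right, rel=0.02)
        assert feats.MFL == pytest.approx(gt.grip_peak_left, rel=0.02)


class TestSampleCohort:
    def test_walker_subjects_last_and_flagged(self):
        cohort = sample_cohort(10, 2, seed=1)
        assert len(cohort) == 10
        assert [c.walker_user for c in cohort] == [False] * 8 + [True] * 2

    def test_walker_profile_is_impaired(self):
        cohort = sample_cohort(10, 2, seed=1)
        healthy = [c for c in cohort if not c.walker_user]
        walkers = [c for c in cohort if c.walker_user]
        assert min(w.stride_time_mean for w in walkers) > max(
            h.stride_time_mean for h in healthy
        ) - 0.5
        assert np.mean([w.grip_peak_right for w in walkers]) < np.mean(
            [h.grip_peak_right for h in healthy]
        )

    def test_deterministic(self):
        assert sample_cohort(5, 1, seed=3) == sample_cohort(5, 1, seed=3)
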