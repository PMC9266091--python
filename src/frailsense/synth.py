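"""Synthetic multimodal sensor streams from one planted walking ground truth.

A single :class:`GaitGroundTruth` (stride timing, swing/stance split, torso
sway, posture geometry, grip peaks) drives four renderers that emulate the
robot's and the wearables' raw streams for a 10 m assisted walk:

* :func:`render_laser`  — 10 Hz rear range scans showing two shank arcs,
* :func:`render_imu`    — 100 Hz foot and sternum gyroscopes,
* :func:`render_pose`   — 30 fps 4-keypoint pose frames with neck depth,
* :func:`render_force`  — 16-channel handle force during a 5 s grip hold.

Because every downstream extractor is exercised against the planted values,
the generator is deliberately analytic: leg motion is piecewise-linear in
robot-relative x between gait events, foot gyro cycles are sums of Gaussian
lobes with troughs exactly at toe-off and heel-strike, and the sternum rate
is a per-step half-sine whose integral equals the planted sway.  All noise
is additive Gaussian and every renderer is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .grip import CHANNEL_NAMES, ForceSeries
from .imu_gait import IMU_CHANNELS, IMU_SENSORS, ImuSeries
from .laser_gait import (
    LASER_MAX_RANGE_MM,
    LASER_RATE_HZ,
    LaserScanSeries,
    beam_angles_rad,
)
from .posture import PersonPose, PoseFrame, PoseFrameSeries

__all__ = [
    "GaitGroundTruth",
    "EventSchedule",
    "simulate_gait",
    "render_laser",
    "render_imu",
    "render_pose",
    "render_force",
    "sample_cohort",
]

#: Minimum physically plausible stride duration (truncation floor), seconds.
STRIDE_FLOOR_S = 0.2
LEG_RADIUS_M = 0.06  # 0.12 m diameter shank cylinder
LEG_Y_OFFSET_M = 0.15  # lateral half-separation of the feet
LEG_X_MIN_M = 0.5  # nearest robot-relative foot position
REF_GRIP_N = 76.52  # reference plateau at which force_noise_n is specified


@dataclass
class GaitGroundTruth:
    """Planted walking/posture/grip parameters for one synthetic subject.

    Defaults describe a typical older adult walking 10 m with robot support:
    ~2.3 s strides covering ~0.5 m each, a fifth of the cycle in swing,
    ~1 degree of torso sway per step and ~77 N of grip strength.
    """

    n_strides: int = 20
    stride_time_mean: float = 2.32  # s
    stride_time_sd: float = 0.53  # s, within-subject stride variability
    swing_fraction: float = 0.19
    swing_time_sd: float = 0.08  # s, within-subject swing variability
    path_length: float = 10.0  # m
    torso_sway_deg: float = 1.08
    grip_peak_right: float = 76.52  # N
    grip_peak_left: float = 78.01  # N
    # posture plant
    shoulder_theta_deg: float = 2.46
    nose_neck_px: float = 144.6
    neck_depth_min_mm: float = 575.3
    neck_depth_max_mm: float = 794.5
    pose_sway_px: float = 3.0
    # noise / nuisance controls
    laser_noise_mm: float = 5.0
    laser_dropout: float = 0.0  # per-frame probability of losing one leg
    imu_noise_dps: float = 0.2  # XSens-class gyro noise at 100 Hz
    pose_noise_px: float = 0.5
    pose_dropout: float = 0.0
    pose_distractor: bool = False
    force_noise_n: float = 1.0  # SD of the per-hand summed profile
    # left/right phase offset as a fraction of the stride (0.5 = symmetric)
    phase_offset: float = 0.5
    walker_user: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_strides < 2:
            raise ValueError("n_strides must be >= 2")
        if self.stride_time_mean <= 0 or self.stride_time_sd < 0:
            raise ValueError("stride timing parameters must be positive")
        if not 0 < self.swing_fraction < 1:
            raise ValueError("swing_fraction must lie in (0, 1)")
        if self.path_length <= 0:
            raise ValueError("path_length must be positive")
        if self.grip_peak_right < 0 or self.grip_peak_left < 0:
            raise ValueError("grip peaks must be non-negative")
        if self.neck_depth_min_mm > self.neck_depth_max_mm:
            raise ValueError("neck depth min exceeds max")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic substream per renderer."""
        return np.random.default_rng([int(self.seed) % (2**31), stream])

    def low_noise(self) -> "GaitGroundTruth":
        """Copy of this config under the benign low-noise sensing conditions
        used for parameter-recovery checks (sensors behaving at the favourable
        end of their spec sheets)."""
        return replace(
            self,
            laser_noise_mm=2.0,
            imu_noise_dps=0.1,
            pose_noise_px=0.2,
            force_noise_n=0.3,
        )


@dataclass
class EventSchedule:
    """Planted gait event times (seconds) for both feet.

    Per foot: ``to`` and ``hs`` alternate strictly (``to[i] < hs[i] <
    to[i+1]``); stride ``i`` spans ``to[i]`` to ``to[i] + durations[i]``.
    ``t_start``/``t_end`` bound the rendered recording including lead-in and
    lead-out.
    """

    to: dict = field(default_factory=dict)  # foot -> np.ndarray
    hs: dict = field(default_factory=dict)
    durations: dict = field(default_factory=dict)
    t_start: float = 0.0
    t_end: float = 0.0

    def merged_hs(self) -> np.ndarray:
        return np.sort(np.concatenate([self.hs["right"], self.hs["left"]]))

    def n_strides(self, foot: str) -> int:
        return int(self.to[foot].size)


LEAD_S = 1.0  # quiet lead-in/lead-out around the walk


def simulate_gait(config: GaitGroundTruth) -> EventSchedule:
    """Draw the stride schedule for both feet from the planted parameters.

    Stride durations come from a normal truncated below at 0.2 s; the left
    foot starts ``phase_offset`` of a stride after the right.  Exactly
    ``n_strides`` TO and HS events are produced per foot.
    """
    config.validate()
    rng = config.rng(0)

    def draw(n: int) -> np.ndarray:
        if config.stride_time_sd == 0:
            return np.full(n, config.stride_time_mean)
        a = (STRIDE_FLOOR_S - config.stride_time_mean) / config.stride_time_sd
        return truncnorm.rvs(
            a, np.inf, loc=config.stride_time_mean, scale=config.stride_time_sd,
            size=n, random_state=rng,
        )

    schedule = EventSchedule(t_start=0.0)
    # Right foot carries the stride draw; the left foot steps in between at
    # phase_offset of the concurrent right stride (plus a small timing
    # jitter).  Deriving the left foot from the right keeps the feet strictly
    # alternating at ~half-stride offset, as in real gait — independent
    # per-foot draws would let the feet drift past each other.
    d_r = draw(config.n_strides)
    to_r = LEAD_S + np.concatenate([[0.0], np.cumsum(d_r[:-1])])
    jitter = rng.normal(0.0, 0.02, config.n_strides) if config.stride_time_sd > 0 else 0.0
    to_l = to_r + np.clip(config.phase_offset + jitter / d_r, 0.15, 0.85) * d_r
    d_l = np.append(np.diff(to_l), d_r[-1])
    t_end = 0.0
    for foot, to, d in (("right", to_r, d_r), ("left", to_l, d_l)):
        # swing time is largely speed-invariant in human gait: slow strides
        # lengthen stance, not swing.  The planted swing is therefore tied to
        # the subject's mean stride (with its own, much smaller, stride-to-
        # stride jitter) and floored at a physiological 0.25 s.
        swing = config.swing_fraction * config.stride_time_mean + (
            rng.normal(0.0, config.swing_time_sd, config.n_strides)
            if config.swing_time_sd > 0
            else 0.0
        )
        swing = np.clip(swing, 0.25, 0.6 * d)
        schedule.to[foot] = to
        schedule.hs[foot] = to + swing
        schedule.durations[foot] = d
        t_end = max(t_end, to[-1] + d[-1])
    schedule.t_end = t_end + LEAD_S
    return schedule


def _leg_x_nodes(
    schedule: EventSchedule, foot: str, amplitude: float
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-linear node list of robot-relative x for one foot.

    x sits at its maximum at every TO, its minimum at every HS (swing moves
    the foot toward the robot, stance away).  A lead-in ramp from the
    minimum up to the first TO makes the first TO a detectable maximum; the
    track then holds the final maximum flat to the end of the recording.
    """
    x_min, x_max = LEG_X_MIN_M, LEG_X_MIN_M + amplitude
    to, hs, d = schedule.to[foot], schedule.hs[foot], schedule.durations[foot]
    times = [schedule.t_start]
    xs = [x_min]
    for i in range(to.size):
        times += [to[i], hs[i]]
        xs += [x_max, x_min]
    times.append(to[-1] + d[-1])
    xs.append(x_max)
    times.append(schedule.t_end)
    xs.append(x_max)
    return np.asarray(times), np.asarray(xs)


def leg_position(
    schedule: EventSchedule, config: GaitGroundTruth, foot: str, t: np.ndarray
) -> np.ndarray:
    """Planted robot-relative x of one foot at times ``t`` (bookkeeping)."""
    amplitude = config.path_length / config.n_strides / 2.0
    nodes_t, nodes_x = _leg_x_nodes(schedule, foot, amplitude)
    return np.interp(t, nodes_t, nodes_x)


def render_laser(schedule: EventSchedule, config: GaitGroundTruth) -> LaserScanSeries:
    """Render 10 Hz range scans of two 0.12 m cylinders at the planted leg x.

    The per-stride amplitude of the relative motion is half the per-stride
    ground distance, so the total variation of x over one stride equals the
    planted stride length.  Optional dropout deletes one leg's returns for a
    whole frame; Gaussian range noise is added beam-wise.
    """
    rng = config.rng(1)
    t = np.arange(schedule.t_start, schedule.t_end, 1.0 / LASER_RATE_HZ)
    angles = beam_angles_rad()
    cos_a, sin_a = np.cos(angles), np.sin(angles)

    leg_y = {"right": -LEG_Y_OFFSET_M, "left": LEG_Y_OFFSET_M}
    per_leg = {}
    for foot in ("right", "left"):
        cx = leg_position(schedule, config, foot, t)[:, None]  # (F,1)
        cy = leg_y[foot]
        t_c = cx * cos_a[None, :] + cy * sin_a[None, :]
        d2 = cx**2 + cy**2 - t_c**2
        hit = (d2 <= LEG_RADIUS_M**2) & (t_c > 0)
        rr = np.full((t.size, angles.size), np.inf)
        rr[hit] = t_c[hit] - np.sqrt(LEG_RADIUS_M**2 - d2[hit])
        per_leg[foot] = rr

    if config.laser_dropout > 0:
        drop = rng.random(t.size) < config.laser_dropout
        which = rng.random(t.size) < 0.5
        per_leg["right"][drop & which] = np.inf
        per_leg["left"][drop & ~which] = np.inf

    ranges_m = np.minimum(per_leg["right"], per_leg["left"])
    ranges_mm = ranges_m * 1000.0
    finite = np.isfinite(ranges_mm)
    if config.laser_noise_mm > 0:
        noise = rng.normal(0.0, config.laser_noise_mm, size=ranges_mm.shape)
        ranges_mm = np.where(finite, ranges_mm + noise, np.nan)
    else:
        ranges_mm = np.where(finite, ranges_mm, np.nan)
    ranges_mm = np.clip(ranges_mm, 1.0, LASER_MAX_RANGE_MM)
    return LaserScanSeries(t=t, ranges_mm=ranges_mm)


# foot-gyro template amplitudes (deg/s) and trough width (s)
SWING_PEAK_DPS = 200.0
TROUGH_DPS = 100.0
TROUGH_WIDTH_S = 0.04


def _foot_gyro_template(
    t: np.ndarray, to: np.ndarray, hs: np.ndarray, durations: np.ndarray
) -> np.ndarray:
    """Canonical sagittal foot-gyro cycle: mid-swing lobe + TO/HS troughs."""
    sig = np.zeros_like(t)
    for i in range(to.size):
        mid = 0.5 * (to[i] + hs[i])
        swing = hs[i] - to[i]
        # narrow enough that the lobe has decayed at the flanking troughs
        # even for the shortest plausible swings
        sigma_s = max(swing / 6.0, 0.025)
        sig += SWING_PEAK_DPS * np.exp(-0.5 * ((t - mid) / sigma_s) ** 2)
        for ev in (to[i], hs[i]):
            sig -= TROUGH_DPS * np.exp(-0.5 * ((t - ev) / TROUGH_WIDTH_S) ** 2)
    return sig


def render_imu(
    schedule: EventSchedule, config: GaitGroundTruth, fs: float = 100.0
) -> ImuSeries:
    """Render 100 Hz gyro/accel streams for both feet and the sternum.

    Foot ``gy`` carries the event template (troughs exactly at the planted
    TO/HS); sternum ``gz`` is a per-step half-sine of alternating sign whose
    integral per step equals ``torso_sway_deg``.  Accelerometer channels are
    gravity plus noise (they are not used by the extractors).
    """
    rng = config.rng(2)
    t = np.arange(schedule.t_start, schedule.t_end, 1.0 / fs)
    cols = {}

    for foot in ("right", "left"):
        gy = _foot_gyro_template(
            t, schedule.to[foot], schedule.hs[foot], schedule.durations[foot]
        )
        for ch in IMU_CHANNELS:
            base = gy if ch == "gy" else np.zeros_like(t)
            if ch == "az":
                base = base + 9.81
            noise_sd = config.imu_noise_dps if ch.startswith("g") else 0.05
            cols[f"{foot}_foot_{ch}"] = base + rng.normal(0, noise_sd, t.size)

    gz = np.zeros_like(t)
    hs = schedule.merged_hs()
    for k, (a, b) in enumerate(zip(hs[:-1], hs[1:])):
        step = b - a
        amp = config.torso_sway_deg * np.pi / (2.0 * step)
        sel = (t >= a) & (t < b)
        gz[sel] += ((-1.0) ** k) * amp * np.sin(np.pi * (t[sel] - a) / step)
    for ch in IMU_CHANNELS:
        base = gz if ch == "gz" else np.zeros_like(t)
        if ch == "az":
            base = base + 9.81
        noise_sd = config.imu_noise_dps if ch.startswith("g") else 0.05
        cols[f"sternum_{ch}"] = base + rng.normal(0, noise_sd, t.size)

    order = [f"{s}_{c}" for s in IMU_SENSORS for c in IMU_CHANNELS]
    return ImuSeries(t=t, data=pd.DataFrame({k: cols[k] for k in order}), fs=fs)


def render_pose(
    schedule: EventSchedule, config: GaitGroundTruth, fps: float = 30.0
) -> PoseFrameSeries:
    """Render 30 fps 4-keypoint pose frames with neck depth.

    The planted geometry is constant (shoulder inclination, nose-neck
    distance); a per-stride lateral sinusoid moves all keypoints together
    (common-mode sway) and the neck depth oscillates between the planted
    extremes at the stride cadence.  Optionally a distractor person offset by
    300 px is added and random frames are dropped.
    """
    rng = config.rng(3)
    t = np.arange(schedule.t_start, schedule.t_end, 1.0 / fps)
    theta = np.deg2rad(config.shoulder_theta_deg)
    half_w = 80.0  # shoulder half-width, px
    neck0 = np.array([640.0, 300.0])
    stride = config.stride_time_mean

    sway = config.pose_sway_px * np.sin(2 * np.pi * t / stride)
    depth_mid = 0.5 * (config.neck_depth_min_mm + config.neck_depth_max_mm)
    depth_amp = 0.5 * (config.neck_depth_max_mm - config.neck_depth_min_mm)
    depth = depth_mid + depth_amp * np.sin(2 * np.pi * t / stride + np.pi / 4)

    frames: list[PoseFrame] = []
    for i, ti in enumerate(t):
        if config.pose_dropout > 0 and i > 0 and rng.random() < config.pose_dropout:
            frames.append(PoseFrame(t=ti, people=[]))
            continue
        neck = neck0 + np.array([sway[i], 0.0])
        nose = neck + np.array([0.0, -config.nose_neck_px])
        sh = half_w * np.array([np.cos(theta), np.sin(theta)])
        l_sh = neck + sh
        r_sh = neck - sh

        def kp(p: np.ndarray) -> tuple[float, float, float]:
            q = p + rng.normal(0, config.pose_noise_px, 2)
            return (float(q[0]), float(q[1]), float(rng.uniform(0.7, 1.0)))

        people = [
            PersonPose(
                keypoints={
                    "nose": kp(nose),
                    "neck": kp(neck),
                    "r_shoulder": kp(r_sh),
                    "l_shoulder": kp(l_sh),
                },
                neck_depth_mm=float(depth[i]),
            )
        ]
        if config.pose_distractor:
            # a bystander at the edge of the frame: offset 300 px, detected
            # with visibly lower keypoint confidence than the assisted user
            off = np.array([300.0, 40.0])

            def kp_low(p: np.ndarray) -> tuple[float, float, float]:
                q = p + rng.normal(0, config.pose_noise_px, 2)
                return (float(q[0]), float(q[1]), float(rng.uniform(0.35, 0.6)))

            people.append(
                PersonPose(
                    keypoints={
                        "nose": kp_low(nose + off),
                        "neck": kp_low(neck + off),
                        "r_shoulder": kp_low(r_sh + off),
                        "l_shoulder": kp_low(l_sh + off),
                    },
                    neck_depth_mm=float(depth[i] + 500.0),
                )
            )
        frames.append(PoseFrame(t=float(ti), people=people))
    return PoseFrameSeries(frames=frames, fps=fps)


def render_force(
    config: GaitGroundTruth, fs: float = 100.0, hold_s: float = 5.0
) -> ForceSeries:
    """Render the 16-channel grip recording: ramp, 5 s hold, release.

    Each hand's 8 channels share the planted total according to a fixed
    random split; at the plateau the channel sum equals the planted peak.
    ``force_noise_n`` is the SD of the per-hand summed profile (per-channel
    SD is ``force_noise_n / sqrt(8)``), and forces are clipped at zero.
    """
    if config.grip_peak_right < 0 or config.grip_peak_left < 0:
        raise ValueError("grip peaks must be non-negative")
    rng = config.rng(4)
    ramp, release, rest = 2.0, 1.5, 1.0
    total = rest + ramp + hold_s + release + rest
    t = np.arange(0.0, total, 1.0 / fs)
    env = np.interp(
        t,
        [0, rest, rest + ramp, rest + ramp + hold_s, rest + ramp + hold_s + release, total],
        [0, 0, 1, 1, 0, 0],
    )

    data = {}
    peaks = {"right": config.grip_peak_right, "left": config.grip_peak_left}
    ch_of_hand = {"right": range(0, 8), "left": range(8, 16)}
    for hand, peak in peaks.items():
        shares = rng.dirichlet(np.full(8, 5.0))
        # sensor noise scales with the reading (%-of-load accuracy):
        # force_noise_n is the SD of the summed profile at the 76.52 N
        # reference plateau
        sd_frac = config.force_noise_n / np.sqrt(8) / REF_GRIP_N
        for j, ch in enumerate(ch_of_hand[hand]):
            sig = peak * shares[j] * env
            if config.force_noise_n > 0:
                sig = sig + rng.normal(0.0, 1.0, t.size) * sd_frac * peak * env
            data[CHANNEL_NAMES[ch]] = np.clip(sig, 0.0, None)
    return ForceSeries(t=t, forces=pd.DataFrame(data)[list(CHANNEL_NAMES)])


# ---------------------------------------------------------------------------
# cohort sampling

#: Population parameters for per-subject draws (means/SDs of the emulated
#: study population).  Walker-dependent subjects walk slower with shorter
#: strides, sway more, and grip weaker.
_HEALTHY = dict(
    stride_time=(2.2, 0.35),
    strides=(19.0, 3.0),
    swing=(0.19, 0.02),
    sway=(1.1, 0.5),
    grip=(85.0, 25.0),
    theta=(2.5, 1.0),
)
_WALKER = dict(
    stride_time=(3.4, 0.35),
    strides=(29.0, 3.0),
    swing=(0.15, 0.015),
    sway=(3.5, 0.8),
    grip=(35.0, 10.0),
    theta=(6.0, 2.0),
)


def sample_cohort(
    n_subjects: int = 10,
    n_walker: int = 2,
    seed: int = 0,
    base: GaitGroundTruth | None = None,
) -> list[GaitGroundTruth]:
    """Draw per-subject ground truths for a synthetic cohort.

    The last ``n_walker`` subjects carry the impaired (walker-dependent)
    profile.  Per-subject parameters are drawn around the population values
    and stored in independent :class:`GaitGroundTruth` configs whose seeds
    derive from ``seed``.
    """
    if n_walker > n_subjects:
        raise ValueError("n_walker cannot exceed n_subjects")
    base = base if base is not None else GaitGroundTruth()
    rng = np.random.default_rng([seed % (2**31), 99])
    cohort = []
    for i in range(n_subjects):
        impaired = i >= n_subjects - n_walker
        pop = _WALKER if impaired else _HEALTHY

        def norm(key, lo, hi):
            mu, sd = pop[key]
            return float(np.clip(rng.normal(mu, sd), lo, hi))

        cfg = replace(
            base,
            n_strides=int(np.clip(round(rng.normal(*pop["strides"])), 8, 45)),
            stride_time_mean=norm("stride_time", 1.2, 5.0),
            stride_time_sd=float(rng.uniform(0.2, 0.5)),
            swing_fraction=norm("swing", 0.08, 0.4),
            torso_sway_deg=norm("sway", 0.2, 8.0),
            grip_peak_right=norm("grip", 8.0, 160.0),
            grip_peak_left=norm("grip", 8.0, 160.0),
            shoulder_theta_deg=norm("theta", 0.3, 12.0),
            nose_neck_px=float(np.clip(rng.normal(144.6, 14.8), 100.0, 190.0)),
            neck_depth_min_mm=float(np.clip(rng.normal(575.3, 40.0), 450.0, 700.0)),
            walker_user=impaired,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        cfg = replace(
            cfg,
            neck_depth_max_mm=float(
                cfg.neck_depth_min_mm + np.clip(rng.normal(219.0, 30.0), 60.0, 400.0)
            ),
        )
        cohort.append(cfg)
    return cohort
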