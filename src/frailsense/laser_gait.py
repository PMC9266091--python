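"""Gait features from a robot-mounted 2-D scanning laser.

The rear-facing range finder (240 deg field, 0.36 deg angular step, 10 Hz,
4 m reach) sees the user's shanks as two small arcs behind the robot.  Each
scan is converted to Cartesian points, points inside a leg search window are
clustered, and the two cluster centroids are tracked over time.  Only the
coordinate along the walking direction (x, robot at the origin) is analysed:
during swing the foot approaches the robot (x decreases), during stance the
robot pulls away (x increases), so local maxima of x mark toe-off (TO) and
local minima heel-strike (HS).  From these events the same 18 gait features
as the inertial route are computed; stride length here is the length of the
x-curve travelled between consecutive TO points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .imu_gait import GaitEvents, GaitFeatures, single_foot_features

__all__ = [
    "LaserScanSeries",
    "LegTrack",
    "extract_leg_tracks",
    "segment_track",
    "laser_features",
    "LASER_FOV_DEG",
    "LASER_ANGULAR_STEP_DEG",
    "LASER_MAX_RANGE_MM",
    "LASER_RATE_HZ",
]

LASER_FOV_DEG = 240.0
LASER_ANGULAR_STEP_DEG = 0.36
LASER_MAX_RANGE_MM = 4000.0
LASER_RATE_HZ = 10.0
#: Number of beams on the fixed angular grid.
N_BEAMS = int(round(LASER_FOV_DEG / LASER_ANGULAR_STEP_DEG)) + 1  # 667


def beam_angles_rad() -> np.ndarray:
    """Fixed angular grid, centred on the walking direction (x axis)."""
    half = np.deg2rad(LASER_FOV_DEG / 2)
    return np.linspace(-half, half, N_BEAMS)


@dataclass
class LaserScanSeries:
    """Timestamped range scans on the fixed angular grid (mm, NaN = no return)."""

    t: np.ndarray
    ranges_mm: np.ndarray  # (n_scans, N_BEAMS)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.ranges_mm = np.asarray(self.ranges_mm, dtype=float)
        if self.ranges_mm.shape != (self.t.size, N_BEAMS):
            raise ValueError(
                f"ranges must be (n_scans, {N_BEAMS}); got {self.ranges_mm.shape}"
            )
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("scan timestamps must be strictly increasing")
        finite = self.ranges_mm[np.isfinite(self.ranges_mm)]
        if finite.size and (finite.min() <= 0 or finite.max() > LASER_MAX_RANGE_MM):
            raise ValueError(f"ranges must lie in (0, {LASER_MAX_RANGE_MM}] mm")


@dataclass
class LegTrack:
    """Robot-relative x position of one foot on the retained frames (m)."""

    foot: str
    t: np.ndarray
    x: np.ndarray
    retained: np.ndarray  # boolean mask over the original frames

    @property
    def n_frames(self) -> int:
        return int(self.t.size)


def _cluster_by_gap(points: np.ndarray, gap_m: float) -> list[np.ndarray]:
    """Split angularly-ordered points where consecutive points jump > gap_m."""
    if points.shape[0] == 0:
        return []
    jumps = np.linalg.norm(np.diff(points, axis=0), axis=1)
    breaks = np.flatnonzero(jumps > gap_m) + 1
    return [c for c in np.split(points, breaks) if c.shape[0] > 0]


def extract_leg_tracks(
    scans: LaserScanSeries,
    *,
    x_window: tuple[float, float] = (0.2, 1.5),
    y_halfwidth: float = 0.5,
    cluster_gap_m: float = 0.15,
) -> tuple[LegTrack, LegTrack]:
    """Detect and track the two leg centroids across scans.

    Frames in which the leg window does not contain exactly two clusters are
    dropped (the documented noise-removal rule: the laser "did not see two
    centroids").  Left/right labels come from the lateral (y) sign on the
    first accepted frame and are maintained by nearest-centroid association.
    """
    if scans.t.size < 10:
        raise ValueError("need at least 10 scans")
    angles = beam_angles_rad()
    cos_a, sin_a = np.cos(angles), np.sin(angles)

    n = scans.t.size
    retained = np.zeros(n, dtype=bool)
    cx = {"left": [], "right": []}
    times = []
    prev: dict[str, np.ndarray] | None = None
    for i in range(n):
        r = scans.ranges_mm[i] / 1000.0  # m
        ok = np.isfinite(r)
        pts = np.column_stack([r[ok] * cos_a[ok], r[ok] * sin_a[ok]])
        in_win = (
            (pts[:, 0] > x_window[0])
            & (pts[:, 0] <= x_window[1])
            & (np.abs(pts[:, 1]) <= y_halfwidth)
        )
        clusters = _cluster_by_gap(pts[in_win], cluster_gap_m)
        if len(clusters) != 2:
            continue
        centroids = np.array([c.mean(axis=0) for c in clusters])
        if prev is None:
            # lateral sign on the first accepted frame fixes the labels
            order = np.argsort(centroids[:, 1])  # ascending y: right (-) first
            assign = {"right": centroids[order[0]], "left": centroids[order[1]]}
        else:
            d00 = np.linalg.norm(centroids[0] - prev["right"]) + np.linalg.norm(
                centroids[1] - prev["left"]
            )
            d01 = np.linalg.norm(centroids[0] - prev["left"]) + np.linalg.norm(
                centroids[1] - prev["right"]
            )
            if d00 <= d01:
                assign = {"right": centroids[0], "left": centroids[1]}
            else:
                assign = {"right": centroids[1], "left": centroids[0]}
        prev = assign
        retained[i] = True
        times.append(scans.t[i])
        for foot in ("right", "left"):
            cx[foot].append(assign[foot][0])

    n_kept = int(retained.sum())
    if n_kept == 0:
        raise ValueError("no scan contained two leg centroids")
    if n_kept < 0.5 * n:
        warnings.warn(
            f"only {n_kept}/{n} scans retained two leg centroids", stacklevel=2
        )
    t_arr = np.asarray(times)
    return (
        LegTrack("right", t_arr, np.asarray(cx["right"]), retained.copy()),
        LegTrack("left", t_arr, np.asarray(cx["left"]), retained.copy()),
    )


def _refine_extremum(t: np.ndarray, x: np.ndarray, idx: int) -> float:
    """Sub-sample apex time by intersecting the flanking linear segments.

    The leg's robot-relative x is close to piecewise-linear between gait
    events, so the apex lies at the crossing of the incoming and outgoing
    slopes; at a 10 Hz scan rate the raw argmax is otherwise biased toward
    the shallower side.  Falls back to the sample time near the track ends
    or for degenerate slopes.
    """
    if idx < 2 or idx + 2 >= t.size:
        return float(t[idx])
    sl = (x[idx - 1] - x[idx - 2]) / (t[idx - 1] - t[idx - 2])
    sr = (x[idx + 2] - x[idx + 1]) / (t[idx + 2] - t[idx + 1])
    if not np.isfinite(sl) or not np.isfinite(sr) or abs(sl - sr) < 1e-12:
        return float(t[idx])
    ts = (x[idx + 1] - x[idx - 1] + sl * t[idx - 1] - sr * t[idx + 1]) / (sl - sr)
    if not t[idx - 1] <= ts <= t[idx + 1]:
        return float(t[idx])
    return float(ts)


def segment_track(
    track: LegTrack,
    *,
    prominence_frac: float = 0.25,
    refine: bool = True,
) -> GaitEvents:
    """Locate TO (local maxima of x) and HS (local minima) on a leg track.

    Extrema are prominence-gated at ``prominence_frac`` of the track's
    peak-to-peak amplitude; missing frames are not interpolated, the search
    runs on the retained timestamps.  With ``refine`` the event times are
    sharpened to sub-scan resolution by intersecting the flanking linear
    segments.  A monotone (event-free) track yields an empty event set with
    a warning.
    """
    x = np.asarray(track.x, dtype=float)
    if x.size < 4 or np.ptp(x) == 0:
        warnings.warn(f"{track.foot} track has no oscillation; no events", stacklevel=2)
        return GaitEvents(foot=track.foot)
    prom = prominence_frac * np.ptp(x)
    max_idx, _ = find_peaks(x, prominence=prom)
    min_idx, _ = find_peaks(-x, prominence=prom)
    if max_idx.size == 0 or min_idx.size == 0:
        warnings.warn(f"{track.foot} track is monotone; no events", stacklevel=2)
        return GaitEvents(foot=track.foot)

    # pair each TO with the first following HS; enforce strict alternation
    to_idx, hs_idx = [], []
    for m in max_idx:
        after = min_idx[min_idx > m]
        if after.size == 0:
            break
        h = after[0]
        if to_idx and h == hs_idx[-1]:
            continue  # two maxima sharing a minimum: keep the earlier
        to_idx.append(m)
        hs_idx.append(h)
    if len(to_idx) == 0:
        return GaitEvents(foot=track.foot)
    if refine:
        to_t = [_refine_extremum(track.t, x, i) for i in to_idx]
        hs_t = [_refine_extremum(track.t, x, i) for i in hs_idx]
    else:
        to_t = list(track.t[np.asarray(to_idx)])
        hs_t = list(track.t[np.asarray(hs_idx)])
    return GaitEvents(foot=track.foot, to=np.asarray(to_t), hs=np.asarray(hs_t))


def stride_curve_lengths(events: GaitEvents, track: LegTrack) -> np.ndarray:
    """Per-stride curve length: total variation of x between consecutive TOs (m)."""
    lengths = []
    for a, b in zip(events.to[:-1], events.to[1:]):
        sel = (track.t >= a - 1e-9) & (track.t <= b + 1e-9)
        if sel.sum() < 2:
            continue
        lengths.append(float(np.sum(np.abs(np.diff(track.x[sel])))))
    return np.asarray(lengths)


def laser_features(
    events_right: GaitEvents,
    events_left: GaitEvents,
    track_right: LegTrack,
    track_left: LegTrack,
) -> GaitFeatures:
    """Compute the 18 gait features from laser leg tracks.

    Identical feature set to the inertial route except stride length, which
    is the mean per-stride curve length of the robot-relative x trajectory.
    """
    per_foot = {}
    for ev, tr in ((events_right, track_right), (events_left, track_left)):
        if ev.n_strides < 2:
            raise ValueError(f"fewer than 2 TO events for {ev.foot} foot")
        lengths = stride_curve_lengths(ev, tr)
        stride_len = float(lengths.mean()) if lengths.size else 0.0
        per_foot[ev.foot] = single_foot_features(ev, stride_len)
    return GaitFeatures(right=per_foot["right"], left=per_foot["left"])
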