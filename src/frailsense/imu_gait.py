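"""Gait-cycle segmentation and feature extraction from foot-mounted gyroscopes.

The walking signal of interest is the angular velocity about the axis
perpendicular to the direction of progression (sagittal-plane foot rotation).
In that channel a gait cycle shows a stereotyped shape: a large positive lobe
at mid-swing flanked by two negative troughs, the first at toe-off (TO, the
foot leaving the ground) and the second at heel-strike (HS, ground contact).
Cycles are segmented trough-peak-trough and nine temporal/spatial features
per foot are derived, eighteen in total:

======== =============================================== =======
acronym  meaning                                         unit
======== =============================================== =======
GT       total gait time (first to last event)           s
GSTRD    number of strides                               --
GSTRDL   stride length = path length / GSTRD             m
GSTRDT   mean stride time (TO to TO)                     s
GSTRDT_SD SD of stride times                             s
GSWT     mean swing time (TO to HS)                      s
GSWT_SD  SD of swing times                               s
GSTT     mean stance time (HS to next TO)                s
GSTT_SD  SD of stance times                              s
======== =============================================== =======

Acronyms carry an ``R``/``L`` foot suffix (``GTR``, ``GSTRDTR_SD``, ...).
A sternum-mounted gyroscope additionally yields the torso angular excursion
per step (THETAI) by integrating trunk yaw rate between heel-strikes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.signal import butter, filtfilt, find_peaks

__all__ = [
    "GaitEvents",
    "GaitFeatures",
    "ImuSeries",
    "lowpass",
    "detect_events",
    "imu_features",
    "sternum_excursion",
    "GAIT_FEATURE_BASENAMES",
    "gait_feature_names",
]

#: Per-foot feature basenames in their fixed, documented order.
GAIT_FEATURE_BASENAMES = (
    "GT",
    "GSTRD",
    "GSTRDL",
    "GSTRDT",
    "GSTRDT_SD",
    "GSWT",
    "GSWT_SD",
    "GSTT",
    "GSTT_SD",
)

IMU_SENSORS = ("right_foot", "left_foot", "sternum")
IMU_CHANNELS = ("gx", "gy", "gz", "ax", "ay", "az")


def gait_feature_names(foot: str) -> list[str]:
    """Ordered feature names for one foot, e.g. ``GTR``, ``GSTRDTR_SD``."""
    suffix = {"right": "R", "left": "L"}[foot]
    out = []
    for base in GAIT_FEATURE_BASENAMES:
        if base.endswith("_SD"):
            out.append(base[:-3] + suffix + "_SD")
        else:
            out.append(base + suffix)
    return out


@dataclass
class ImuSeries:
    """Synchronised 100 Hz inertial streams for both feet and the sternum.

    ``data`` holds one column per sensor/channel pair named
    ``{sensor}_{channel}`` (gyro in deg/s, accelerometer in m/s^2).
    """

    t: np.ndarray
    data: pd.DataFrame
    fs: float = 100.0

    def channel(self, sensor: str, channel: str) -> np.ndarray:
        return self.data[f"{sensor}_{channel}"].to_numpy()

    def foot_gyro(self, foot: str) -> np.ndarray:
        """Angular rate about the axis perpendicular to progression (deg/s)."""
        return self.channel(f"{foot}_foot", "gy")

    def sternum_yaw_rate(self) -> np.ndarray:
        return self.channel("sternum", "gz")


@dataclass
class GaitEvents:
    """Toe-off / heel-strike instants for one foot, in seconds.

    Within each stride ``to[i] < hs[i] < to[i+1]``; the two event lists are
    therefore equal-length and strictly alternating.
    """

    foot: str
    to: np.ndarray = field(default_factory=lambda: np.empty(0))
    hs: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.to = np.asarray(self.to, dtype=float)
        self.hs = np.asarray(self.hs, dtype=float)
        if self.to.size and self.hs.size:
            merged = np.empty(self.to.size + self.hs.size)
            merged[0::2] = self.to[: merged[0::2].size]
            merged[1::2] = self.hs[: merged[1::2].size]
            if np.any(np.diff(merged) <= 0):
                raise ValueError(f"{self.foot}: TO/HS events do not alternate")

    @property
    def n_strides(self) -> int:
        return int(self.to.size)

    def stride_times(self) -> np.ndarray:
        return np.diff(self.to)

    def swing_times(self) -> np.ndarray:
        n = min(self.to.size, self.hs.size)
        return self.hs[:n] - self.to[:n]

    def stance_times(self) -> np.ndarray:
        if self.to.size < 2:
            return np.empty(0)
        return self.to[1:] - self.hs[: self.to.size - 1]

    def gait_time(self) -> float:
        events = np.concatenate([self.to, self.hs])
        if events.size == 0:
            return 0.0
        return float(events.max() - events.min())


@dataclass(frozen=True)
class GaitFeatures:
    """The 18 named gait features (9 per foot) of one subject."""

    right: pd.Series
    left: pd.Series

    def __post_init__(self) -> None:
        for foot, series in (("right", self.right), ("left", self.left)):
            expected = gait_feature_names(foot)
            if list(series.index) != expected:
                raise ValueError(
                    f"{foot}-foot features must be exactly {expected}, "
                    f"got {list(series.index)}"
                )

    def to_series(self) -> pd.Series:
        return pd.concat([self.right, self.left])


def lowpass(signal: np.ndarray, fs: float, cutoff_hz: float = 5.0, order: int = 4) -> np.ndarray:
    """Zero-phase low-pass Butterworth filter (order 4, 5 Hz by default).

    Applied forward-backward (``filtfilt``) so detected event timestamps are
    not lagged by the filter's group delay; the effective magnitude response
    is the squared one-pass response.
    """
    signal = np.asarray(signal, dtype=float)
    if fs <= 2 * cutoff_hz:
        raise ValueError(f"sampling rate {fs} Hz too low for {cutoff_hz} Hz cutoff")
    b, a = butter(order, cutoff_hz, btype="low", fs=fs)
    padlen = 3 * max(len(a), len(b))
    if signal.size <= padlen:
        raise ValueError(
            f"signal of length {signal.size} too short for order-{order} "
            f"zero-phase filtering (need > {padlen} samples)"
        )
    return filtfilt(b, a, signal)


def detect_events(
    gyro: np.ndarray,
    fs: float,
    *,
    foot: str = "right",
    t0: float = 0.0,
    sign: int = 1,
    prominence_frac: float = 0.3,
    min_peak_separation_s: float = 0.4,
) -> GaitEvents:
    """Segment a filtered foot-gyro signal into toe-off / heel-strike events.

    Mid-swing positive peaks are located first (prominence gated at
    ``prominence_frac`` of the signal inter-quartile range, minimum spacing
    ``min_peak_separation_s``); each peak's TO is the nearest preceding
    negative trough and its HS the nearest following one.  ``sign=-1``
    accommodates the opposite sensor mounting convention.

    Strides lacking either trough are discarded.  Fewer than two detected
    strides emits a warning and returns an empty event set.
    """
    sig = sign * np.asarray(gyro, dtype=float)
    if sig.size == 0 or np.ptp(sig) == 0:
        return GaitEvents(foot=foot)

    # IQR alone collapses to the noise floor when stance dominates the
    # recording, so the gate is also floored at 10% of the signal span.
    # Swing peaks must additionally clear 30% of the signal maximum:
    # baseline bumps between the TO and HS troughs inherit ~trough-depth
    # topographic prominence but stay near zero in height.
    q75, q25 = np.percentile(sig, [75, 25])
    prom = max(prominence_frac * (q75 - q25), 0.1 * np.ptp(sig))
    peaks, _ = find_peaks(
        sig,
        prominence=prom,
        height=0.3 * float(np.max(sig)),
        distance=max(1, int(round(min_peak_separation_s * fs))),
    )
    troughs, _ = find_peaks(-sig, prominence=prom, distance=max(1, int(round(0.1 * fs))))

    to_idx, hs_idx = [], []
    for p in peaks:
        before = troughs[troughs < p]
        after = troughs[troughs > p]
        if before.size == 0 or after.size == 0:
            continue
        to, hs = before[-1], after[0]
        if to_idx and to <= hs_idx[-1]:
            continue  # overlapping cycle (shared trough): keep the earlier
        to_idx.append(to)
        hs_idx.append(hs)

    if len(to_idx) < 2:
        warnings.warn(
            f"{foot} foot: fewer than 2 strides detected; downstream gait "
            "features will be empty",
            stacklevel=2,
        )
        return GaitEvents(foot=foot)
    return GaitEvents(
        foot=foot,
        to=t0 + np.asarray(to_idx, dtype=float) / fs,
        hs=t0 + np.asarray(hs_idx, dtype=float) / fs,
    )


def _sd(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1)) if values.size >= 2 else 0.0


def single_foot_features(
    events: GaitEvents,
    stride_length: float,
) -> pd.Series:
    """Assemble the 9 named features for one foot given its stride length."""
    if events.n_strides == 0:
        raise ValueError(f"no strides detected for {events.foot} foot")
    stride = events.stride_times()
    swing = events.swing_times()
    stance = events.stance_times()
    values = {
        "GT": events.gait_time(),
        "GSTRD": float(events.n_strides),
        "GSTRDL": stride_length,
        "GSTRDT": float(np.mean(stride)) if stride.size else 0.0,
        "GSTRDT_SD": _sd(stride),
        "GSWT": float(np.mean(swing)) if swing.size else 0.0,
        "GSWT_SD": _sd(swing),
        "GSTT": float(np.mean(stance)) if stance.size else 0.0,
        "GSTT_SD": _sd(stance),
    }
    return pd.Series(
        [values[b] for b in GAIT_FEATURE_BASENAMES],
        index=gait_feature_names(events.foot),
        dtype=float,
    )


def imu_features(
    events_right: GaitEvents,
    events_left: GaitEvents,
    path_length: float = 10.0,
) -> GaitFeatures:
    """Compute the 18 gait features from per-foot IMU events.

    Stride length uses the protocol's known walk distance:
    ``GSTRDL = path_length / GSTRD``.
    """
    per_foot = {}
    for ev in (events_right, events_left):
        if ev.n_strides == 0:
            raise ValueError(f"no strides detected for {ev.foot} foot")
        per_foot[ev.foot] = single_foot_features(ev, path_length / ev.n_strides)
    return GaitFeatures(right=per_foot["right"], left=per_foot["left"])


def sternum_excursion(
    sternum_gyro_z: np.ndarray,
    fs: float,
    hs_times: np.ndarray,
    t0: float = 0.0,
) -> tuple[float, float, np.ndarray]:
    """Torso angular excursion per step from the sternum yaw-rate gyro.

    Steps are delimited by the merged heel-strikes of both feet.  The
    gyroscope bias is estimated as the mean over the whole recording
    (left/right sway cancels over full steps) and removed once; each step's
    angular excursion is the peak absolute value of the trapezoidal integral
    of the de-biased rate over that step.

    Returns ``(THETAI, THETAI_SD, per_step_excursions)`` in degrees.
    """
    omega = np.asarray(sternum_gyro_z, dtype=float)
    hs = np.sort(np.asarray(hs_times, dtype=float))
    if hs.size < 2:
        raise ValueError("need at least 2 heel-strike events to delimit steps")
    omega = omega - omega.mean()

    excursions = []
    for a, b in zip(hs[:-1], hs[1:]):
        i = int(round((a - t0) * fs))
        j = int(round((b - t0) * fs)) + 1
        i, j = max(i, 0), min(j, omega.size)
        if j - i < 3:
            continue
        theta = cumulative_trapezoid(omega[i:j], dx=1.0 / fs, initial=0.0)
        excursions.append(float(np.max(np.abs(theta))))
    if not excursions:
        raise ValueError("no usable step intervals within the signal span")
    exc = np.asarray(excursions)
    return float(exc.mean()), _sd(exc), exc
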