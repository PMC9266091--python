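"""Handgrip-strength profiles from the instrumented handle's force sensors.

The handle carries 16 force sensors, 8 under each hand (channels 0-7 right,
8-15 left).  Per hand the channels are summed sample-wise into a total-force
profile, lightly smoothed, and the grip maximum (MFR / MFL, newtons) is the
global peak of that profile — the quantity clinicians compare against a hand
dynamometer when screening for sarcopenia.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ForceSeries", "GripFeatures", "hand_profiles", "max_grip", "grip_features"]

N_CHANNELS = 16
RIGHT_CHANNELS = tuple(range(0, 8))
LEFT_CHANNELS = tuple(range(8, 16))
CHANNEL_NAMES = tuple(f"ch{i:02d}" for i in range(N_CHANNELS))


@dataclass
class ForceSeries:
    """16-channel force time series in newtons (channels 0-7 right hand)."""

    t: np.ndarray
    forces: pd.DataFrame  # columns ch00..ch15

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if list(self.forces.columns) != list(CHANNEL_NAMES):
            raise ValueError(f"force columns must be {CHANNEL_NAMES}")
        if len(self.forces) != self.t.size:
            raise ValueError("timestamp/sample count mismatch")
        if (self.forces.to_numpy() < 0).any():
            raise ValueError("forces must be non-negative")

    @property
    def fs(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t)))


@dataclass(frozen=True)
class GripFeatures:
    """Maximum grip force per hand (newtons)."""

    MFR: float
    MFL: float

    def __post_init__(self) -> None:
        if self.MFR < 0 or self.MFL < 0:
            raise ValueError("grip maxima must be non-negative")

    def to_series(self) -> pd.Series:
        return pd.Series({"MFR": self.MFR, "MFL": self.MFL}, dtype=float)


def hand_profiles(
    series: ForceSeries, smooth_window_s: float = 0.1
) -> tuple[np.ndarray, np.ndarray]:
    """Sum each hand's 8 channels into a total-force profile (right, left).

    A centred moving mean over ``smooth_window_s`` suppresses sensor noise
    before peak search; window ends are averaged over the available samples.
    """
    if series.forces.shape[1] != N_CHANNELS:
        raise ValueError(f"expected {N_CHANNELS} channels")
    arr = series.forces.to_numpy()
    right = arr[:, RIGHT_CHANNELS].sum(axis=1)
    left = arr[:, LEFT_CHANNELS].sum(axis=1)
    win = max(1, int(round(smooth_window_s * series.fs)))
    if win > 1:
        kernel = pd.Series(right)
        right = kernel.rolling(win, center=True, min_periods=1).mean().to_numpy()
        left = pd.Series(left).rolling(win, center=True, min_periods=1).mean().to_numpy()
    return right, left


def max_grip(profile: np.ndarray) -> float:
    """Global maximum of a (smoothed) total-force profile, in newtons."""
    profile = np.asarray(profile, dtype=float)
    if profile.size == 0:
        raise ValueError("empty force profile")
    return float(np.max(profile))


def grip_features(series: ForceSeries) -> GripFeatures:
    """Extract MFR and MFL from a 16-channel recording."""
    right, left = hand_profiles(series)
    return GripFeatures(MFR=max_grip(right), MFL=max_grip(left))
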