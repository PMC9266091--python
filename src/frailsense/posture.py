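"""Upper-body posture features from 2-D pose keypoints plus neck depth.

Only four keypoints of the BODY_25 pose model are used — nose (0), neck (1),
right shoulder (2), left shoulder (5) — together with the neck position in
the depth image.  Thirteen features summarise the walk:

=========  ============================================== ======
name       meaning                                        unit
=========  ============================================== ======
m, m_SD    shoulder-line slope (mean, SD)                 --
THETA,     shoulder inclination (mean of |theta|, SD)     deg
THETA_SD
DIS,       nose-neck Euclidean distance (mean, SD)        px
DIS_SD
NOSE,      nose displacement between frames (mean, SD)    px
NOSE_SD
NECK,      neck displacement between frames (mean, SD)    px
NECK_SD
Zmin       minimum neck depth                             mm
Zmax       maximum neck depth                             mm
ZRMSE      RMS deviation of neck depth about its mean     mm
=========  ============================================== ======

Image coordinates follow the OpenPose convention: origin top-left, y
downward, 0-based pixels.  When several people appear in a frame the main
user is tracked from their initial pose by nearest-pose association.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PersonPose",
    "PoseFrame",
    "PoseFrameSeries",
    "PostureFeatures",
    "select_main_user",
    "shoulder_geometry",
    "nose_neck_distance",
    "displacement",
    "depth_features",
    "posture_features",
    "POSTURE_FEATURE_NAMES",
]

KEYPOINTS = ("nose", "neck", "r_shoulder", "l_shoulder")

#: BODY_25 indices of the keypoints consumed here.
BODY25_INDEX = {"nose": 0, "neck": 1, "r_shoulder": 2, "l_shoulder": 5}

POSTURE_FEATURE_NAMES = (
    "m",
    "m_SD",
    "THETA",
    "THETA_SD",
    "DIS",
    "DIS_SD",
    "NOSE",
    "NOSE_SD",
    "NECK",
    "NECK_SD",
    "Zmin",
    "Zmax",
    "ZRMSE",
)


@dataclass
class PersonPose:
    """One person's keypoints in one frame: name -> (x_px, y_px, confidence)."""

    keypoints: dict[str, tuple[float, float, float]]
    neck_depth_mm: float = float("nan")

    def xy(self, name: str) -> np.ndarray:
        x, y, _ = self.keypoints[name]
        return np.array([x, y], dtype=float)

    def confidence(self, name: str) -> float:
        return float(self.keypoints[name][2])

    def mean_confidence(self) -> float:
        return float(np.mean([self.confidence(k) for k in KEYPOINTS if k in self.keypoints]))

    def mean_distance_to(self, other: "PersonPose") -> float:
        shared = [k for k in KEYPOINTS if k in self.keypoints and k in other.keypoints]
        if not shared:
            return math.inf
        return float(
            np.mean([np.linalg.norm(self.xy(k) - other.xy(k)) for k in shared])
        )


@dataclass
class PoseFrame:
    t: float
    people: list[PersonPose] = field(default_factory=list)


@dataclass
class PoseFrameSeries:
    """Per-frame pose candidates at a nominal camera rate (default 30 fps)."""

    frames: list[PoseFrame]
    fps: float = 30.0

    def __len__(self) -> int:
        return len(self.frames)


def select_main_user(
    series: PoseFrameSeries,
    *,
    confidence_gate: float = 0.3,
    distance_gate_px: float = 150.0,
) -> PoseFrameSeries:
    """Track the main user across frames from their initial pose.

    In every frame the person whose keypoints are nearest (mean pixel
    distance) to the previously accepted pose is kept; frames whose best
    candidate exceeds ``distance_gate_px`` or whose mean keypoint confidence
    falls below ``confidence_gate`` are dropped.
    """
    if not series.frames:
        raise ValueError("empty pose series")
    first_people = series.frames[0].people
    if not first_people:
        raise ValueError("first frame contains no person")
    reference = max(first_people, key=lambda p: p.mean_confidence())

    kept: list[PoseFrame] = []
    for frame in series.frames:
        if not frame.people:
            continue
        best = min(frame.people, key=lambda p: p.mean_distance_to(reference))
        if best.mean_distance_to(reference) > distance_gate_px:
            continue
        if best.mean_confidence() < confidence_gate:
            continue
        reference = best
        kept.append(PoseFrame(t=frame.t, people=[best]))
    return PoseFrameSeries(frames=kept, fps=series.fps)


def shoulder_geometry(person: PersonPose) -> tuple[float, float]:
    """Slope ``m`` and inclination ``theta`` (degrees) of the shoulder line.

    ``m = dy/dx`` between the two shoulders; ``theta`` is the line's angle to
    the image horizontal, folded into (-90, 90].  A vertical shoulder line
    gives ``theta = 90`` and an infinite (flagged) slope.
    """
    for k in ("l_shoulder", "r_shoulder"):
        if k not in person.keypoints:
            raise ValueError(f"missing keypoint {k}")
    dx, dy = person.xy("l_shoulder") - person.xy("r_shoulder")
    theta = math.degrees(math.atan2(dy, dx))
    if theta > 90:
        theta -= 180
    elif theta <= -90:
        theta += 180
    m = math.inf if dx == 0 else dy / dx
    return m, theta


def nose_neck_distance(person: PersonPose) -> float:
    """Euclidean nose-neck distance in pixels."""
    for k in ("nose", "neck"):
        if k not in person.keypoints:
            raise ValueError(f"missing keypoint {k}")
    return float(np.linalg.norm(person.xy("nose") - person.xy("neck")))


def displacement(series: PoseFrameSeries, keypoint: str) -> np.ndarray:
    """Per-frame pixel displacement of one keypoint between consecutive frames.

    N retained frames yield N-1 values.
    """
    pts = [
        f.people[0].xy(keypoint)
        for f in series.frames
        if f.people and keypoint in f.people[0].keypoints
    ]
    if len(pts) < 2:
        raise ValueError(f"need at least 2 frames with keypoint {keypoint!r}")
    pts_arr = np.asarray(pts)
    return np.linalg.norm(np.diff(pts_arr, axis=0), axis=1)


def depth_features(depth_mm: np.ndarray) -> tuple[float, float, float]:
    """(Zmin, Zmax, ZRMSE) of the neck depth series in millimetres.

    ZRMSE is the root-mean-square deviation about the series mean — the mean
    oscillation of the torso in the depth domain.
    """
    z = np.asarray(depth_mm, dtype=float)
    z = z[np.isfinite(z)]
    if z.size == 0:
        raise ValueError("depth series has no finite values")
    zrmse = float(np.sqrt(np.mean((z - z.mean()) ** 2)))
    return float(z.min()), float(z.max()), zrmse


@dataclass(frozen=True)
class PostureFeatures:
    """The 13 named camera posture features of one subject."""

    values: pd.Series

    def __post_init__(self) -> None:
        if list(self.values.index) != list(POSTURE_FEATURE_NAMES):
            raise ValueError(
                f"posture features must be exactly {POSTURE_FEATURE_NAMES}"
            )
        if self.values["Zmin"] > self.values["Zmax"]:
            raise ValueError("Zmin exceeds Zmax")

    def to_series(self) -> pd.Series:
        return self.values.copy()


def posture_features(
    series: PoseFrameSeries,
    *,
    confidence_gate: float = 0.3,
    theta_absolute: bool = True,
    already_selected: bool = False,
) -> PostureFeatures:
    """Aggregate the 13 posture features over a walk's retained frames.

    THETA is by default the mean of per-frame ``|theta|`` (the inclination
    magnitude irrespective of lean side); set ``theta_absolute=False`` for a
    signed mean.
    """
    sel = series if already_selected else select_main_user(series, confidence_gate=confidence_gate)
    if len(sel.frames) < 2:
        raise ValueError("fewer than 2 retained frames")

    m_vals, theta_vals, dis_vals, depth_vals = [], [], [], []
    for frame in sel.frames:
        person = frame.people[0]
        m, theta = shoulder_geometry(person)
        if math.isfinite(m):
            m_vals.append(m)
        theta_vals.append(abs(theta) if theta_absolute else theta)
        dis_vals.append(nose_neck_distance(person))
        depth_vals.append(person.neck_depth_mm)

    nose_d = displacement(sel, "nose")
    neck_d = displacement(sel, "neck")
    zmin, zmax, zrmse = depth_features(np.asarray(depth_vals))

    def sd(v):
        v = np.asarray(v)
        return float(np.std(v, ddof=1)) if v.size >= 2 else 0.0

    values = pd.Series(
        [
            float(np.mean(m_vals)) if m_vals else float("nan"),
            sd(m_vals),
            float(np.mean(theta_vals)),
            sd(theta_vals),
            float(np.mean(dis_vals)),
            sd(dis_vals),
            float(np.mean(nose_d)),
            sd(nose_d),
            float(np.mean(neck_d)),
            sd(neck_d),
            zmin,
            zmax,
            zrmse,
        ],
        index=list(POSTURE_FEATURE_NAMES),
        dtype=float,
    )
    return PostureFeatures(values=values)
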