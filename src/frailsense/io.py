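"""Readers and writers for the four sensor-stream formats and feature tables.

All files are UTF-8 text with '.' decimal and mandatory headers:

* laser CSV   — ``timestamp`` (ISO 8601, ns resolution) + ``r0000..r0666``
  range columns in mm, blank cells for no-return beams;
* IMU CSV     — ``timestamp`` (float seconds from start) + one
  ``{sensor}_{channel}`` column per sensor (right_foot, left_foot, sternum)
  and channel (gx..az);
* pose JSON   — ``{"fps": .., "frames": [{"t": .., "people": [..]}]}`` with
  each person's keypoints keyed by BODY_25 index (0 nose, 1 neck,
  2 right shoulder, 5 left shoulder) as ``[x, y, confidence]`` plus
  ``neck_depth_mm``;
* force CSV   — ``timestamp`` (s) + ``ch00..ch15`` in newtons;
* feature CSV — one row per subject, columns named exactly by the feature
  acronyms.

Reads validate column sets and strictly-increasing timestamps and report
offending rows with line numbers; write-then-read round-trips reproduce all
values to 1e-9.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .grip import CHANNEL_NAMES, ForceSeries
from .imu_gait import IMU_CHANNELS, IMU_SENSORS, ImuSeries
from .laser_gait import N_BEAMS, LaserScanSeries
from .posture import BODY25_INDEX, PersonPose, PoseFrame, PoseFrameSeries

__all__ = [
    "write_laser_csv", "read_laser_csv",
    "write_imu_csv", "read_imu_csv",
    "write_pose_json", "read_pose_json",
    "write_force_csv", "read_force_csv",
    "write_feature_table", "read_feature_table",
]

_EPOCH = pd.Timestamp("2000-01-01T00:00:00")
_RANGE_COLS = [f"r{i:04d}" for i in range(N_BEAMS)]
_IMU_COLS = [f"{s}_{c}" for s in IMU_SENSORS for c in IMU_CHANNELS]
_INDEX_TO_KEYPOINT = {str(v): k for k, v in BODY25_INDEX.items()}


def _check_timestamps(t: np.ndarray, path: Path) -> None:
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        # +2: one for the header line, one for 1-based numbering
        raise ValueError(
            f"{path}: non-monotone timestamp at line {int(bad[0]) + 3}"
        )


def _check_columns(df: pd.DataFrame, required: list[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


def _read_csv(path: Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except pd.errors.ParserError as exc:  # pragma: no cover - message passthrough
        raise ValueError(f"{path}: malformed CSV ({exc})") from exc


def write_laser_csv(series: LaserScanSeries, path: str | Path) -> Path:
    path = Path(path)
    stamps = _EPOCH + pd.to_timedelta(np.round(series.t * 1e9).astype("int64"), unit="ns")
    df = pd.DataFrame(series.ranges_mm, columns=_RANGE_COLS)
    df.insert(0, "timestamp", stamps.strftime("%Y-%m-%dT%H:%M:%S.%f") + (
        pd.Series(stamps.nanosecond).astype(str).str.zfill(3).values
    ))
    df.to_csv(path, index=False)
    return path


def read_laser_csv(path: str | Path) -> LaserScanSeries:
    path = Path(path)
    df = _read_csv(path)
    _check_columns(df, ["timestamp"] + _RANGE_COLS, path)
    stamps = pd.to_datetime(df["timestamp"], format="ISO8601")
    t = (stamps - stamps.iloc[0]).dt.total_seconds().to_numpy() + (
        (stamps.iloc[0] - _EPOCH).total_seconds()
    )
    _check_timestamps(t, path)
    ranges = df[_RANGE_COLS].to_numpy(dtype=float)
    return LaserScanSeries(t=t, ranges_mm=ranges)


def _write_timeseries_csv(t: np.ndarray, data: pd.DataFrame, path: Path) -> Path:
    out = data.copy()
    out.insert(0, "timestamp", t)
    out.to_csv(path, index=False)
    return path


def _read_timeseries_csv(path: Path, cols: list[str]) -> tuple[np.ndarray, pd.DataFrame]:
    df = _read_csv(path)
    _check_columns(df, ["timestamp"] + cols, path)
    numeric = df[["timestamp"] + cols].apply(pd.to_numeric, errors="coerce")
    bad_rows = numeric.index[numeric.isna().any(axis=1)]
    if len(bad_rows):
        raise ValueError(
            f"{path}: non-numeric values at line(s) {[int(i) + 2 for i in bad_rows[:5]]}"
        )
    t = numeric["timestamp"].to_numpy(dtype=float)
    _check_timestamps(t, path)
    return t, numeric[cols]


def write_imu_csv(series: ImuSeries, path: str | Path) -> Path:
    return _write_timeseries_csv(series.t, series.data[_IMU_COLS], Path(path))


def read_imu_csv(path: str | Path) -> ImuSeries:
    path = Path(path)
    t, data = _read_timeseries_csv(path, _IMU_COLS)
    fs = 1.0 / float(np.median(np.diff(t)))
    return ImuSeries(t=t, data=data.reset_index(drop=True), fs=fs)


def write_force_csv(series: ForceSeries, path: str | Path) -> Path:
    return _write_timeseries_csv(series.t, series.forces[list(CHANNEL_NAMES)], Path(path))


def read_force_csv(path: str | Path) -> ForceSeries:
    path = Path(path)
    t, data = _read_timeseries_csv(path, list(CHANNEL_NAMES))
    return ForceSeries(t=t, forces=data.reset_index(drop=True))


def write_pose_json(series: PoseFrameSeries, path: str | Path) -> Path:
    path = Path(path)
    frames = []
    for frame in series.frames:
        people = []
        for person in frame.people:
            entry = {
                "keypoints": {
                    str(BODY25_INDEX[name]): [float(v) for v in kp]
                    for name, kp in person.keypoints.items()
                },
            }
            if np.isfinite(person.neck_depth_mm):
                entry["neck_depth_mm"] = float(person.neck_depth_mm)
            people.append(entry)
        frames.append({"t": float(frame.t), "people": people})
    path.write_text(json.dumps({"fps": series.fps, "frames": frames}))
    return path


def read_pose_json(path: str | Path) -> PoseFrameSeries:
    path = Path(path)
    doc = json.loads(path.read_text())
    for key in ("fps", "frames"):
        if key not in doc:
            raise ValueError(f"{path}: missing top-level key {key!r}")
    frames = []
    last_t = -np.inf
    for i, fr in enumerate(doc["frames"]):
        if "t" not in fr:
            raise ValueError(f"{path}: frame {i} lacks a timestamp")
        t = float(fr["t"])
        if t <= last_t:
            raise ValueError(f"{path}: non-monotone timestamp at frame {i}")
        last_t = t
        people = []
        for entry in fr.get("people", []):
            kps = {}
            for idx, xyc in entry.get("keypoints", {}).items():
                name = _INDEX_TO_KEYPOINT.get(str(idx))
                if name is None:
                    continue
                kps[name] = (float(xyc[0]), float(xyc[1]), float(xyc[2]))
            people.append(
                PersonPose(
                    keypoints=kps,
                    neck_depth_mm=float(entry.get("neck_depth_mm", float("nan"))),
                )
            )
        frames.append(PoseFrame(t=t, people=people))
    return PoseFrameSeries(frames=frames, fps=float(doc["fps"]))


def write_feature_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, index=True, index_label="subject_id")
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = _read_csv(path)
    if "subject_id" not in df.columns:
        raise ValueError(f"{path}: missing subject_id column")
    return df.set_index("subject_id")
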