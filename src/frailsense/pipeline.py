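"""End-to-end orchestration: simulate/ingest -> extract -> compare -> profile.

The pipeline mirrors the robot's processing order: the sensing stage turns
raw streams into per-modality features (18 gait features per route, 13
posture features, 2 grip maxima — 33 robot-side parameters per subject),
the comparison stage cross-validates the contactless route against the
wearable reference, and the perception stage fuses 24 features per subject
and embeds the cohort in 2-D for the decision-support display.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .config import RunConfig
from .grip import ForceSeries, GripFeatures, grip_features
from .imu_gait import (
    GaitEvents,
    GaitFeatures,
    ImuSeries,
    detect_events,
    imu_features,
    lowpass,
    sternum_excursion,
)
from .laser_gait import LaserScanSeries, extract_leg_tracks, laser_features, segment_track
from .posture import PoseFrameSeries, PostureFeatures, posture_features, select_main_user
from .profiling import (
    Embedding2D,
    SubjectProfile,
    build_profile_matrix,
    profile_report,
    sammon_embed,
    tsne_embed,
)
from .synth import (
    GaitGroundTruth,
    render_force,
    render_imu,
    render_laser,
    render_pose,
    sample_cohort,
    simulate_gait,
)
from .validation import compare_modalities

__all__ = [
    "extract_imu_gait",
    "extract_laser_gait",
    "extract_sternum_sway",
    "SubjectRecord",
    "simulate_subject",
    "extract_subject",
    "PipelineResult",
    "run_pipeline",
]

log = logging.getLogger("frailsense")


def extract_imu_gait(
    imu: ImuSeries, config: RunConfig | None = None
) -> tuple[GaitFeatures, GaitEvents, GaitEvents]:
    """Filter both foot gyros, segment events, and compute the 18 features."""
    cfg = config or RunConfig()
    events = {}
    for foot in ("right", "left"):
        sig = lowpass(imu.foot_gyro(foot), imu.fs, cutoff_hz=cfg.filter_cutoff_hz)
        events[foot] = detect_events(
            sig,
            imu.fs,
            foot=foot,
            t0=float(imu.t[0]),
            prominence_frac=cfg.peak_prominence_frac,
            min_peak_separation_s=cfg.min_peak_separation_s,
        )
    feats = imu_features(events["right"], events["left"], path_length=cfg.path_length_m)
    return feats, events["right"], events["left"]


def extract_laser_gait(
    scans: LaserScanSeries, config: RunConfig | None = None
) -> tuple[GaitFeatures, GaitEvents, GaitEvents]:
    """Track the legs in the scans, segment events, and compute the features."""
    cfg = config or RunConfig()
    track_r, track_l = extract_leg_tracks(
        scans,
        x_window=cfg.leg_window_x_m,
        y_halfwidth=cfg.leg_window_halfwidth_m,
        cluster_gap_m=cfg.cluster_gap_m,
    )
    ev_r = segment_track(track_r, prominence_frac=cfg.laser_prominence_frac)
    ev_l = segment_track(track_l, prominence_frac=cfg.laser_prominence_frac)
    feats = laser_features(ev_r, ev_l, track_r, track_l)
    return feats, ev_r, ev_l


def extract_sternum_sway(
    imu: ImuSeries,
    events_right: GaitEvents,
    events_left: GaitEvents,
    config: RunConfig | None = None,
) -> tuple[float, float]:
    """THETAI / THETAI_SD from the sternum gyro, steps delimited by HS events."""
    cfg = config or RunConfig()
    sig = lowpass(imu.sternum_yaw_rate(), imu.fs, cutoff_hz=cfg.filter_cutoff_hz)
    hs = np.sort(np.concatenate([events_right.hs, events_left.hs]))
    thetai, thetai_sd, _ = sternum_excursion(sig, imu.fs, hs, t0=float(imu.t[0]))
    return thetai, thetai_sd


@dataclass
class SubjectRecord:
    """One subject's raw synthetic streams plus the planted truth."""

    subject_id: str
    truth: GaitGroundTruth
    laser: LaserScanSeries
    imu: ImuSeries
    pose: PoseFrameSeries
    force: ForceSeries


@dataclass
class SubjectFeatures:
    subject_id: str
    group: str
    imu_gait: GaitFeatures
    laser_gait: GaitFeatures
    posture: PostureFeatures
    grip: GripFeatures
    thetai: float
    thetai_sd: float


def simulate_subject(truth: GaitGroundTruth, subject_id: str = "s00") -> SubjectRecord:
    """Render all four streams for one planted ground truth."""
    schedule = simulate_gait(truth)
    return SubjectRecord(
        subject_id=subject_id,
        truth=truth,
        laser=render_laser(schedule, truth),
        imu=render_imu(schedule, truth),
        pose=render_pose(schedule, truth),
        force=render_force(truth),
    )


def extract_subject(
    record: SubjectRecord, config: RunConfig | None = None
) -> SubjectFeatures:
    """Run every per-subject extractor on one record."""
    cfg = config or RunConfig()
    imu_feats, ev_r, ev_l = extract_imu_gait(record.imu, cfg)
    laser_feats, _, _ = extract_laser_gait(record.laser, cfg)
    selected = select_main_user(record.pose, confidence_gate=cfg.confidence_gate)
    post = posture_features(selected, already_selected=True)
    grip = grip_features(record.force)
    thetai, thetai_sd = extract_sternum_sway(record.imu, ev_r, ev_l, cfg)
    return SubjectFeatures(
        subject_id=record.subject_id,
        group="walker" if record.truth.walker_user else "walks-alone",
        imu_gait=imu_feats,
        laser_gait=laser_feats,
        posture=post,
        grip=grip,
        thetai=thetai,
        thetai_sd=thetai_sd,
    )


@dataclass
class PipelineResult:
    imu_table: pd.DataFrame  # 18 gait + THETAI/THETAI_SD per subject
    robot_table: pd.DataFrame  # 33 robot-side features per subject
    comparison: pd.DataFrame
    profile_matrix: pd.DataFrame
    embeddings: list[Embedding2D]
    groups: list[str] = field(default_factory=list)
    outputs: dict[str, Path] = field(default_factory=dict)


def _feature_tables(features: list[SubjectFeatures]) -> tuple[pd.DataFrame, pd.DataFrame]:
    imu_rows, robot_rows = {}, {}
    for f in features:
        imu_rows[f.subject_id] = pd.concat(
            [f.imu_gait.to_series(), pd.Series({"THETAI": f.thetai, "THETAI_SD": f.thetai_sd})]
        )
        robot_rows[f.subject_id] = pd.concat(
            [f.laser_gait.to_series(), f.posture.to_series(), f.grip.to_series()]
        )
    return (
        pd.DataFrame(imu_rows).T.rename_axis("subject_id"),
        pd.DataFrame(robot_rows).T.rename_axis("subject_id"),
    )


def run_pipeline(
    config: RunConfig | None = None,
    seed: int = 42,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Execute the full desk-scale study on a synthetic cohort.

    Simulates ``config.n_subjects`` subjects (``config.n_walker`` of them
    walker-dependent), extracts all modality features, compares the gait
    routes statistically, fuses the 24-feature profiles, and embeds the
    cohort with exact t-SNE and the Sammon mapping.  With ``outdir`` set,
    feature tables, the comparison report, embedding coordinates and figures
    are written there.
    """
    cfg = config or RunConfig()
    cfg.validate()
    cohort = sample_cohort(cfg.n_subjects, cfg.n_walker, seed=seed)

    features: list[SubjectFeatures] = []
    records: list[SubjectRecord] = []
    for i, truth in enumerate(cohort):
        sid = f"s{i:02d}"
        log.info("subject %s: simulating (seed=%d, strides=%d)", sid, truth.seed, truth.n_strides)
        record = simulate_subject(truth, sid)
        records.append(record)
        try:
            feats = extract_subject(record, cfg)
        except Exception as exc:
            raise RuntimeError(f"extraction failed for subject {sid}: {exc}") from exc
        log.info(
            "subject %s: GSTRD imu=%d laser=%d, MFR=%.1f N",
            sid,
            int(feats.imu_gait.right["GSTRDR"]),
            int(feats.laser_gait.right["GSTRDR"]),
            feats.grip.MFR,
        )
        features.append(feats)

    imu_table, robot_table = _feature_tables(features)
    gait_cols = features[0].imu_gait.to_series().index.tolist()
    comparison = compare_modalities(imu_table[gait_cols], robot_table[gait_cols])

    profiles = [
        SubjectProfile(
            subject_id=f.subject_id,
            gait=f.laser_gait,
            posture=f.posture,
            grip=f.grip,
            group=f.group,
        )
        for f in features
    ]
    groups = [p.group for p in profiles]
    matrix = build_profile_matrix(profiles)
    embeddings = [
        tsne_embed(matrix, perplexity=cfg.perplexity, seed=seed),
        sammon_embed(matrix, max_iter=cfg.sammon_max_iter),
    ]
    log.info("Sammon stress: %.3f%%", embeddings[1].stress_percent)

    outputs: dict[str, Path] = {}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        outputs["imu_features"] = fio.write_feature_table(imu_table, outdir / "imu_features.csv")
        outputs["robot_features"] = fio.write_feature_table(
            robot_table, outdir / "robot_features.csv"
        )
        comparison.to_csv(outdir / "comparison.csv")
        outputs["comparison"] = outdir / "comparison.csv"
        outputs.update(profile_report(embeddings, groups, outdir))
        if cfg.write_streams:
            streams = outdir / "streams"
            streams.mkdir(exist_ok=True)
            for rec in records:
                fio.write_laser_csv(rec.laser, streams / f"{rec.subject_id}_laser.csv")
                fio.write_imu_csv(rec.imu, streams / f"{rec.subject_id}_imu.csv")
                fio.write_pose_json(rec.pose, streams / f"{rec.subject_id}_pose.json")
                fio.write_force_csv(rec.force, streams / f"{rec.subject_id}_force.csv")

    return PipelineResult(
        imu_table=imu_table,
        robot_table=robot_table,
        comparison=comparison,
        profile_matrix=matrix,
        embeddings=embeddings,
        groups=groups,
        outputs=outputs,
    )
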