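"""Run configuration: validated parameters for the end-to-end pipeline."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All tunable parameters of a pipeline run.

    Defaults reproduce the standard desk-scale study: a 10-subject synthetic
    cohort (2 walker-dependent) walking 10 m, 5 Hz zero-phase filtering of
    the inertial streams, and a perplexity-3 exact t-SNE next to the Sammon
    mapping.
    """

    # cohort / simulation
    n_subjects: int = 10
    n_walker: int = 2
    path_length_m: float = 10.0
    # filtering and event detection
    filter_cutoff_hz: float = 5.0
    peak_prominence_frac: float = 0.3
    min_peak_separation_s: float = 0.4
    laser_prominence_frac: float = 0.25
    # laser leg window
    leg_window_x_m: tuple[float, float] = (0.2, 1.5)
    leg_window_halfwidth_m: float = 0.5
    cluster_gap_m: float = 0.15
    # posture
    confidence_gate: float = 0.3
    # embedding
    perplexity: float = 3.0
    sammon_max_iter: int = 500
    # stream file paths for ingest mode (None -> simulate)
    laser_path: str | None = None
    imu_path: str | None = None
    pose_path: str | None = None
    force_path: str | None = None
    write_streams: bool = False

    def validate(self) -> None:
        positive = {
            "n_subjects": self.n_subjects,
            "path_length_m": self.path_length_m,
            "filter_cutoff_hz": self.filter_cutoff_hz,
            "peak_prominence_frac": self.peak_prominence_frac,
            "min_peak_separation_s": self.min_peak_separation_s,
            "laser_prominence_frac": self.laser_prominence_frac,
            "cluster_gap_m": self.cluster_gap_m,
            "leg_window_halfwidth_m": self.leg_window_halfwidth_m,
            "confidence_gate": self.confidence_gate,
            "perplexity": self.perplexity,
            "sammon_max_iter": self.sammon_max_iter,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.n_walker < 0 or self.n_walker > self.n_subjects:
            raise ValueError("n_walker must lie in [0, n_subjects]")
        lo, hi = self.leg_window_x_m
        if not 0 <= lo < hi:
            raise ValueError("leg_window_x_m must satisfy 0 <= lo < hi")
        if self.perplexity >= self.n_subjects:
            raise ValueError("perplexity must be < n_subjects")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(doc) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "leg_window_x_m" in doc:
            doc["leg_window_x_m"] = tuple(doc["leg_window_x_m"])
        cfg = cls(**doc)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        doc = asdict(self)
        doc["leg_window_x_m"] = list(self.leg_window_x_m)
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
        return path
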