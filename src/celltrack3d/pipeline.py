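"""End-to-end orchestration: contrast boost, correlation, tracking, features.

`run_pipeline` drives the full flow over a volume sequence with a single
config object whose defaults are the standard acquisition/tracking setup
(0.78/0.78/8 µm voxels, 4-minute frames, 20x20x10 detection neighborhood,
softThresh 5, noiseThresh 120, 7-voxel flat kernel, 0.01-voxel stop, 10/5
boundary margins, 5-frame parasite lifetime, 45-frame feature filter).
`run_benchmark` simulates a ground-truthed scene, runs the pipeline on it
and scores the trajectories against the truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .analysis import compute_features, features_table
from .correlation import CellTemplate, correlate_volume, extract_template
from .detection import DetectionParams
from .lifecycle import TrackingSession
from .tracking import MeanShiftParams
from .volume_io import (
    DEFAULT_FRAME_INTERVAL,
    DEFAULT_SPACING,
    VolumeSequence,
    enhance_contrast,
    write_stack,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "run_benchmark"]


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with its standard default."""

    spacing: tuple = DEFAULT_SPACING  # µm per voxel (dx, dy, dz)
    frame_interval: float = DEFAULT_FRAME_INTERVAL  # minutes
    contrast_percentiles: tuple = (0.01, 0.99)
    enhance: bool = True
    neighborhood: tuple = (20, 20, 10)  # soft-max window extents (nx, ny, nz)
    soft_thresh: float = 5.0
    noise_thresh: float = 120.0
    kernel_size: int = 7
    tolerance: float = 0.01
    max_iterations: int = 100
    boundary_margins: tuple = (10.0, 5.0)  # (xy voxels, z slices)
    collision_distance: tuple = (3.5, 2.0)
    parasite_max_life: int = 5
    min_frames: int = 45
    cache_correlated: bool = False
    seed: int = 0

    def detection_params(self) -> DetectionParams:
        return DetectionParams(
            neighborhood=tuple(self.neighborhood),
            soft_thresh=self.soft_thresh,
            noise_thresh=self.noise_thresh,
        )

    def mean_shift_params(self) -> MeanShiftParams:
        return MeanShiftParams(
            kernel_size=self.kernel_size,
            tolerance=self.tolerance,
            max_iterations=self.max_iterations,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for k, v in d.items():
            kwargs[k] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)


@dataclass
class PipelineResult:
    trajectories: list
    features: list
    events: list
    session: TrackingSession
    config: PipelineConfig

    def trajectory_table(self) -> pd.DataFrame:
        dx, dy, dz = self.config.spacing
        rows = []
        for traj in self.trajectories:
            for f, (x, y, z) in traj.points:
                rows.append(
                    {
                        "tracker_id": traj.tracker_id,
                        "frame_index": f,
                        "x_voxel": x,
                        "y_voxel": y,
                        "z_voxel": z,
                        "x_um": x * dx,
                        "y_um": y * dy,
                        "z_um": z * dz,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "tracker_id", "frame_index", "x_voxel", "y_voxel", "z_voxel",
                "x_um", "y_um", "z_um",
            ],
        )

    def metadata_table(self) -> pd.DataFrame:
        rows = [
            {
                "tracker_id": t.tracker_id,
                "birth_frame": t.birth_frame,
                "last_frame": t.last_frame,
                "n_frames": t.n_frames,
                "end_reason": t.end_reason,
            }
            for t in self.trajectories
        ]
        return pd.DataFrame(
            rows, columns=["tracker_id", "birth_frame", "last_frame", "n_frames", "end_reason"]
        )

    def features_table(self) -> pd.DataFrame:
        return features_table(self.features)

    def write(self, out_dir) -> dict:
        """Write trajectories, metadata, features CSVs and the event log."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "trajectories": out_dir / "trajectories.csv",
            "metadata": out_dir / "trajectory_metadata.csv",
            "features": out_dir / "features.csv",
            "events": out_dir / "events.jsonl",
            "report": out_dir / "run_report.json",
        }
        self.trajectory_table().to_csv(paths["trajectories"], index=False, float_format="%.6f")
        self.metadata_table().to_csv(paths["metadata"], index=False)
        self.features_table().to_csv(paths["features"], index=False, float_format="%.6f")
        with open(paths["events"], "w") as fh:
            for event in self.events:
                fh.write(json.dumps(event, sort_keys=True) + "\n")
        report = {
            "config": self.config.to_dict(),
            "n_trajectories": len(self.trajectories),
            "n_features": len(self.features),
            "end_reasons": self.metadata_table()["end_reason"].value_counts().to_dict(),
        }
        with open(paths["report"], "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        return {k: str(v) for k, v in paths.items()}


def run_pipeline(
    sequence: VolumeSequence,
    template: CellTemplate,
    config: PipelineConfig | None = None,
    out_dir=None,
    cache_dir=None,
) -> PipelineResult:
    """Run contrast boost -> correlation -> tracking loop -> features.

    Deterministic given the sequence, template and config.  If ``out_dir``
    is given the CSV/JSONL artifacts are written there; ``cache_dir``
    stores the correlated volumes as TIFF stacks when
    ``config.cache_correlated`` is set.
    """
    config = config or PipelineConfig()
    session = TrackingSession(
        detection_params=config.detection_params(),
        mean_shift_params=config.mean_shift_params(),
        boundary_margins=tuple(config.boundary_margins),
        collision_distance=tuple(config.collision_distance),
        parasite_max_life=config.parasite_max_life,
    )
    lo, hi = config.contrast_percentiles
    for volume in sequence:
        if config.enhance:
            volume = enhance_contrast(volume, lo, hi)
        corr = correlate_volume(volume, template)
        if config.cache_correlated and cache_dir is not None:
            path = Path(cache_dir) / f"frame_{corr.frame_index:04d}_corr.tif"
            write_stack(
                dataclasses.replace(corr, data=np.clip(np.rint(corr.data), 0, 255).astype(np.uint8)),
                path,
            )
        session.advance_frame(corr)
    trajectories = session.finalize()
    features = compute_features(
        trajectories,
        spacing=config.spacing,
        frame_interval=config.frame_interval,
        min_frames=config.min_frames,
    )
    result = PipelineResult(
        trajectories=trajectories,
        features=features,
        events=session.events,
        session=session,
        config=config,
    )
    if out_dir is not None:
        result.write(out_dir)
    return result


def run_benchmark(
    seed: int = 0,
    config: PipelineConfig | None = None,
    scene=None,
    model=None,
    match_dist=(5.0, 2.0),
    out_dir=None,
) -> dict:
    """Simulate, render, track and score the default synthetic benchmark.

    Returns the ground-truth metrics (recall, precision, id-switch
    fraction) together with trajectory counts.
    """
    config = config or PipelineConfig(seed=seed)
    scene = scene if scene is not None else synthetic.default_benchmark_scene(seed)
    model = model or synthetic.SyntheticCellModel()
    sequence = synthetic.render_sequence(scene, model)
    template = synthetic.make_template(model)
    result = run_pipeline(sequence, template, config, out_dir=out_dir)
    metrics = synthetic.score_against_truth(result.trajectories, scene, match_dist)
    metrics["n_features"] = len(result.features)
    if out_dir is not None:
        with open(Path(out_dir) / "benchmark_metrics.json", "w") as fh:
            json.dump(metrics, fh, indent=2, sort_keys=True)
    return metrics
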