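"""Duration-normalized migration descriptors and condition comparison.

Trajectories of different lengths are made comparable by normalizing
distances by follow-up duration: the average speed (path length / duration,
µm/h) and the MRDO rate (maximum relative distance covered from the
trajectory origin / duration, µm/h).  Short follow-ups yield noisy,
outlier-prone values of such rates, so trajectories shorter than a minimum
number of frames (45 frames = 3 h at a 4-minute interval) are filtered out
before statistics.  Feature distributions of cell populations under
different experimental conditions are compared with the rank-based
Kruskal-Wallis k-sample test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .lifecycle import Trajectory
from .volume_io import DEFAULT_FRAME_INTERVAL, DEFAULT_SPACING

__all__ = [
    "TrajectoryFeatures",
    "ConditionSummary",
    "to_physical",
    "average_speed",
    "mrdo",
    "max_displacement",
    "filter_min_duration",
    "compute_features",
    "features_table",
    "compare_conditions",
]


@dataclass
class TrajectoryFeatures:
    tracker_id: int
    duration_h: float
    avg_speed: float  # µm/h
    mrdo_rate: float  # µm/h
    max_displacement_um: float

    def __post_init__(self) -> None:
        if self.duration_h <= 0:
            raise ValueError("duration must be positive")
        # path length is at least the largest displacement from the origin
        if self.avg_speed < 0 or self.mrdo_rate < 0:
            raise ValueError("features must be nonnegative")


@dataclass
class ConditionSummary:
    """Feature values of one cell population (one experimental condition)."""

    condition_name: str
    features: list[TrajectoryFeatures] = field(default_factory=list)

    @property
    def n_trajectories(self) -> int:
        return len(self.features)

    def values(self, feature_name: str) -> np.ndarray:
        return np.array([getattr(f, feature_name) for f in self.features], dtype=float)


def to_physical(trajectory: Trajectory, spacing=DEFAULT_SPACING, frame_interval=DEFAULT_FRAME_INTERVAL):
    """Convert a voxel trajectory to physical units.

    Returns ``(times_h, positions_um)`` where positions are an (n, 3) array
    of (x, y, z) in µm (per-axis voxel spacing applied) and times are hours
    (``frame_index * frame_interval / 60``).
    """
    if not trajectory.points:
        raise ValueError("trajectory is empty")
    frames = np.array([p[0] for p in trajectory.points], dtype=float)
    pos = np.array([p[1] for p in trajectory.points], dtype=float)
    times_h = frames * frame_interval / 60.0
    positions_um = pos * np.asarray(spacing, dtype=float)
    return times_h, positions_um


def _check_physical(times_h, positions_um):
    times_h = np.asarray(times_h, dtype=float)
    positions_um = np.asarray(positions_um, dtype=float)
    if len(times_h) < 2:
        raise ValueError("need at least two points for duration-normalized features")
    duration = times_h[-1] - times_h[0]
    if duration <= 0:
        raise ValueError("trajectory duration must be positive")
    return times_h, positions_um, duration


def average_speed(times_h, positions_um) -> float:
    """Path length divided by follow-up duration, in µm/h."""
    _, pos, duration = _check_physical(times_h, positions_um)
    steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    return float(steps.sum() / duration)


def mrdo(times_h, positions_um) -> float:
    """Maximum relative distance covered from the origin per hour (µm/h)."""
    _, pos, duration = _check_physical(times_h, positions_um)
    return float(np.linalg.norm(pos - pos[0], axis=1).max() / duration)


def max_displacement(times_h, positions_um) -> float:
    """Unnormalized maximum distance from the trajectory origin, in µm."""
    _, pos, _ = _check_physical(times_h, positions_um)
    return float(np.linalg.norm(pos - pos[0], axis=1).max())


def filter_min_duration(trajectories, min_frames: int = 45):
    """Keep only trajectories with at least ``min_frames`` recorded frames."""
    if min_frames < 2:
        raise ValueError("min_frames must be >= 2")
    return [t for t in trajectories if t.n_frames >= min_frames]


def compute_features(
    trajectories,
    spacing=DEFAULT_SPACING,
    frame_interval=DEFAULT_FRAME_INTERVAL,
    min_frames: int = 45,
) -> list[TrajectoryFeatures]:
    """Per-trajectory migration features after the minimum-duration filter."""
    out = []
    for traj in filter_min_duration(trajectories, min_frames):
        times_h, pos_um = to_physical(traj, spacing, frame_interval)
        out.append(
            TrajectoryFeatures(
                tracker_id=traj.tracker_id,
                duration_h=float(times_h[-1] - times_h[0]),
                avg_speed=average_speed(times_h, pos_um),
                mrdo_rate=mrdo(times_h, pos_um),
                max_displacement_um=max_displacement(times_h, pos_um),
            )
        )
    return out


def features_table(features, condition: str | None = None) -> pd.DataFrame:
    """Features as a DataFrame (one row per trajectory)."""
    rows = [
        {
            "tracker_id": f.tracker_id,
            "duration_h": f.duration_h,
            "avg_speed_um_h": f.avg_speed,
            "mrdo_um_h": f.mrdo_rate,
            "max_displacement_um": f.max_displacement_um,
        }
        for f in features
    ]
    df = pd.DataFrame(rows, columns=[
        "tracker_id", "duration_h", "avg_speed_um_h", "mrdo_um_h", "max_displacement_um",
    ])
    if condition is not None:
        df.insert(0, "condition", condition)
    return df


def compare_conditions(summaries, feature_name: str = "avg_speed"):
    """Kruskal-Wallis rank test of one feature across k >= 2 conditions.

    Returns ``(H, p_value)`` with the tie-corrected rank statistic.  Also
    reports per-condition medians and interquartile ranges in the returned
    report dict under ``.report`` style usage via :func:`condition_report`.
    """
    if len(summaries) < 2:
        raise ValueError("need at least two conditions to compare")
    samples = [s.values(feature_name) for s in summaries]
    if any(len(s) < 1 for s in samples):
        raise ValueError("every condition needs at least one trajectory")
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def condition_report(summaries, feature_names=("avg_speed", "mrdo_rate")) -> dict:
    """Per-feature test statistics plus per-condition median and IQR."""
    report: dict = {"conditions": [s.condition_name for s in summaries], "features": {}}
    for name in feature_names:
        h, p = compare_conditions(summaries, name)
        per_condition = {}
        for s in summaries:
            v = s.values(name)
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            per_condition[s.condition_name] = {
                "n": int(len(v)),
                "median": float(med),
                "iqr": [float(q1), float(q3)],
            }
        report["features"][name] = {"H": h, "p_value": p, "per_condition": per_condition}
    return report
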