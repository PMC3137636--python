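"""Ground-truthed synthetic 3D time-lapse scenes.

Emulates what matters to the tracking pipeline about phase-contrast cells
in gel: a bright focal disk whose off-focus slices carry ring-like halos
growing linearly with defocus (two cones squashed into each other),
band-limited background texture standing in for collagen fibers, Gaussian
random-walk cell motion, and the motion events that stress a tracker —
crossings, divisions, entries, exits.  Every scene is generated from a
seed, carries its ground-truth paths, and can score a set of trajectories
against that truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .volume_io import (
    DEFAULT_FRAME_INTERVAL,
    DEFAULT_SPACING,
    Volume,
    VolumeSequence,
)
from .correlation import CellTemplate

__all__ = [
    "SyntheticCellModel",
    "CellPath",
    "SyntheticScene",
    "render_cell",
    "make_template",
    "simulate_scene",
    "render_frame",
    "render_sequence",
    "score_against_truth",
    "scenario_two_cell_crossing",
    "scenario_parasite",
    "default_benchmark_scene",
]


@dataclass
class SyntheticCellModel:
    """Appearance of one phase-contrast cell.

    focal_radius_vox : XY radius of the bright focal disk (~7.5 voxels, a
        15-pixel cell diameter at 0.78 µm/pixel).
    z_extent_slices : depth of the double-cone halo pattern (12 slices,
        i.e. the cell appearance covers 10-15 Z-slices at 8 µm/slice).
    peak_intensity : 8-bit value at the focal center.
    halo_amplitude : intensity of the off-focus rings.
    """

    focal_radius_vox: float = 7.5
    z_extent_slices: int = 12
    peak_intensity: float = 200.0
    halo_amplitude: float = 110.0

    def __post_init__(self) -> None:
        if self.focal_radius_vox <= 0 or self.z_extent_slices < 1:
            raise ValueError("focal radius and z extent must be positive")
        if not (0 < self.peak_intensity <= 255):
            raise ValueError("peak_intensity must lie in (0, 255]")


@dataclass
class CellPath:
    """Ground-truth path of one cell: frame -> continuous (x, y, z)."""

    cell_id: int
    positions: dict  # frame -> np.ndarray (x, y, z)
    intensity: float = 1.0
    tag: str = ""  # "", "entry", "division", "crossing", "artifact", "exit"

    @property
    def frames(self) -> list[int]:
        return sorted(self.positions)


@dataclass
class SyntheticScene:
    shape: tuple[int, int, int]  # (nz, ny, nx)
    n_frames: int
    cells: list
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    frame_interval: float = DEFAULT_FRAME_INTERVAL
    background_level: float = 30.0
    background_amplitude: float = 15.0
    seed: int = 0
    events: list = field(default_factory=list)

    def cells_at(self, frame: int):
        return [c for c in self.cells if frame in c.positions]


def render_cell(model: SyntheticCellModel, center, canvas: np.ndarray, intensity: float = 1.0) -> np.ndarray:
    """Additively render the double-cone cell pattern into a (z, y, x) canvas.

    At slice offset ``dz`` from the focal plane the pattern is a Gaussian
    annulus whose radius grows linearly with ``|dz|`` (a disk at focus) and
    whose amplitude decays from the focal peak toward the cone tips.
    Contributions falling outside the canvas are clipped away; values are
    not clipped here (the caller clips to 8 bits after compositing).
    """
    cx, cy, cz = (float(c) for c in center)
    nz, ny, nx = canvas.shape
    half = model.z_extent_slices / 2.0
    w = model.focal_radius_vox / 1.7  # in-plane Gaussian width
    slope = model.focal_radius_vox / half  # ring growth per slice of defocus
    rmax = model.focal_radius_vox * 2.0 + 3.0 * w

    z_lo = max(0, int(math.ceil(cz - half)))
    z_hi = min(nz - 1, int(math.floor(cz + half)))
    y_lo = max(0, int(math.floor(cy - rmax)))
    y_hi = min(ny - 1, int(math.ceil(cy + rmax)))
    x_lo = max(0, int(math.floor(cx - rmax)))
    x_hi = min(nx - 1, int(math.ceil(cx + rmax)))
    if z_lo > z_hi or y_lo > y_hi or x_lo > x_hi:
        return canvas

    yy, xx = np.meshgrid(np.arange(y_lo, y_hi + 1), np.arange(x_lo, x_hi + 1), indexing="ij")
    r = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2)
    for z in range(z_lo, z_hi + 1):
        dz = z - cz
        axial = max(0.0, 1.0 - abs(dz) / (half + 1.0))
        amp = (
            model.halo_amplitude
            + (model.peak_intensity - model.halo_amplitude) * math.exp(-((dz / 1.2) ** 2))
        ) * axial * intensity
        rho = slope * abs(dz)
        canvas[z, y_lo:y_hi + 1, x_lo:x_hi + 1] += amp * np.exp(-((r - rho) ** 2) / (2.0 * w * w))
    return canvas


def make_template(model: SyntheticCellModel | None = None, size=(21, 21, 13)) -> CellTemplate:
    """Synthesize a matched-filter template by rendering one cell.

    ``size`` is (sx, sy, sz); the cell is rendered at the geometric middle
    of a zero canvas, so the template's maximum sits at its center offset.
    """
    model = model or SyntheticCellModel()
    sx, sy, sz = size
    canvas = np.zeros((sz, sy, sx), dtype=np.float64)
    center = (sx // 2, sy // 2, sz // 2)
    render_cell(model, center, canvas)
    return CellTemplate(data=np.clip(canvas, 0, 255))


# ---------------------------------------------------------------------------
# scene simulation


def _reflect(value: float, lo: float, hi: float) -> float:
    """Reflect a coordinate into [lo, hi]."""
    if hi <= lo:
        return lo
    span = hi - lo
    v = (value - lo) % (2.0 * span)
    if v > span:
        v = 2.0 * span - v
    return lo + v


def _clamp(v, lo, hi):
    return min(max(v, lo), hi)


def simulate_scene(
    n_cells: int = 20,
    n_frames: int = 100,
    shape=(28, 288, 288),
    sigma_xy: float = 0.8,
    sigma_z: float = 0.12,
    drift_um_h=(0.0, 0.0, 0.0),
    events=(),
    seed: int = 0,
    spacing=DEFAULT_SPACING,
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
    placement_margin: float = 25.0,
    min_separation: float = 40.0,
    background_level: float = 30.0,
    background_amplitude: float = 15.0,
    intensity_range=(0.9, 1.0),
) -> SyntheticScene:
    """Generate seeded ground-truth cell paths.

    Cells start at mutually separated random positions and perform a
    Gaussian random walk (per-axis voxel sigmas, optional drift given in
    µm/h and converted through spacing and frame interval), reflected at
    the volume borders.  ``events`` is a list of dicts scripting motion
    events, e.g.::

        {"type": "crossing", "cells": (0, 1), "frame": 22}
        {"type": "division", "cell": 4, "frame": 40}
        {"type": "entry", "frame": 30, "side": "x_low"}
        {"type": "exit", "cell": 7, "frame": 80}

    Scripted segments override the random walk; afterwards the cell
    resumes walking from the scripted end point.
    """
    if n_cells < 0 or n_frames < 1:
        raise ValueError("need n_cells >= 0 and n_frames >= 1")
    nz, ny, nx = shape
    rng = np.random.default_rng(seed)
    drift_vox = np.asarray(drift_um_h, dtype=float) * (frame_interval / 60.0) / np.asarray(spacing)

    events = [dict(e) for e in events]
    for e in events:
        if e["type"] in ("division", "exit") and not (0 <= e["cell"] < n_cells):
            raise ValueError(f"event references nonexistent cell {e['cell']}")
        if e["type"] == "crossing" and any(not (0 <= c < n_cells) for c in e["cells"]):
            raise ValueError(f"crossing references nonexistent cell: {e['cells']}")
        if not (0 <= e["frame"] < n_frames):
            raise ValueError(f"event frame {e['frame']} outside the sequence")

    # initial placement with minimum mutual separation (rejection sampling)
    z_lo, z_hi = max(0, nz // 2 - 3), min(nz - 1, nz // 2 + 3)
    starts: list[np.ndarray] = []
    for _round in range(20):
        starts = []
        for _ in range(400 * max(1, n_cells)):
            p = np.array(
                [
                    rng.uniform(placement_margin, nx - 1 - placement_margin),
                    rng.uniform(placement_margin, ny - 1 - placement_margin),
                    rng.uniform(z_lo, z_hi),
                ]
            )
            if all(np.hypot(p[0] - q[0], p[1] - q[1]) >= min_separation for q in starts):
                starts.append(p)
                if len(starts) == n_cells:
                    break
        if len(starts) == n_cells:
            break
    if len(starts) < n_cells and n_cells > 0:
        # dense request: fall back to a jittered grid, which guarantees the
        # separation whenever the field can hold it at all
        width = nx - 1 - 2 * placement_margin
        height = ny - 1 - 2 * placement_margin
        cols = max(1, int(math.ceil(math.sqrt(n_cells * width / max(height, 1e-9)))))
        rows = int(math.ceil(n_cells / cols))
        step_x, step_y = width / cols, height / rows
        if min(step_x, step_y) < min_separation:
            raise ValueError("cannot place cells with the requested separation")
        jx = max(0.0, (step_x - min_separation) / 2.0)
        jy = max(0.0, (step_y - min_separation) / 2.0)
        nodes = [(i, j) for j in range(rows) for i in range(cols)]
        rng.shuffle(nodes)
        starts = [
            np.array(
                [
                    placement_margin + (i + 0.5) * step_x + rng.uniform(-jx, jx),
                    placement_margin + (j + 0.5) * step_y + rng.uniform(-jy, jy),
                    rng.uniform(z_lo, z_hi),
                ]
            )
            for i, j in nodes[:n_cells]
        ]

    cells = [
        CellPath(
            cell_id=i,
            positions={0: starts[i].copy()},
            intensity=float(rng.uniform(*intensity_range)),
        )
        for i in range(n_cells)
    ]
    # scripted future positions per cell: cell_id -> {frame: (x, y, z)}
    scripts: dict[int, dict[int, np.ndarray]] = {}
    absent_after: dict[int, int] = {}
    next_cell_id = n_cells

    def script_segment(cid, start_frame, p_from, p_to, n_steps):
        seg = scripts.setdefault(cid, {})
        for k in range(1, n_steps + 1):
            f = start_frame + k - 1
            if f < n_frames:
                seg[f] = p_from + (p_to - p_from) * (k / n_steps)

    by_frame: dict[int, list[dict]] = {}
    for e in events:
        by_frame.setdefault(e["frame"], []).append(e)

    for t in range(1, n_frames + 1):
        # handle events declared at frame t-1 (positions at t-1 now known)
        for e in by_frame.get(t - 1, ()):
            kind = e["type"]
            if kind == "crossing":
                i, j = e["cells"]
                pi = cells[i].positions[t - 1]
                pj = cells[j].positions[t - 1]
                others = [
                    c.positions[t - 1] for c in cells
                    if c.cell_id not in (i, j) and (t - 1) in c.positions
                ]
                mid = (pi + pj) / 2.0
                sep0 = pi[:2] - pj[:2]
                n0 = np.hypot(*sep0)
                perp = (np.array([-sep0[1], sep0[0]]) / n0) if n0 > 1e-9 else np.array([0.0, 1.0])
                # nudge the meeting point away from bystander cells
                best = None
                for k in (-3, -2, -1, 0, 1, 2, 3):
                    cand = mid[:2] + perp * (10.0 * k)
                    cand = np.array([
                        _clamp(cand[0], placement_margin, nx - 1 - placement_margin),
                        _clamp(cand[1], placement_margin, ny - 1 - placement_margin),
                    ])
                    probes = [cand, cand + 30.0 * u_probe, cand - 30.0 * u_probe] if (u_probe := (sep0 / n0 if n0 > 1e-9 else np.array([1.0, 0.0]))) is not None else [cand]
                    clearance = min(
                        (np.hypot(pr[0] - q[0], pr[1] - q[1]) for q in others for pr in probes),
                        default=1e9,
                    )
                    if best is None or clearance > best[0]:
                        best = (clearance, cand)
                mx, my = best[1]
                mz = _clamp(mid[2], 7, nz - 8)
                sep = pi[:2] - pj[:2]
                norm = np.hypot(*sep)
                u = sep / norm if norm > 1e-9 else np.array([1.0, 0.0])
                qi = np.array([mx + 2.5 * u[0], my + 2.5 * u[1], mz])
                qj = np.array([mx - 2.5 * u[0], my - 2.5 * u[1], mz])
                na = max(2, int(math.ceil(max(np.linalg.norm(pi - qi), np.linalg.norm(pj - qj)) / 6.0)))
                script_segment(i, t, pi, qi, na)
                script_segment(j, t, pj, qj, na)
                hold = 3
                for k in range(hold):
                    f = t + na + k
                    if f < n_frames:
                        scripts[i][f] = qi.copy()
                        scripts[j][f] = qj.copy()
                ri = np.array([_clamp(mx + 30 * u[0], 12, nx - 13), _clamp(my + 30 * u[1], 12, ny - 13), mz])
                rj = np.array([_clamp(mx - 30 * u[0], 12, nx - 13), _clamp(my - 30 * u[1], 12, ny - 13), mz])
                script_segment(i, t + na + hold, qi, ri, 5)
                script_segment(j, t + na + hold, qj, rj, 5)
                cells[i].tag = cells[i].tag or "crossing"
                cells[j].tag = cells[j].tag or "crossing"
            elif kind == "division":
                parent = cells[e["cell"]]
                p0 = parent.positions[t - 1]
                child = CellPath(
                    cell_id=next_cell_id,
                    positions={t - 1: p0 + np.array([2.0, 0.0, 0.0])},
                    intensity=parent.intensity,
                    tag="division",
                )
                next_cell_id += 1
                cells.append(child)
                far = p0 + np.array([2.0 + 2.5 * 15, 0.0, 0.0])
                far[0] = _clamp(far[0], 12, nx - 13)
                script_segment(child.cell_id, t, child.positions[t - 1], far, 15)
            elif kind == "entry":
                side = e.get("side", "x_low")
                present = [c.positions[t - 1] for c in cells if (t - 1) in c.positions]

                def entry_points(side, lateral, zc):
                    if side == "x_low":
                        return np.array([1.0, lateral, zc]), np.array([31.0, lateral, zc])
                    if side == "x_high":
                        return np.array([nx - 2.0, lateral, zc]), np.array([nx - 32.0, lateral, zc])
                    if side == "y_low":
                        return np.array([lateral, 1.0, zc]), np.array([lateral, 31.0, zc])
                    return np.array([lateral, ny - 2.0, zc]), np.array([lateral, ny - 32.0, zc])

                hi_lat = (ny if side.startswith("x") else nx) - 1 - placement_margin
                p0 = p1 = None
                # enter well clear of resident cells so the entry itself, not a
                # chance near-miss, is the event being exercised
                for _ in range(200):
                    lateral = float(rng.uniform(placement_margin, hi_lat))
                    zc = float(rng.uniform(z_lo, z_hi))
                    q0, q1 = entry_points(side, lateral, zc)
                    clearance = min(
                        (min(np.hypot(q[0] - p[0], q[1] - p[1]) for q in (q0, q1))
                         for p in present),
                        default=1e9,
                    )
                    if clearance >= 50.0:
                        p0, p1 = q0, q1
                        break
                if p0 is None:
                    p0, p1 = entry_points(side, float(rng.uniform(placement_margin, hi_lat)),
                                          float(rng.uniform(z_lo, z_hi)))
                child = CellPath(
                    cell_id=next_cell_id, positions={t - 1: p0},
                    intensity=float(rng.uniform(*intensity_range)), tag="entry",
                )
                next_cell_id += 1
                cells.append(child)
                script_segment(child.cell_id, t, p0, p1, 12)
            elif kind == "exit":
                cell = cells[e["cell"]]
                p0 = cell.positions[t - 1]
                # walk out through the nearest XY face
                faces = [
                    (p0[0], np.array([-6.0, p0[1], p0[2]])),
                    (nx - 1 - p0[0], np.array([nx + 5.0, p0[1], p0[2]])),
                    (p0[1], np.array([p0[0], -6.0, p0[2]])),
                    (ny - 1 - p0[1], np.array([p0[0], ny + 5.0, p0[2]])),
                ]
                target = min(faces)[1]
                n_steps = max(2, int(math.ceil(np.linalg.norm(target - p0) / 2.5)))
                script_segment(cell.cell_id, t, p0, target, n_steps)
                cell.tag = cell.tag or "exit"
            else:
                raise ValueError(f"unknown event type {kind!r}")

        if t >= n_frames:
            break

        # advance every present cell by script or random walk
        for cell in cells:
            if cell.cell_id in absent_after and t > absent_after[cell.cell_id]:
                continue
            if (t - 1) not in cell.positions:
                continue
            scripted = scripts.get(cell.cell_id, {})
            if t in scripted:
                p = scripted[t]
                inside = 0 <= p[0] <= nx - 1 and 0 <= p[1] <= ny - 1 and 0 <= p[2] <= nz - 1
                if not inside:
                    absent_after[cell.cell_id] = t - 1
                    continue
                cell.positions[t] = np.asarray(p, dtype=float).copy()
            else:
                prev = cell.positions[t - 1]
                step = rng.normal(0.0, [sigma_xy, sigma_xy, sigma_z]) + drift_vox
                p = prev + step
                cell.positions[t] = np.array(
                    [
                        _reflect(p[0], 0.0, nx - 1.0),
                        _reflect(p[1], 0.0, ny - 1.0),
                        _reflect(p[2], 0.0, nz - 1.0),
                    ]
                )

    return SyntheticScene(
        shape=tuple(shape),
        n_frames=n_frames,
        cells=cells,
        spacing=tuple(spacing),
        frame_interval=frame_interval,
        background_level=background_level,
        background_amplitude=background_amplitude,
        seed=seed,
        events=events,
    )


# ---------------------------------------------------------------------------
# rendering


def render_frame(scene: SyntheticScene, model: SyntheticCellModel, frame: int) -> Volume:
    """Render one frame: seeded background texture plus all present cells."""
    nz, ny, nx = scene.shape
    canvas = np.zeros((nz, ny, nx), dtype=np.float64)
    if scene.background_amplitude > 0:
        rng = np.random.default_rng([int(scene.seed) % (2**31), frame])
        noise = rng.standard_normal((nz, ny, nx))
        # sub-cell-scale texture: collagen artifacts are fine fibers, not blobs
        noise = gaussian_filter(noise, sigma=(0.5, 1.0, 1.0))
        std = noise.std()
        if std > 0:
            noise *= scene.background_amplitude / std
        canvas += noise
    canvas += scene.background_level
    for cell in scene.cells_at(frame):
        render_cell(model, cell.positions[frame], canvas, intensity=cell.intensity)
    data = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    return Volume(data=data, spacing=scene.spacing, frame_index=frame)


def render_sequence(scene: SyntheticScene, model: SyntheticCellModel | None = None) -> VolumeSequence:
    model = model or SyntheticCellModel()
    volumes = [render_frame(scene, model, t) for t in range(scene.n_frames)]
    return VolumeSequence(volumes=volumes, frame_interval=scene.frame_interval)


# ---------------------------------------------------------------------------
# scoring


def score_against_truth(trajectories, scene: SyntheticScene, match_dist=(5.0, 2.0)) -> dict:
    """Score trajectories against the scene's ground truth.

    A trajectory point matches a ground-truth cell present in that frame
    when their XY Euclidean distance is at most ``d_xy`` voxels and the Z
    distance at most ``d_z`` slices; the nearest such cell is the point's
    matched identity.  Artifact-tagged paths are not ground-truth cells.

    Returns recall (matched truth points / truth points), precision
    (matched trajectory points / trajectory points) and the fraction of
    trajectories whose matched identity changes at least once.  Identity
    changes are assessed over the unambiguous points only: while two cells
    are conjoined both fall within the match distance and the nearest one
    is arbitrary, so a tracker legitimately following the conjoined pair is
    not charged with an identity error.
    """
    d_xy, d_z = match_dist
    truth_cells = [c for c in scene.cells if c.tag != "artifact"]
    truth_total = sum(len(c.positions) for c in truth_cells)
    matched_truth: set = set()
    traj_points = 0
    matched_points = 0
    n_switched = 0

    by_frame: dict[int, list] = {}
    for c in truth_cells:
        for f, p in c.positions.items():
            by_frame.setdefault(f, []).append((c.cell_id, p))

    for traj in trajectories:
        ids = []
        for f, (x, y, z) in traj.points:
            traj_points += 1
            candidates = []
            for cid, p in by_frame.get(f, ()):
                dxy = math.hypot(p[0] - x, p[1] - y)
                if dxy <= d_xy and abs(p[2] - z) <= d_z:
                    candidates.append((dxy, cid))
            if candidates:
                matched_points += 1
                matched_truth.add((f, min(candidates)[1]))
                if len(candidates) == 1:
                    ids.append(candidates[0][1])
        if any(a != b for a, b in zip(ids, ids[1:])):
            n_switched += 1

    n_traj = len(trajectories)
    return {
        "recall": len(matched_truth) / truth_total if truth_total else 0.0,
        "precision": matched_points / traj_points if traj_points else 0.0,
        "id_switch_fraction": n_switched / n_traj if n_traj else 0.0,
        "n_trajectories": n_traj,
        "n_truth_points": truth_total,
        "n_matched_truth_points": len(matched_truth),
    }


# ---------------------------------------------------------------------------
# named scenarios and the default benchmark


def scenario_two_cell_crossing():
    """Two cells whose paths intersect: the canonical collision scenario.

    A bright cell sits still while a dimmer one crosses it; their trackers
    collide when the correlation blobs merge, a fresh tracker takes over
    the conjoined object, and the departing cell is re-detected after
    parting.  Rendered without background texture so the four-trajectory
    timeline is exact.
    """
    n_frames = 20
    shape = (20, 120, 160)
    y0, z0 = 60.0, 9.0
    a = CellPath(cell_id=0, positions={}, intensity=1.0, tag="crossing")
    b = CellPath(cell_id=1, positions={}, intensity=0.8, tag="crossing")
    xb = [130, 120, 110, 100, 90, 80, 70, 60, 54, 54, 54, 64, 74, 84, 94, 104, 104, 104, 104, 104]
    for t in range(n_frames):
        a.positions[t] = np.array([50.0, y0, z0])
        b.positions[t] = np.array([float(xb[t]), y0, z0])
    scene = SyntheticScene(
        shape=shape, n_frames=n_frames, cells=[a, b],
        background_level=0.0, background_amplitude=0.0, seed=0,
    )
    return scene, SyntheticCellModel()


def scenario_parasite():
    """A transient spurious detection spawning a short-lived tracker.

    An artifact blob appears next to a steadily tracked cell for two
    frames; the tracker it spawns converges onto the cell's peak and is
    removed as a parasite, leaving the established trajectory unbroken.
    """
    n_frames = 12
    shape = (20, 100, 100)
    cell = CellPath(cell_id=0, positions={}, intensity=1.0)
    artifact = CellPath(cell_id=1, positions={}, intensity=1.0, tag="artifact")
    for t in range(n_frames):
        cell.positions[t] = np.array([50.0, 50.0, 9.0])
    for t in (6, 7):
        artifact.positions[t] = np.array([74.0, 50.0, 9.0])
    scene = SyntheticScene(
        shape=shape, n_frames=n_frames, cells=[cell, artifact],
        background_level=0.0, background_amplitude=0.0, seed=0,
    )
    return scene, SyntheticCellModel()


def default_benchmark_scene(seed: int = 0) -> SyntheticScene:
    """The default tracking benchmark: 20 cells, 100 frames, with events.

    Two scripted crossings, two cell entries and one division, on the
    default background texture — the conditions under which detection
    recall and the trajectory identity-error fraction are measured.
    """
    events = [
        {"type": "crossing", "cells": (0, 1), "frame": 22},
        {"type": "crossing", "cells": (2, 3), "frame": 55},
        {"type": "entry", "frame": 30, "side": "x_low"},
        {"type": "entry", "frame": 60, "side": "y_high"},
        {"type": "division", "cell": 4, "frame": 40},
    ]
    return simulate_scene(
        n_cells=20,
        n_frames=100,
        shape=(28, 288, 288),
        sigma_xy=0.8,
        sigma_z=0.12,
        events=events,
        seed=seed,
    )
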