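"""The per-frame tracking loop: convergence, collisions, association, spawning.

Every distinguishable object must carry a tracker — that is what makes
tracker collisions (two kernels converging onto the same peak) a reliable
signal of cells touching or of duplicate detections.  Each frame runs, in
order:

1. converge every active tracker in the current correlated volume;
2. stop trackers that converged into the boundary margins;
3. group trackers that converged to (nearly) the same point and resolve
   each group: a uniquely short-lived member (a "parasite", at most 5
   frames old) is removed and the established trajectory continues;
   otherwise every member stops, because after cells touch it is not
   knowable which tracker follows which cell;
4. detect all objects in the volume, associate each surviving tracker to
   the object its position falls in, and spawn a fresh tracker on the
   geometric center of every object left untracked (conjoined pairs,
   entering cells, division products, or re-detections after a collision).

Stopped trajectories end at their last pre-collision frame and are kept
for analysis; tracker ids are never reused.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .correlation import CorrelatedVolume
from .detection import DetectionParams, DetectedObject, detect_cells
from . import tracking
from .tracking import MeanShiftParams, Tracker, mean_shift_converge, near_boundary

__all__ = [
    "Trajectory",
    "CollisionEvent",
    "find_collisions",
    "resolve_collision",
    "associate",
    "spawn_on_untracked",
    "TrackingSession",
]

END_REASONS = ("collision", "boundary", "parasite", "sequence_end", "ongoing")


@dataclass
class Trajectory:
    """The ordered positions of one tracker and why it ended."""

    tracker_id: int
    points: list  # of (frame_index, (x, y, z))
    end_reason: str = "ongoing"

    @property
    def birth_frame(self) -> int:
        return self.points[0][0]

    @property
    def last_frame(self) -> int:
        return self.points[-1][0]

    @property
    def n_frames(self) -> int:
        return len(self.points)


@dataclass
class CollisionEvent:
    frame_index: int
    tracker_ids: tuple
    resolution: str  # "all_stopped" | "parasite_removed"
    removed_ids: tuple = ()


def find_collisions(trackers, positions, collision_distance=(3.5, 2.0)):
    """Group trackers that converged to the same location.

    ``positions`` maps tracker id -> converged (x, y, z).  Two trackers are
    proximate when their positions differ by at most ``d_xy`` in each of x
    and y AND at most ``d_z`` in z; groups are the connected components of
    that relation.  Returns a list of id tuples (each of size >= 2).
    """
    d_xy, d_z = collision_distance
    ids = [t.id for t in trackers if t.state == tracking.ACTIVE]
    parent = {i: i for i in ids}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            pa, pb = positions[ids[a]], positions[ids[b]]
            if (
                abs(pa[0] - pb[0]) <= d_xy
                and abs(pa[1] - pb[1]) <= d_xy
                and abs(pa[2] - pb[2]) <= d_z
            ):
                parent[find(ids[a])] = find(ids[b])
    groups: dict[int, list[int]] = {}
    for i in ids:
        groups.setdefault(find(i), []).append(i)
    return [tuple(sorted(g)) for g in groups.values() if len(g) >= 2]


def resolve_collision(group, trajectories, frame_index: int, parasite_max_life: int = 5) -> CollisionEvent:
    """Decide the fate of a group of collided trackers.

    A tracker's lifetime is the number of frames it has existed (recorded
    points so far).  If exactly one member's lifetime is at most
    ``parasite_max_life``, it is a parasite — a short-lived duplicate born
    of a false detection or oversegmentation — and only it is removed; the
    longer trajectories continue unaffected.  In every other case (all
    long-lived, or several short-lived so no unique parasite) all members
    stop, ending at the previous frame's position.
    """
    lifetimes = {tid: trajectories[tid].n_frames for tid in group}
    short = [tid for tid in group if lifetimes[tid] <= parasite_max_life]
    if len(short) == 1:
        return CollisionEvent(
            frame_index=frame_index,
            tracker_ids=tuple(group),
            resolution="parasite_removed",
            removed_ids=(short[0],),
        )
    return CollisionEvent(
        frame_index=frame_index,
        tracker_ids=tuple(group),
        resolution="all_stopped",
        removed_ids=tuple(group),
    )


def associate(trackers, objects):
    """Partition detected objects into tracked and untracked.

    An object is tracked iff at least one active tracker's rounded position
    lies inside its voxel set.  Trackers sitting on background (inside no
    object) are tolerated — a weak cell may simply have dipped below the
    noise threshold this frame.
    """
    active = [t for t in trackers if t.state == tracking.ACTIVE]
    tracked, untracked = [], []
    for obj in objects:
        if any(obj.contains_position(t.position) for t in active):
            tracked.append(obj)
        else:
            untracked.append(obj)
    return tracked, untracked


def spawn_on_untracked(untracked, next_id: int, frame: int, volume=None):
    """Create one new tracker per untracked object, at its geometric center.

    On the rare non-convex component whose rounded centroid falls outside
    its own voxel set, the tracker is placed on the object's peak voxel so
    the object genuinely contains its tracker.
    """
    new = []
    for k, obj in enumerate(untracked):
        pos = obj.centroid
        if not obj.contains_position(pos):
            if volume is not None:
                data = np.asarray(volume.data if hasattr(volume, "data") else volume)
                z, y, x = max(obj.voxels, key=lambda v: data[v])
            else:
                z, y, x = next(iter(obj.voxels))
            pos = (float(x), float(y), float(z))
        new.append(Tracker(id=next_id + k, position=pos, birth_frame=frame))
    return new


@dataclass
class TrackingSession:
    """Incremental state of a tracking run over a correlated volume sequence.

    Feed correlated volumes in frame order to :meth:`advance_frame`; call
    :meth:`finalize` after the last frame to close the surviving
    trajectories with ``end_reason='sequence_end'``.
    """

    detection_params: DetectionParams = field(default_factory=DetectionParams)
    mean_shift_params: MeanShiftParams = field(default_factory=MeanShiftParams)
    boundary_margins: tuple[float, float] = (10.0, 5.0)
    collision_distance: tuple[float, float] = (3.5, 2.0)
    parasite_max_life: int = 5

    trackers: dict = field(default_factory=dict)  # id -> Tracker
    trajectories: dict = field(default_factory=dict)  # id -> Trajectory
    events: list = field(default_factory=list)
    next_id: int = 0
    last_frame: int = -1
    last_objects: list = field(default_factory=list)

    def _active(self):
        return [t for t in self.trackers.values() if t.state == tracking.ACTIVE]

    def _stop(self, tid: int, state: str, reason: str) -> None:
        self.trackers[tid].state = state
        self.trajectories[tid].end_reason = reason

    def advance_frame(self, corr_volume: CorrelatedVolume) -> None:
        t = corr_volume.frame_index
        if t != self.last_frame + 1:
            raise ValueError(
                f"frames must be fed in order; expected {self.last_frame + 1}, got {t}"
            )
        shape = corr_volume.data.shape

        # (a) converge every active tracker from its previous position
        converged: dict[int, tuple] = {}
        for trk in self._active():
            pos, n_iter, ok = mean_shift_converge(corr_volume, trk.position, self.mean_shift_params)
            converged[trk.id] = pos
            if not ok:
                self.events.append(
                    {"type": "no_convergence", "frame": t, "tracker_id": trk.id}
                )

        # (b) boundary stops
        for trk in self._active():
            if near_boundary(converged[trk.id], shape, self.boundary_margins):
                self._stop(trk.id, tracking.STOPPED_BOUNDARY, "boundary")
                self.events.append(
                    {"type": "boundary_stop", "frame": t, "tracker_id": trk.id}
                )

        # (c) collisions among the survivors
        for group in find_collisions(self._active(), converged, self.collision_distance):
            event = resolve_collision(group, self.trajectories, t, self.parasite_max_life)
            if event.resolution == "parasite_removed":
                tid = event.removed_ids[0]
                self._stop(tid, tracking.REMOVED_PARASITE, "parasite")
            else:
                for tid in event.removed_ids:
                    self._stop(tid, tracking.STOPPED_COLLISION, "collision")
            self.events.append(
                {
                    "type": "collision",
                    "frame": t,
                    "tracker_ids": list(event.tracker_ids),
                    "resolution": event.resolution,
                    "removed_ids": list(event.removed_ids),
                }
            )

        # commit converged positions to the surviving trackers
        for trk in self._active():
            trk.position = converged.get(trk.id, trk.position)
            if trk.id in converged:
                self.trajectories[trk.id].points.append((t, trk.position))

        # (d) detect all cells, (e) associate, (f) spawn on untracked objects
        objects = detect_cells(corr_volume, self.detection_params)
        tracked, untracked = associate(self._active(), objects)
        new_trackers = spawn_on_untracked(untracked, self.next_id, t, corr_volume)
        for trk in new_trackers:
            self.trackers[trk.id] = trk
            self.trajectories[trk.id] = Trajectory(tracker_id=trk.id, points=[(t, trk.position)])
            self.events.append({"type": "spawn", "frame": t, "tracker_id": trk.id})
        self.next_id += len(new_trackers)

        self.last_frame = t
        self.last_objects = objects

    def finalize(self) -> list[Trajectory]:
        for trk in self._active():
            self._stop(trk.id, tracking.STOPPED_END, "sequence_end")
        return [self.trajectories[tid] for tid in sorted(self.trajectories)]

    def all_objects_tracked(self) -> bool:
        """The all-cells-tracked invariant for the most recent frame."""
        active = self._active()
        return all(
            any(obj.contains_position(t.position) for t in active) for obj in self.last_objects
        )
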