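import numpy as np
import pytest

from celltrack3d import synthetic as syn
from celltrack3d.correlation import correlate_volume
from celltrack3d.detection import DetectedObject
from celltrack3d.lifecycle import (
    TrackingSession,
    Trajectory,
    associate,
    find_collisions,
    resolve_collision,
    spawn_on_untracked,
)
from celltrack3d.pipeline import PipelineConfig, run_pipeline
from celltrack3d.tracking import Tracker
from celltrack3d.volume_io import Volume, enhance_contrast


def _trackers(*positions):
    return [Tracker(id=i, position=p, birth_frame=0) for i, p in enumerate(positions)]


def _trajectory(tid, n_points, start_frame=0):
    return Trajectory(
        tracker_id=tid,
        points=[(start_frame + k, (0.0, 0.0, 0.0)) for k in range(n_points)],
    )


class TestFindCollisions:
    def test_identical_points_grouped(self):
        trackers = _trackers((10.0, 10.0, 5.0), (10.0, 10.0, 5.0))
        pos = {t.id: t.position for t in trackers}
        assert find_collisions(trackers, pos) == [(0, 1)]

    def test_distant_trackers_not_grouped(self):
        trackers = _trackers((10.0, 10.0, 5.0), (40.0, 10.0, 5.0), (10.0, 40.0, 5.0))
        pos = {t.id: t.position for t in trackers}
        assert find_collisions(trackers, pos) == []

    def test_proximity_chain_is_one_group(self):
        # A~B and B~C but A and C are 6 apart in x (> 3.5): union is {A, B, C}
        trackers = _trackers((10.0, 10.0, 5.0), (13.0, 10.0, 5.0), (16.0, 10.0, 5.0))
        pos = {t.id: t.position for t in trackers}
        assert find_collisions(trackers, pos) == [(0, 1, 2)]

    def test_z_distance_uses_own_threshold(self):
        trackers = _trackers((10.0, 10.0, 5.0), (10.0, 10.0, 8.0))
        pos = {t.id: t.position for t in trackers}
        assert find_collisions(trackers, pos, collision_distance=(3.5, 2.0)) == []


class TestResolveCollision:
    def test_two_long_lifetimes_all_stopped(self):
        trajs = {0: _trajectory(0, 50), 1: _trajectory(1, 60)}
        event = resolve_collision((0, 1), trajs, frame_index=70)
        assert event.resolution == "all_stopped"
        assert set(event.removed_ids) == {0, 1}

    def test_unique_short_lifetime_is_parasite(self):
        trajs = {0: _trajectory(0, 3), 1: _trajectory(1, 40)}
        event = resolve_collision((0, 1), trajs, frame_index=45)
        assert event.resolution == "parasite_removed"
        assert event.removed_ids == (0,)

    def test_two_short_lifetimes_no_unique_parasite(self):
        trajs = {0: _trajectory(0, 3), 1: _trajectory(1, 4)}
        event = resolve_collision((0, 1), trajs, frame_index=10)
        assert event.resolution == "all_stopped"
        assert set(event.removed_ids) == {0, 1}

    def test_boundary_lifetime_five_counts_as_parasite(self):
        trajs = {0: _trajectory(0, 5), 1: _trajectory(1, 30)}
        event = resolve_collision((0, 1), trajs, frame_index=35, parasite_max_life=5)
        assert event.resolution == "parasite_removed"


def _block_object(label, corner, size=3):
    z0, y0, x0 = corner
    voxels = frozenset(
        (z0 + dz, y0 + dy, x0 + dx)
        for dz in range(size) for dy in range(size) for dx in range(size)
    )
    centroid = (x0 + (size - 1) / 2, y0 + (size - 1) / 2, z0 + (size - 1) / 2)
    return DetectedObject(label=label, voxels=voxels, centroid=centroid, peak_intensity=200.0)


class TestAssociateAndSpawn:
    def test_tracker_inside_object_claims_it(self):
        obj = _block_object(1, (4, 4, 4))
        trackers = _trackers((5.2, 4.8, 5.1))
        tracked, untracked = associate(trackers, [obj])
        assert tracked == [obj] and untracked == []

    def test_no_trackers_everything_untracked(self):
        objs = [_block_object(i, (4 * i, 4 * i, 4 * i)) for i in (1, 2, 3)]
        tracked, untracked = associate([], objs)
        assert tracked == [] and untracked == objs

    def test_tracker_between_objects_claims_neither(self):
        a = _block_object(1, (4, 4, 4))
        b = _block_object(2, (4, 4, 12))
        trackers = _trackers((9.5, 5.0, 5.0))  # x between the blocks
        tracked, untracked = associate(trackers, [a, b])
        assert tracked == [] and untracked == [a, b]

    def test_spawn_one_per_object_with_consecutive_ids(self):
        objs = [_block_object(1, (2, 2, 2)), _block_object(2, (8, 8, 8))]
        new = spawn_on_untracked(objs, next_id=7, frame=4)
        assert [t.id for t in new] == [7, 8]
        assert all(t.birth_frame == 4 for t in new)
        assert new[0].position == objs[0].centroid

    def test_spawn_empty_list(self):
        assert spawn_on_untracked([], next_id=0, frame=0) == []


@pytest.fixture(scope="module")
def static_cell_run(cell_model):
    """Ten frames of a single stationary cell through the full loop."""
    cell = syn.CellPath(cell_id=0, positions={t: np.array([40.0, 40.0, 10.0]) for t in range(10)})
    scene = syn.SyntheticScene(shape=(22, 80, 80), n_frames=10, cells=[cell],
                               background_level=0.0, background_amplitude=0.0)
    seq = syn.render_sequence(scene, cell_model)
    result = run_pipeline(seq, syn.make_template(cell_model), PipelineConfig(min_frames=5))
    return scene, result


class TestAdvanceFrame:
    def test_static_cell_yields_one_full_trajectory(self, static_cell_run):
        scene, result = static_cell_run
        assert len(result.trajectories) == 1
        traj = result.trajectories[0]
        assert traj.n_frames == 10
        for _, (x, y, z) in traj.points:
            assert abs(x - 40.0) <= 1 and abs(y - 40.0) <= 1 and abs(z - 10.0) <= 1

    def test_frame_indices_strictly_consecutive(self, static_cell_run):
        _, result = static_cell_run
        for traj in result.trajectories:
            frames = [f for f, _ in traj.points]
            assert frames == list(range(frames[0], frames[0] + len(frames)))

    def test_out_of_order_frame_rejected(self):
        session = TrackingSession()
        vol = Volume(np.zeros((8, 20, 20)), frame_index=3)
        with pytest.raises(ValueError):
            session.advance_frame(vol)


@pytest.fixture(scope="module")
def crossing_result():
    scene, model = syn.scenario_two_cell_crossing()
    seq = syn.render_sequence(scene, model)
    return run_pipeline(seq, syn.make_template(model), PipelineConfig())


@pytest.fixture(scope="module")
def parasite_result():
    scene, model = syn.scenario_parasite()
    seq = syn.render_sequence(scene, model)
    return run_pipeline(seq, syn.make_template(model), PipelineConfig())


class TestScenarioCrossing:
    """The two-cells-touch-and-part scenario and its four-trajectory timeline."""

    def test_exactly_four_trajectories(self, crossing_result):
        assert len(crossing_result.trajectories) == 4

    def test_timeline(self, crossing_result):
        a, b, c, d = sorted(crossing_result.trajectories, key=lambda t: t.tracker_id)
        # A and B start at frame 0 and end together at the collision
        assert a.birth_frame == b.birth_frame == 0
        assert a.end_reason == b.end_reason == "collision"
        assert a.last_frame == b.last_frame
        # C takes over the conjoined object the frame the collision happened
        assert c.birth_frame == a.last_frame + 1
        assert c.end_reason == "sequence_end"
        # D starts when the departing cell is re-detected after parting
        assert d.birth_frame > c.birth_frame
        assert d.end_reason == "sequence_end"

    def test_single_collision_event(self, crossing_result):
        collisions = [e for e in crossing_result.events if e["type"] == "collision"]
        assert len(collisions) == 1
        assert collisions[0]["resolution"] == "all_stopped"


class TestScenarioParasite:
    def test_parasite_removed_and_long_trajectory_unbroken(self, parasite_result):
        long = [t for t in parasite_result.trajectories if t.end_reason == "sequence_end"]
        parasites = [t for t in parasite_result.trajectories if t.end_reason == "parasite"]
        assert len(long) == 1 and len(parasites) == 1
        assert long[0].birth_frame == 0 and long[0].n_frames == 12
        assert parasites[0].n_frames <= 5


class TestStateInvariants:
    def test_single_ownership_and_end_reason_conservation(self, benchmark_run):
        trajectories = benchmark_run["trajectories"]
        ids = [t.tracker_id for t in trajectories]
        assert len(ids) == len(set(ids))
        assert all(t.end_reason != "ongoing" for t in trajectories)
        stopped_by_collision = sum(1 for t in trajectories if t.end_reason == "collision")
        from_events = sum(
            len(e["removed_ids"])
            for e in benchmark_run["events"]
            if e["type"] == "collision" and e["resolution"] == "all_stopped"
        )
        assert stopped_by_collision == from_events

    def test_no_event_scene_keeps_tracker_count_constant(self, cell_model):
        scene = syn.simulate_scene(n_cells=6, n_frames=12, shape=(24, 160, 160),
                                   sigma_xy=0.4, sigma_z=0.05, seed=9)
        seq = syn.render_sequence(scene, cell_model)
        template = syn.make_template(cell_model)
        config = PipelineConfig()
        session = TrackingSession(
            detection_params=config.detection_params(),
            mean_shift_params=config.mean_shift_params(),
        )
        counts = []
        for vol in seq:
            corr = correlate_volume(enhance_contrast(vol), template)
            session.advance_frame(corr)
            counts.append(sum(1 for t in session.trackers.values() if t.state == "active"))
        assert counts == [6] * 12
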