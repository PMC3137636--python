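import numpy as np
import pytest

from celltrack3d import synthetic as syn
from celltrack3d.analysis import average_speed, to_physical
from celltrack3d.correlation import correlate_raw, correlate_volume
from celltrack3d.lifecycle import Trajectory
from celltrack3d.volume_io import Volume


class TestRenderCell:
    def test_argmax_at_center(self, cell_model):
        canvas = np.zeros((24, 60, 60))
        syn.render_cell(cell_model, (30.0, 28.0, 11.0), canvas)
        z, y, x = np.unravel_index(np.argmax(canvas), canvas.shape)
        assert abs(x - 30) <= 1 and abs(y - 28) <= 1 and abs(z - 11) <= 1

    def test_additive_composition_preserves_separated_peaks(self, cell_model):
        one = np.zeros((24, 80, 80))
        syn.render_cell(cell_model, (20.0, 20.0, 11.0), one)
        two = np.zeros((24, 80, 80))
        syn.render_cell(cell_model, (60.0, 60.0, 11.0), two)
        both = np.zeros((24, 80, 80))
        syn.render_cell(cell_model, (20.0, 20.0, 11.0), both)
        syn.render_cell(cell_model, (60.0, 60.0, 11.0), both)
        np.testing.assert_allclose(both, one + two, atol=1e-9)

    def test_self_correlation_peaks_at_center(self, cell_model):
        canvas = np.zeros((26, 70, 70))
        syn.render_cell(cell_model, (35.0, 35.0, 13.0), canvas)
        template = syn.make_template(cell_model)
        corr = correlate_raw(canvas, template)
        z, y, x = np.unravel_index(np.argmax(corr), corr.shape)
        assert abs(x - 35) <= 1 and abs(y - 35) <= 1 and abs(z - 13) <= 1


class TestSimulateScene:
    def test_empty_scene(self):
        scene = syn.simulate_scene(n_cells=0, n_frames=5, seed=0)
        assert scene.cells == []

    def test_same_seed_bit_reproducible(self):
        a = syn.simulate_scene(n_cells=8, n_frames=20, seed=13)
        b = syn.simulate_scene(n_cells=8, n_frames=20, seed=13)
        assert len(a.cells) == len(b.cells)
        for ca, cb in zip(a.cells, b.cells):
            assert ca.positions.keys() == cb.positions.keys()
            for f in ca.positions:
                np.testing.assert_array_equal(ca.positions[f], cb.positions[f])

    def test_pure_drift_ground_truth_speed_exact(self):
        scene = syn.simulate_scene(
            n_cells=1, n_frames=16, sigma_xy=0.0, sigma_z=0.0,
            drift_um_h=(5.0, 0.0, 0.0), seed=3,
        )
        traj = Trajectory(0, sorted(
            (f, tuple(p)) for f, p in scene.cells[0].positions.items()
        ))
        times, pos = to_physical(traj, scene.spacing, scene.frame_interval)
        assert average_speed(times, pos) == pytest.approx(5.0)

    def test_paths_stay_inside_volume(self):
        scene = syn.simulate_scene(n_cells=10, n_frames=50, sigma_xy=3.0, seed=4)
        nz, ny, nx = scene.shape
        for cell in scene.cells:
            for p in cell.positions.values():
                assert 0 <= p[0] <= nx - 1 and 0 <= p[1] <= ny - 1 and 0 <= p[2] <= nz - 1

    def test_division_adds_a_cell_entry_inserts_at_border(self):
        events = [
            {"type": "division", "cell": 0, "frame": 5},
            {"type": "entry", "frame": 8, "side": "x_low"},
        ]
        scene = syn.simulate_scene(n_cells=3, n_frames=20, events=events, seed=6)
        assert len(scene.cells) == 5
        daughter = scene.cells[3]
        assert daughter.tag == "division" and min(daughter.positions) == 5
        entrant = scene.cells[4]
        assert entrant.tag == "entry" and min(entrant.positions) == 8
        assert entrant.positions[min(entrant.positions)][0] <= 2.0

    def test_exit_truncates_the_path(self):
        events = [{"type": "exit", "cell": 0, "frame": 4}]
        scene = syn.simulate_scene(n_cells=2, n_frames=40, events=events, seed=7)
        exiting = scene.cells[0]
        assert max(exiting.positions) < 39
        assert max(scene.cells[1].positions) == 39

    def test_infeasible_event_rejected(self):
        with pytest.raises(ValueError):
            syn.simulate_scene(n_cells=2, n_frames=10,
                               events=[{"type": "division", "cell": 5, "frame": 3}], seed=0)
        with pytest.raises(ValueError):
            syn.simulate_scene(n_cells=2, n_frames=10,
                               events=[{"type": "crossing", "cells": (0, 9), "frame": 3}], seed=0)


class TestRenderSequence:
    def test_zero_background_support_is_cell_only(self, cell_model):
        cell = syn.CellPath(0, {0: np.array([30.0, 30.0, 10.0])})
        scene = syn.SyntheticScene(shape=(22, 60, 60), n_frames=1, cells=[cell],
                                   background_level=0.0, background_amplitude=0.0)
        vol = syn.render_frame(scene, cell_model, 0)
        reference = np.zeros((22, 60, 60))
        syn.render_cell(cell_model, (30.0, 30.0, 10.0), reference)
        np.testing.assert_array_equal(vol.data > 0, np.rint(np.clip(reference, 0, 255)) > 0)

    def test_rendering_bit_reproducible(self, cell_model):
        scene = syn.simulate_scene(n_cells=4, n_frames=3, seed=11)
        a = syn.render_sequence(scene, cell_model)
        b = syn.render_sequence(scene, cell_model)
        for va, vb in zip(a, b):
            np.testing.assert_array_equal(va.data, vb.data)

    def test_every_rendered_cell_above_threshold_is_detected(self, cell_model):
        # rendering-detection consistency: detection may flag extra background
        # maxima in very sparse scenes, but never misses a bright cell
        scene = syn.simulate_scene(n_cells=6, n_frames=1, seed=12)
        from celltrack3d.detection import detect_cells
        from celltrack3d.volume_io import enhance_contrast

        vol = syn.render_frame(scene, cell_model, 0)
        corr = correlate_volume(enhance_contrast(vol), syn.make_template(cell_model))
        objects = detect_cells(corr)
        for cell in scene.cells:
            x, y, z = cell.positions[0]
            near = [
                o for o in objects
                if abs(o.centroid[0] - x) <= 2 and abs(o.centroid[1] - y) <= 2
                and abs(o.centroid[2] - z) <= 1 and o.peak_intensity >= 120.0
            ]
            assert near, f"cell at {(x, y, z)} not detected"


class TestScoreAgainstTruth:
    @staticmethod
    def _scene_with_two_cells(n_frames=10):
        cells = [
            syn.CellPath(0, {t: np.array([20.0 + t, 20.0, 8.0]) for t in range(n_frames)}),
            syn.CellPath(1, {t: np.array([60.0, 60.0 + t, 9.0]) for t in range(n_frames)}),
        ]
        return syn.SyntheticScene(shape=(20, 100, 100), n_frames=n_frames, cells=cells)

    def test_perfect_trajectories_score_perfectly(self):
        scene = self._scene_with_two_cells()
        trajs = [
            Trajectory(i, [(f, tuple(c.positions[f])) for f in sorted(c.positions)])
            for i, c in enumerate(scene.cells)
        ]
        m = syn.score_against_truth(trajs, scene)
        assert m["recall"] == 1.0 and m["precision"] == 1.0
        assert m["id_switch_fraction"] == 0.0

    def test_half_tracked_gives_half_recall(self):
        scene = self._scene_with_two_cells()
        c = scene.cells[0]
        trajs = [Trajectory(0, [(f, tuple(c.positions[f])) for f in sorted(c.positions)])]
        assert syn.score_against_truth(trajs, scene)["recall"] == 0.5

    def test_deliberate_identity_swap_counted(self):
        scene = self._scene_with_two_cells(n_frames=10)
        points = [(f, tuple(scene.cells[0].positions[f])) for f in range(5)]
        points += [(f, tuple(scene.cells[1].positions[f])) for f in range(5, 10)]
        trajs = [Trajectory(0, points)]
        assert syn.score_against_truth(trajs, scene)["id_switch_fraction"] == 1.0

    def test_artifact_paths_are_not_truth(self):
        scene = self._scene_with_two_cells()
        scene.cells[1].tag = "artifact"
        c = scene.cells[0]
        trajs = [Trajectory(0, [(f, tuple(c.positions[f])) for f in sorted(c.positions)])]
        assert syn.score_against_truth(trajs, scene)["recall"] == 1.0
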