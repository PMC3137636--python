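import numpy as np
import pytest

from celltrack3d import synthetic as syn
from celltrack3d.correlation import correlate_volume
from celltrack3d.lifecycle import TrackingSession
from celltrack3d.pipeline import PipelineConfig
from celltrack3d.volume_io import Volume, enhance_contrast


@pytest.fixture(scope="session")
def cell_model():
    return syn.SyntheticCellModel()


def gaussian_blob(shape=(16, 40, 40), center=(20.0, 20.0, 8.0), peak=255.0,
                  sigma_xy=6.0, sigma_z=2.0):
    """A smooth anisotropic Gaussian peak, the idealized correlation blob."""
    nz, ny, nx = shape
    zz, yy, xx = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij")
    cx, cy, cz = center
    return peak * np.exp(
        -((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma_xy**2)
        - (zz - cz) ** 2 / (2 * sigma_z**2)
    )


@pytest.fixture()
def blob_volume():
    return gaussian_blob()


@pytest.fixture(scope="session")
def benchmark_run(cell_model):
    """One full tracking run of the default 20-cell, 100-frame benchmark.

    Runs the pipeline frame by frame so the all-objects-tracked invariant
    can be recorded after every frame, then scores against ground truth.
    Shared session-wide because it is the most expensive fixture.
    """
    scene = syn.default_benchmark_scene(seed=1)
    template = syn.make_template(cell_model)
    config = PipelineConfig()
    session = TrackingSession(
        detection_params=config.detection_params(),
        mean_shift_params=config.mean_shift_params(),
        boundary_margins=config.boundary_margins,
        collision_distance=config.collision_distance,
        parasite_max_life=config.parasite_max_life,
    )
    invariant_per_frame = []
    lo, hi = config.contrast_percentiles
    for frame in range(scene.n_frames):
        volume = syn.render_frame(scene, cell_model, frame)
        corr = correlate_volume(enhance_contrast(volume, lo, hi), template)
        session.advance_frame(corr)
        invariant_per_frame.append(session.all_objects_tracked())
    trajectories = session.finalize()
    metrics = syn.score_against_truth(trajectories, scene)
    return {
        "scene": scene,
        "trajectories": trajectories,
        "events": session.events,
        "invariant_per_frame": invariant_per_frame,
        "metrics": metrics,
    }
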