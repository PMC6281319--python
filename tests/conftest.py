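"""Shared fixtures: small generated scenes reused across test modules."""

import numpy as np
import pytest

import nichedyn as nd


@pytest.fixture(scope="session")
def small_scene():
    """A modest control-like scene with default observation noise."""
    return nd.generate_scene(nd.control_like(n_cells=20, n_frames=40, seed=42))


@pytest.fixture(scope="session")
def noiseless_scene():
    """Zero-jitter scene: observed positions equal true cell centres."""
    params = nd.control_like(n_cells=20, n_frames=40, seed=7,
                             membrane_jitter_sd=0.0)
    return nd.generate_scene(params)


@pytest.fixture(scope="session")
def rendered_frame():
    """A tiny isotropic-voxel scene rendered at one frame."""
    params = nd.SceneParameters(n_cells=4, n_frames=5, tip_radius=12.0,
                                voxel_size=(0.4, 0.4, 0.4),
                                drift_velocity=(0.0, 0.0, 0.0),
                                tip_growth_rate=0.0, p_detach=0.0,
                                p_divide=0.0, p_exit=0.0,
                                membrane_jitter_sd=0.0, image_margin=6.0,
                                max_polar_deg=45.0, min_cell_spacing=8.5,
                                seed=3)
    scene = nd.generate_scene(params)
    return scene, nd.render_image_stack(scene, 2)


def random_track(rng, n=20, scale=5.0, cell_id=0):
    """Helper: a random CellTrack with consecutive frames."""
    pos = rng.normal(0.0, scale, size=(n, 3)).cumsum(axis=0)
    return nd.CellTrack(cell_id=cell_id, frames=np.arange(n), positions=pos)
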