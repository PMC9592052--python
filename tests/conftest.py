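import numpy as np
import pytest

from tpmquant import (
    OpticsNoiseModel,
    SceneConfig,
    project,
    render_scene,
    sample_scene,
)


@pytest.fixture(scope="session")
def fast_config():
    """Small field with short cells for quick rendering."""
    return SceneConfig(
        field_size_px=(320, 320),
        n_cells=2,
        cell_length_range_um=(5.0, 8.0),
        ring_fraction=0.5,
    )


@pytest.fixture(scope="session")
def noiseless_optics():
    return OpticsNoiseModel.noiseless_2d()


@pytest.fixture(scope="session")
def default2d_optics():
    """Default blur and noise, single plane."""
    return OpticsNoiseModel(n_zplanes=1)


@pytest.fixture(scope="session")
def exact_scene(fast_config, noiseless_optics):
    """A rendered noiseless, unblurred scene with ground truth."""
    scene = sample_scene(fast_config, seed=42)
    stack, gt = render_scene(scene, noiseless_optics)
    return scene, stack, gt


@pytest.fixture(scope="session")
def exact_projection(exact_scene):
    _, stack, _ = exact_scene
    return project(stack, mode="average")


def make_toy_cell():
    """Closed-form piecewise-constant cell (see tpmquant.validation)."""
    from tpmquant.validation import toy_cell

    return toy_cell()
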