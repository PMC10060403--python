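import numpy as np
import pytest

from spotgrid.synthetic import SceneSpec, generate_cell_scene, generate_grid_scene


@pytest.fixture
def grid_spec():
    return SceneSpec(rows=4, cols=6, pitch_x=40, pitch_y=40, spot_radius=12, seed=0)


@pytest.fixture
def clean_grid_scene(grid_spec):
    return generate_grid_scene(grid_spec)


@pytest.fixture
def cell_spec():
    return SceneSpec(
        rows=3, cols=3, pitch_x=40, pitch_y=40, spot_radius=16,
        cells_per_spot=4, alive_fraction=0.5, noise_sigma=0.0, seed=11,
    )


@pytest.fixture
def cell_scene(cell_spec):
    return generate_cell_scene(cell_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
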