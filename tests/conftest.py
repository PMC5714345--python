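import numpy as np
import pytest

from ecoscape.grids import Grid
from ecoscape.synthscape import SceneConfig, make_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_scene_config(seed: int = 7, **over) -> SceneConfig:
    """A compact scene for fast tests: 300x300 cells at 25 m (7.5 km)."""
    defaults = dict(n_rows=300, n_cols=300, cell_size=25.0, seed=seed,
                    n_species_iucn=10, n_species_endemic=6)
    defaults.update(over)
    return SceneConfig(**defaults)


@pytest.fixture(scope="session")
def small_scene():
    return make_scene(small_scene_config())


def grid_of(values, cell_size=25.0, **kw) -> Grid:
    return Grid(np.asarray(values, dtype=float), cell_size=cell_size, **kw)
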