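import numpy as np
import pytest

from specdiv import synthgen as sg


@pytest.fixture(scope="session")
def landscape():
    """Small 4-PA landscape shared by integration-style tests."""
    pool = sg.generate_species_pool(10, 4, 0.3, seed=42)
    grids = sg.generate_climate_grids(4, cells_per_pa=(2, 2), seed=43)
    return pool, grids


@pytest.fixture(scope="session")
def scene(landscape):
    pool, grids = landscape
    return sg.generate_scene(
        pool, grids, 0, size=(250, 250), noise_sd=0.002, seed=44
    )


@pytest.fixture(scope="session")
def survey(scene):
    return sg.generate_field_survey(scene, n_quadrats=40, seed=45)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
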