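import numpy as np
import pytest

from voxsegan.phantom import PhantomConfig, generate_phantom
from voxsegan.prep import normalize_intensity


@pytest.fixture(scope="session")
def small_config() -> PhantomConfig:
    """Desk-scale phantom cohort configuration shared across tests."""
    return PhantomConfig(grid_size=32, tumour_radius_range=(5.0, 8.0),
                         n_cases=3, seed=123)


@pytest.fixture(scope="session")
def small_case(small_config):
    return generate_phantom(small_config, 0)


@pytest.fixture(scope="session")
def normalized_case(small_case):
    return normalize_intensity(small_case)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
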