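import numpy as np
import pytest

from strainclass.presets import desk_generator_config
from strainclass.synthetic import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def desk_config():
    """Default desk-scale study conditions (58 cases, 25 concussions)."""
    return desk_generator_config(seed=1)


@pytest.fixture(scope="session")
def desk_dataset(desk_config):
    return generate_dataset(desk_config)


@pytest.fixture(scope="session")
def desk_features(desk_dataset):
    return desk_dataset.feature_matrix()


@pytest.fixture(scope="session")
def tiny_config():
    """A small, fast dataset for I/O and protocol plumbing tests."""
    return GeneratorConfig(grid_shape=(24, 24, 24), n_cases=16, n_concussion=7,
                           seed=7)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return generate_dataset(tiny_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
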