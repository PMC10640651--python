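import numpy as np
import pytest
from hypothesis import settings

# property tests run the same examples everywhere
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from mangalmorph.config import (GridConfig, HydroConfig, RiverConfig,
                                RunConfig, SedimentConfig, VegetationConfig)


@pytest.fixture
def cfg():
    return RunConfig()


@pytest.fixture
def grid_cfg():
    return GridConfig()


@pytest.fixture
def sed_cfg():
    return SedimentConfig()


@pytest.fixture
def veg_cfg():
    return VegetationConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
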