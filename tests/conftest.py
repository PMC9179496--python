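import numpy as np
import pytest
from hypothesis import settings

from adaptherapy import CellPopulationParams

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def default_params():
    return CellPopulationParams()
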