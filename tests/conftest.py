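import numpy as np
import pytest
from hypothesis import settings

from dosegrid.model import ModelSpace, PriorSpec

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def space() -> ModelSpace:
    return ModelSpace(x_min=0.0, x_max=1.0, theta=0.33)


@pytest.fixture
def uniform_prior() -> PriorSpec:
    return PriorSpec()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)
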