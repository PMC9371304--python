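import numpy as np
import pytest

from gliosim.parameters import (ModelParameters, SensorParameters,
                                VesiclePools, default_parameters)


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    return default_parameters()[0]


@pytest.fixture(scope="session")
def sensors() -> SensorParameters:
    return default_parameters()[1]


@pytest.fixture(scope="session")
def pools() -> VesiclePools:
    return default_parameters()[2]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
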