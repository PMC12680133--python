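import numpy as np
import pytest

from dopm.config import ObjectiveSpec, SystemGeometry, default_system


@pytest.fixture(scope="session")
def water_primary() -> ObjectiveSpec:
    return ObjectiveSpec(na=1.2, immersion_index=1.333)


@pytest.fixture(scope="session")
def air_secondary() -> ObjectiveSpec:
    return ObjectiveSpec(na=0.95, immersion_index=1.0, single_pass_transmission=0.9)


@pytest.fixture(scope="session")
def system_35() -> SystemGeometry:
    return default_system(35.0)


@pytest.fixture(scope="session")
def system_45() -> SystemGeometry:
    return default_system(45.0)


@pytest.fixture(scope="session")
def system_0() -> SystemGeometry:
    return default_system(0.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
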