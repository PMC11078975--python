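import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lactokin import (FeedingPattern, InfantSubject, MotherSubject,
                      default_parameters, get_regimen)

settings.register_profile(
    "suite", derandomize=True, max_examples=40, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def feeding():
    return FeedingPattern()


@pytest.fixture(scope="session")
def standard():
    return get_regimen("standard")


@pytest.fixture(scope="session")
def sld():
    return get_regimen("sld")


@pytest.fixture
def typical_mother():
    return MotherSubject(weight=51.0)


@pytest.fixture
def typical_infant():
    return InfantSubject(weight=6.8, age_months=5.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240508)
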