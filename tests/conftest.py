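import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from osmotrap import PhysiologyParams, preset_beverage


@pytest.fixture(scope="session")
def hfcs():
    return preset_beverage("hfcs_softdrink")


@pytest.fixture(scope="session")
def soup():
    return preset_beverage("salty_soup")


@pytest.fixture(scope="session")
def ors():
    return preset_beverage("who_ors")


@pytest.fixture(scope="session")
def sucrose_drink():
    return preset_beverage("sucrose_softdrink")


@pytest.fixture(scope="session")
def params():
    return PhysiologyParams()
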