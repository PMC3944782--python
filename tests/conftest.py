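import pytest
from hypothesis import HealthCheck, settings

import devonto as d

settings.register_profile(
    "suite", derandomize=True, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture
def heart():
    return d.heart_fixture()


@pytest.fixture
def neural():
    return d.neural_ap_fixture()


@pytest.fixture
def swim():
    return d.swim_bladder_fixture()


@pytest.fixture
def series(heart):
    return heart.series()
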