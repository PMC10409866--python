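import numpy as np
import pytest

from ribodecode import CameraModel, FRETMap, REFERENCE_RATES


@pytest.fixture
def cam():
    return CameraModel()


@pytest.fixture
def fmap():
    return FRETMap()


@pytest.fixture
def aaa_rates():
    return REFERENCE_RATES["AAA"]


@pytest.fixture
def m6_rates():
    return REFERENCE_RATES["m6AAA"]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
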