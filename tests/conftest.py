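import numpy as np
import pytest

from cx36mg import VARIANT_PARAMS, get_scheme


@pytest.fixture(scope="session")
def wt():
    return VARIANT_PARAMS["WT"]


@pytest.fixture(scope="session")
def a13k():
    return VARIANT_PARAMS["A13K"]


@pytest.fixture(scope="session")
def h18k():
    return VARIANT_PARAMS["H18K"]


@pytest.fixture(scope="session")
def model5_hill():
    return get_scheme("Model 5, Hill")


@pytest.fixture(scope="session")
def model5():
    return get_scheme("Model 5")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
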