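import numpy as np
import pytest

import corrvim as cv


@pytest.fixture(scope="session")
def ha_model():
    return cv.make_generating_model("HA")


@pytest.fixture(scope="session")
def h0_model():
    return cv.make_generating_model("H0")


@pytest.fixture(scope="session")
def small_ha_dataset(ha_model):
    """One moderate replicate for fast forest/VIM unit tests."""
    return cv.simulate_dataset(ha_model, 400, seed=2718)


CORRELATED = np.array([True] * 4 + [False] * 8)
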