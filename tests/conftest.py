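import numpy as np
import pytest

from ilsim import build_map


@pytest.fixture(scope="session")
def gmap():
    """The standard maize model: 10 x 200 cM, 2000 markers, 100 segments."""
    return build_map()


@pytest.fixture(scope="session")
def toy_map():
    """A small 2-chromosome map: 40 cM, 2 cM spacing, 4 segments of 10 markers."""
    return build_map(2, 40.0, 2.0, 20.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
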