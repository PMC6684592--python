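import numpy as np
import pytest

from glvnet import GLVParams


@pytest.fixture
def eei_params():
    return GLVParams("EEI", a=1.0, b=1.0)


@pytest.fixture
def iii_params():
    return GLVParams("III", a=0.75, b=0.75)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
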