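import numpy as np
import pytest

from spinebase import australopith_preset, giraffe_preset, human_preset


@pytest.fixture(scope="session")
def human():
    return human_preset().params


@pytest.fixture(scope="session")
def giraffe():
    return giraffe_preset().params


@pytest.fixture(scope="session")
def afarensis():
    return australopith_preset("afarensis").params


@pytest.fixture
def rng():
    return np.random.default_rng(42)
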