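import numpy as np
import pytest

from codonlib import GeneticCode
from codonlib.alphabets import uniform20, uniform_early10


@pytest.fixture(scope="session")
def code():
    return GeneticCode.standard()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def target20():
    return uniform20()


@pytest.fixture(scope="session")
def target10():
    return uniform_early10()
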