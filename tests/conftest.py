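import numpy as np
import pytest

from mrcgbsa import build_engine
from mrcgbsa.fixtures import ToySystemSpec, make_toy_complex


@pytest.fixture(scope="session")
def toy_spec():
    return ToySystemSpec()


@pytest.fixture(scope="session")
def toy_complex(toy_spec):
    return make_toy_complex(toy_spec)


@pytest.fixture(scope="session")
def toy_engine(toy_complex):
    return build_engine(toy_complex, eps_in=4.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
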