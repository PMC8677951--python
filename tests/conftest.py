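import numpy as np
import pytest

from hexanlo import chemspace as cs
from hexanlo import evaluators as ev
from hexanlo import nlo_tensor as nt


@pytest.fixture(scope="session")
def fixtures():
    return ev.load_fixtures()


@pytest.fixture(scope="session")
def default_library():
    return cs.default_library()


@pytest.fixture(scope="session")
def a2b2c2():
    return cs.get_pattern("A2B2C2")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_symmetric_tensor(rng, scale=1.0):
    """A random β tensor with intrinsic SHG symmetry enforced."""
    return nt.symmetrize_shg(nt.BetaTensor(rng.normal(0.0, scale, size=(3, 3, 3))))
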