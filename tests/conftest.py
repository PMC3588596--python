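import numpy as np
import pytest

from randinf import AllocationSpec, build_projection
from randinf.projection import DesignMatrixSpec
from randinf.synth import make_study38


@pytest.fixture(scope="session")
def alloc11():
    return AllocationSpec(1, 1)


@pytest.fixture(scope="session")
def alloc21():
    return AllocationSpec(2, 1)


@pytest.fixture(scope="session")
def study38():
    return make_study38(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
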