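import numpy as np
import pytest

from commensim import ColonizerPool, HostState, LifeHistory


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def pool2():
    """Two-taxon pool with focal frequency 0.3."""
    return ColonizerPool(p=np.array([0.3, 0.7]))


@pytest.fixture
def pool1():
    """Single-taxon pool (load dynamics only)."""
    return ColonizerPool(p=np.array([1.0]))


@pytest.fixture
def lh_small():
    return LifeHistory(m=0.01, tau=1e-4, alpha0=1.0, N=1000, H=10)


def make_state(counts, N):
    return HostState(N=N, counts=np.asarray(counts, dtype=np.int64))
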