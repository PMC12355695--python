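import numpy as np
import pytest

from mutcorr.fock_space import CIVector, sector_space


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def random_state(rng, K, na, nb):
    space = sector_space(K, na, nb)
    amps = rng.normal(size=space.dim)
    return CIVector(space, amps / np.linalg.norm(amps))


@pytest.fixture
def random_state_factory(rng):
    def make(K, na, nb):
        return random_state(rng, K, na, nb)

    return make
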