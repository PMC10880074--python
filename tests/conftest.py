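import numpy as np
import pytest

from ecfscan import bundled_pair
from ecfscan.pssm import decode


@pytest.fixture(scope="session")
def pair02():
    return bundled_pair("ecf02")


@pytest.fixture(scope="session")
def pair11():
    return bundled_pair("ecf11")


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return decode(rng.choice(4, size=n, p=p))
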