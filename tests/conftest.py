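import numpy as np
import pytest

from banddp import ERROR_SETS, ScoringScheme


@pytest.fixture(scope="session")
def scoring():
    return ScoringScheme(match=3, mismatch=-1, gap=-2)


@pytest.fixture(scope="session")
def set1():
    return ERROR_SETS[1]


@pytest.fixture(scope="session")
def set2():
    return ERROR_SETS[2]


@pytest.fixture(scope="session")
def set3():
    return ERROR_SETS[3]


@pytest.fixture()
def rng():
    return np.random.default_rng(20240615)


def random_dna(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
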