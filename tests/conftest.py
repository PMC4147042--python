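import numpy as np
import pytest

from mixpower import examples as ex
import mixpower as mp


@pytest.fixture(scope="session")
def hypothetical_model():
    return ex.hypothetical_model()


@pytest.fixture(scope="session")
def dha_model():
    return ex.dha_model()


@pytest.fixture(scope="session")
def parallel():
    return mp.StudyLayout("parallel")


@pytest.fixture(scope="session")
def crossover():
    return mp.StudyLayout("crossover")


@pytest.fixture(scope="session")
def dense_arm():
    return ex.hypothetical_dense_arm()


@pytest.fixture(scope="session")
def sparse_arm():
    return ex.hypothetical_sparse_arm()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
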