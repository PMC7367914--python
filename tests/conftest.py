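import numpy as np
import pytest

from pbpkgsa.drugs import default_fixture
from pbpkgsa.mpbpk import PBPKModel


@pytest.fixture(scope="session")
def quinidine():
    drug, corr = default_fixture("quinidine")
    return drug, corr


@pytest.fixture(scope="session")
def quinidine_model():
    return PBPKModel.from_drug("quinidine")


@pytest.fixture(scope="session")
def alprazolam_model():
    return PBPKModel.from_drug("alprazolam")


@pytest.fixture(scope="session")
def midazolam_model():
    return PBPKModel.from_drug("midazolam")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
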