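import numpy as np
import pytest

import dihedralir as d
from dihedralir import synthdata


@pytest.fixture(scope="session")
def helix_pair():
    return d.make_label_pair_fixture("helix", seed=0)


@pytest.fixture(scope="session")
def sheet_pair():
    return d.make_label_pair_fixture("sheet", seed=0)


@pytest.fixture(scope="session")
def disordered_pair():
    return d.make_label_pair_fixture("disordered", seed=0)


@pytest.fixture(scope="session")
def two_state_data():
    scheme = synthdata.preset_scheme("two-state", noise_sigma=0.01, seed=11)
    return scheme, synthdata.make_kinetics(scheme)


@pytest.fixture(scope="session")
def three_state_data():
    scheme = synthdata.preset_scheme("three-state", noise_sigma=0.01, seed=11)
    return scheme, synthdata.make_kinetics(scheme)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
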