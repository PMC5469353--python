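import numpy as np
import pytest

from rehabsim.session_io import load_cohort, load_joints


@pytest.fixture(scope="session")
def joints():
    return load_joints()


@pytest.fixture(scope="session")
def cohort():
    return load_cohort()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
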