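import numpy as np
import pytest

from rflpmux.assay_config import default_config
from rflpmux.contamination import demo_frequency_table
from rflpmux.simulator import SimParams

#: One fixed seed for every stochastic test in the suite.
SEED = 20260926


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def params():
    return SimParams()


@pytest.fixture(scope="session")
def freqs():
    return demo_frequency_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
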