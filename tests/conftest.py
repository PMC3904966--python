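import numpy as np
import pytest

from intrachain.io import load_et_table, load_reference_relative_d, load_tau_table


@pytest.fixture(scope="session")
def tau_table():
    return load_tau_table()


@pytest.fixture(scope="session")
def et_table():
    return load_et_table()


@pytest.fixture(scope="session")
def reference_d():
    return load_reference_relative_d()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
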