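import warnings

import numpy as np
import pytest

import cortexmap as cm


@pytest.fixture(autouse=True)
def _quiet_degenerate_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="all-zero weight vector")
        warnings.filterwarnings("ignore", message=".*convergence.*")
        yield


@pytest.fixture(scope="session")
def density_table():
    return cm.ips_density_table()


@pytest.fixture(scope="session")
def zscored(density_table):
    return cm.zscore_table(density_table)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
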