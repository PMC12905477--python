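import warnings

import numpy as np
import pytest

from hemovasc.inflow import fit_inflow, synthetic_inflow
from hemovasc.network import BiophysicalParams, fixture_network


@pytest.fixture(autouse=True)
def _quiet():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def base_params():
    return BiophysicalParams()


@pytest.fixture(scope="session")
def inflow_gp():
    t, q = synthetic_inflow(seed=3)
    return fit_inflow(t, q, 1.0)


@pytest.fixture(scope="session")
def single_vessel():
    return fixture_network("single_vessel")


@pytest.fixture(scope="session")
def bifurcation3():
    return fixture_network("bifurcation3")


@pytest.fixture(scope="session")
def nine_vessel():
    return fixture_network("nine_vessel")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250929)
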