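import pytest

from signalnet.cli_io import AGING_PARAMS, TABLE1_FAMILIES
from signalnet.meanfield import solve_activation
from signalnet.rates import make_rates


@pytest.fixture(scope="session")
def constant_rates():
    return make_rates("constant", {"c_lambda": 0.45, "c_mu": 0.65})


@pytest.fixture(scope="session")
def aging_rates():
    return make_rates("gompertz_aging", AGING_PARAMS)


@pytest.fixture(scope="session")
def constant_traj(constant_rates):
    return solve_activation(constant_rates)


@pytest.fixture(scope="session")
def aging_traj(aging_rates):
    return solve_activation(aging_rates)


@pytest.fixture(scope="session")
def all_families():
    """The five reference rate pairs, keyed by family name."""
    return {fam: make_rates(fam, params) for fam, params in TABLE1_FAMILIES}
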