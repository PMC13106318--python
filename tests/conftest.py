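import pytest

from sarcomech.active import ActiveParams
from sarcomech.metrics import load_normal_ranges, load_printed_metric_table
from sarcomech.passive import PassiveParams
from sarcomech.scenarios import build_scenario_table


@pytest.fixture(scope="session")
def passive_params():
    """Verification passive parameter set (packaged defaults)."""
    return PassiveParams()


@pytest.fixture(scope="session")
def active_params():
    """Baseline active parameter set (L_r = 1.85 um, L_0 = 1.58 um)."""
    return ActiveParams()


@pytest.fixture(scope="session")
def printed_table():
    """The packaged 13-scenario reference metric table."""
    return load_printed_metric_table()


@pytest.fixture(scope="session")
def normal_ranges():
    return load_normal_ranges()


@pytest.fixture(scope="session")
def scenario_table():
    return build_scenario_table()
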