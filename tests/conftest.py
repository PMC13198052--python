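import matplotlib

matplotlib.use("Agg")

import pytest

from prehabcea import (
    SimConfig,
    build_analysis_table,
    default_unit_costs,
    simulate_trial,
    toy_valueset,
)


@pytest.fixture(scope="session")
def unit_costs():
    return default_unit_costs()


@pytest.fixture(scope="session")
def valueset():
    return toy_valueset()


@pytest.fixture(scope="session")
def small_records():
    """A small but complete trial: both arms, deaths, dropout."""
    return simulate_trial(SimConfig(n_per_arm=(120, 110), seed=42))


@pytest.fixture(scope="session")
def small_table(small_records, unit_costs, valueset):
    return build_analysis_table(small_records, unit_costs, valueset, winsorised=True)
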