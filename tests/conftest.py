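import numpy as np
import pytest

from n2obudget.agriculture import AgEFSet
from n2obudget.synthetic import (
    ScenarioConfig,
    default_grid,
    generate_activity,
    generate_forcings,
)
from n2obudget.table1 import load_table1_fixture
from n2obudget.taxonomy import RegionRegistry


@pytest.fixture(scope="session")
def registry():
    return RegionRegistry.default()


@pytest.fixture(scope="session")
def ag_efs():
    return AgEFSet()


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def scenario():
    return ScenarioConfig(seed=11)


@pytest.fixture(scope="session")
def activity_tables(scenario):
    return generate_activity(scenario)


@pytest.fixture(scope="session")
def small_grid(scenario):
    return default_grid(scenario, ny=12, nx=12)


@pytest.fixture(scope="session")
def small_forcings(scenario, small_grid):
    return generate_forcings(scenario, small_grid)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
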