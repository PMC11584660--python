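import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from drscreen import (
    LifeTable,
    Scenario,
    kerala_2019_scenario,
    synth_life_table,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def constant_table(q: float, age_min: int = 50, age_max: int = 200) -> LifeTable:
    """Life table with constant qx at every age below the terminal one."""
    ages = np.arange(age_min, age_max + 1)
    qx = np.full(len(ages), q, dtype=float)
    qx[-1] = 1.0
    return LifeTable(ages=ages, qx=qx)


@pytest.fixture(scope="session")
def kerala() -> Scenario:
    return kerala_2019_scenario()


@pytest.fixture(scope="session")
def fixture_lt(kerala) -> LifeTable:
    return synth_life_table(kerala.life_table)
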