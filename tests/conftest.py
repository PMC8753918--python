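import numpy as np
import pandas as pd
import pytest

from triagesim.cohort import CohortSpec, sample_cohort
from triagesim.costs import NhsCostSchedule
from triagesim.parameters import default_parameters
from triagesim.survival import LifeTable


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def life_table():
    return LifeTable.gompertz_makeham(100)


@pytest.fixture(scope="session")
def schedule():
    return NhsCostSchedule.stylised(100)


@pytest.fixture(scope="session")
def cohort_10k():
    return sample_cohort(10_000, CohortSpec(), seed=42)


@pytest.fixture
def flat_life_table():
    """Constant 10% annual mortality up to age 100; handy for closed forms."""
    q = np.full(101, 0.10)
    q[-1] = 1.0
    return LifeTable(q, q)


@pytest.fixture
def flat_schedule():
    """Flat 1000 GBP/year schedule for annuity closed forms."""
    ages = np.arange(101)
    rows = [pd.DataFrame({"age_lo": ages, "age_hi": ages, "sex": s,
                          "annual_cost": 1000.0}) for s in ("female", "male")]
    return NhsCostSchedule(pd.concat(rows, ignore_index=True))
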