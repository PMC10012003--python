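import numpy as np
import pandas as pd
import pytest

import stepcompare as sc


@pytest.fixture
def rng():
    return np.random.default_rng(20250106)


@pytest.fixture(scope="session")
def study2_cohort():
    """One seeded study-2 cohort shared across read-only tests."""
    return sc.simulate_cohort(sc.sim_config(2, seed=42))


@pytest.fixture(scope="session")
def study2_day_table(study2_cohort):
    table, _ = sc.filter_observations(study2_cohort.day_table())
    return table
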