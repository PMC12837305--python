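import numpy as np
import pandas as pd
import pytest

from acthflow.cohort import CohortTable


def make_cohort(records) -> CohortTable:
    """Build a cohort from (id, type, loc, sex, age, event, acth) tuples."""
    df = pd.DataFrame(records, columns=["equid_id", "equid_type", "location",
                                        "sex", "age_years", "event", "acth_pg_ml"])
    return CohortTable(df)


@pytest.fixture
def two_value_hybrid_cohort():
    """The two sparsely sampled hybrid events of the published Table 2
    (May_1-31: {12.6, 16.1}; November_1-15: {22.5, 24.7})."""
    recs = [("H01", "hybrid", "TX", "female", 5.0, "May_1-31", 12.6),
            ("H02", "hybrid", "TX", "male", 7.0, "May_1-31", 16.1),
            ("H01", "hybrid", "TX", "female", 5.0, "November_1-15", 22.5),
            ("H02", "hybrid", "TX", "male", 7.0, "November_1-15", 24.7)]
    return make_cohort(recs)


@pytest.fixture(scope="session")
def default_cohort():
    """One clean study-default synthetic cohort (seed 0)."""
    from acthflow.simulate import generate_cohort, study_default_config
    return generate_cohort(study_default_config(seed=0))


@pytest.fixture(scope="session")
def noise_free_config():
    from acthflow.calendar import PERIOD_EARLY, PERIOD_MID
    from acthflow.simulate import SyntheticConfig
    return SyntheticConfig(sd_id=0.0, sd_month={PERIOD_MID: 0.0, PERIOD_EARLY: 0.0},
                           sd_location=0.0, sd_resid={PERIOD_MID: 0.0, PERIOD_EARLY: 0.0},
                           seed=0)


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
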