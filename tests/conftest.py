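import numpy as np
import pytest

from placebo_enrich import StudyRecord, SyntheticConfig, generate_studies


@pytest.fixture
def high_record():
    """A study with the profile of a high-severity placebo arm."""
    return StudyRecord(
        study_id="high_like",
        n_placebo=100,
        n_abstinent=17,
        duration_months=3.0,
        consumption_mean=130.8,
        consumption_sd=64.5,
        abstinence_days_mean=5.7,
        abstinence_days_sd=3.3,
        pct_male=0.784,
        mean_age=45.4,
    )


@pytest.fixture
def mild_record():
    """A study with the profile of a mild-severity (early-abstainer) arm."""
    return StudyRecord(
        study_id="mild_like",
        n_placebo=115,
        n_abstinent=33,
        duration_months=6.0,
        consumption_mean=155.0,
        consumption_sd=43.9,
        abstinence_days_mean=28.3,
        abstinence_days_sd=16.4,
        pct_male=0.787,
        mean_age=44.4,
    )


@pytest.fixture
def exclusion_zone_record():
    """A study whose mean abstinence duration falls in the 11-17 day zone."""
    return StudyRecord(
        study_id="muller_like",
        n_placebo=28,
        abstinence_rate=0.143,
        duration_months=4.0,
        consumption_mean=120.0,
        consumption_sd=55.0,
        abstinence_days_mean=12.5,
        abstinence_days_sd=4.0,
        pct_male=0.8,
    )


@pytest.fixture
def synthetic_table():
    """Default 19-study synthetic table with its truth table (fixed seed)."""
    return generate_studies(SyntheticConfig(seed=20240917))
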