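import numpy as np
import pandas as pd
import pytest

from heightcurve import studies, synthetic
from heightcurve.model import CohortGrid


@pytest.fixture(scope="session")
def small_world():
    """A 12-country synthetic world shared by read-only tests."""
    truth, obs = synthetic.simulate_world(
        n_countries=12, n_regions=4, n_super_regions=2, seed=42
    )
    retained, _ = studies.filter_analysis_set(obs)
    return truth, retained


@pytest.fixture
def tiny_hierarchy():
    return studies.CountryIndex(
        countries=("AA", "BB"),
        region_of={"AA": "R0", "BB": "R0"},
        super_region_of={"R0": "S0"},
    )


def make_obs(rows):
    """Observation table from (study, country, sex, coverage, year, age_group,
    mean, se, n, measured) tuples."""
    df = pd.DataFrame(
        rows,
        columns=[
            "study_id",
            "country",
            "sex",
            "coverage",
            "survey_year",
            "age_group",
            "mean_cm",
            "se_cm",
            "n",
            "measured",
        ],
    )
    df["scope"] = "mixed"
    return df[list(studies.OBSERVATION_COLUMNS)]


@pytest.fixture
def obs_factory():
    return make_obs
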