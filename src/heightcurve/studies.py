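"""Study-level data model and deterministic preparation rules.

Observations are study x sex x age-group summaries of measured adult
height.  This module holds the standard age-group vocabulary, the
birth-cohort arithmetic (survey year minus mid-age of the age group), the
analysis-set inclusion filters, advisory duplicate flagging, and the
classification of countries into data-availability strata used to stratify
holdout validation.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Standard age groups: single years 18 and 19, then decades, open-ended 80+.
STANDARD_AGE_GROUPS = (
    "18",
    "19",
    "20-29",
    "30-39",
    "40-49",
    "50-59",
    "60-69",
    "70-79",
    "80+",
)

#: Mid-age convention for the open-ended oldest group (symmetric 80-90 band).
OPEN_ENDED_MID_AGE = 85.0

COHORT_MIN = 1896
COHORT_MAX = 1996

OBSERVATION_COLUMNS = (
    "study_id",
    "country",
    "sex",
    "coverage",
    "scope",
    "survey_year",
    "age_group",
    "mean_cm",
    "se_cm",
    "n",
    "measured",
)

SEXES = ("male", "female")
COVERAGE_LEVELS = ("national", "subnational", "community")


def _normalize_age_group(age_group: str) -> str:
    """Map unicode dash variants onto the canonical hyphenated labels."""
    return str(age_group).strip().replace("–", "-").replace("—", "-")


def mid_age(age_group: str, open_ended: float = OPEN_ENDED_MID_AGE) -> float:
    """Midpoint in years of a standard age group.

    Single-year groups return the year itself; decade groups the midpoint of
    the closed integer range (e.g. ``"20-29"`` -> 24.5); the open-ended
    ``"80+"`` group returns the configurable convention (default 85.0).
    """
    label = _normalize_age_group(age_group)
    if label not in STANDARD_AGE_GROUPS:
        raise ValueError(f"unknown age group label: {age_group!r}")
    if label == "80+":
        return float(open_ended)
    if "-" in label:
        lo, hi = label.split("-")
        return (int(lo) + int(hi)) / 2.0
    return float(int(label))


def birth_cohort(survey_year: float, age_group: str) -> float:
    """Birth cohort of an observation: survey year minus mid-age.

    Decade age groups have half-integer mid-ages, so cohorts may be
    half-integers (e.g. survey year 2000, ages 20-29 -> cohort 1975.5).
    """
    return float(survey_year) - mid_age(age_group)


@dataclasses.dataclass(frozen=True)
class CountryIndex:
    """Country -> region -> super-region nesting used for partial pooling."""

    countries: tuple[str, ...]
    region_of: Mapping[str, str]
    super_region_of: Mapping[str, str]

    def __post_init__(self) -> None:
        for c in self.countries:
            if c not in self.region_of:
                raise ValueError(f"country {c!r} has no region")
        for r in set(self.region_of.values()):
            if r not in self.super_region_of:
                raise ValueError(f"region {r!r} has no super-region")

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.region_of.values())))

    @property
    def super_regions(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.super_region_of.values())))

    def indices(self) -> tuple[dict, dict, dict]:
        """Integer codes for countries, regions and super-regions."""
        ci = {c: i for i, c in enumerate(self.countries)}
        ri = {r: i for i, r in enumerate(self.regions)}
        gi = {g: i for i, g in enumerate(self.super_regions)}
        return ci, ri, gi


@dataclasses.dataclass(frozen=True)
class CohortSeries:
    """Distinct birth cohorts with data for one country and sex."""

    country: str
    sex: str
    cohorts_observed: frozenset

    @property
    def n_cohorts(self) -> int:
        return len(self.cohorts_observed)

    @property
    def n_after_1960(self) -> int:
        return sum(1 for t in self.cohorts_observed if t > 1960)


def validate_observations(df: pd.DataFrame) -> None:
    """Check schema and basic invariants of an observation table."""
    missing = [c for c in OBSERVATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"observation table missing columns: {missing}")
    if len(df) == 0:
        return
    bad_sex = set(df["sex"]) - set(SEXES)
    if bad_sex:
        raise ValueError(f"unknown sex values: {sorted(bad_sex)}")
    bad_cov = set(df["coverage"]) - set(COVERAGE_LEVELS)
    if bad_cov:
        raise ValueError(f"unknown coverage values: {sorted(bad_cov)}")
    labels = df["age_group"].map(_normalize_age_group)
    bad_ag = set(labels) - set(STANDARD_AGE_GROUPS)
    if bad_ag:
        raise ValueError(f"unknown age groups: {sorted(bad_ag)}")
    if (df["se_cm"] <= 0).any():
        raise ValueError("se_cm must be positive")
    if (df["n"] < 1).any():
        raise ValueError("n must be >= 1")
    if ((df["mean_cm"] <= 100) | (df["mean_cm"] >= 220)).any():
        raise ValueError("mean_cm outside plausible range (100, 220)")


def load_observations(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"study_id": str, "country": str})
    df["measured"] = df["measured"].astype(bool)
    validate_observations(df)
    return df


def write_observations(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=list(OBSERVATION_COLUMNS))


def filter_analysis_set(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the analysis-set inclusion rules.

    Retains observations that are measured (not self-reported), have
    mid-age >= 18, and a birth cohort in [1896, 1996].  No observation is
    excluded based on its height level.  Returns the retained table plus an
    exclusion log with one reason per dropped row (columns
    ``study_id, row, reason``); the first matching reason wins.
    """
    if len(df) == 0:
        empty_log = pd.DataFrame(columns=["study_id", "row", "reason"])
        return df.copy(), empty_log
    labels = df["age_group"].map(_normalize_age_group)
    mids = labels.map(mid_age)
    cohorts = df["survey_year"].astype(float) - mids
    reasons = pd.Series("", index=df.index, dtype=object)
    reasons[cohorts > COHORT_MAX] = f"cohort after {COHORT_MAX}"
    reasons[cohorts < COHORT_MIN] = f"cohort before {COHORT_MIN}"
    reasons[mids < 18] = "mid-age below 18"
    reasons[~df["measured"].astype(bool)] = "self-reported"
    drop = reasons != ""
    log = pd.DataFrame(
        {
            "study_id": df.loc[drop, "study_id"].astype(str).to_numpy(),
            "row": df.index[drop].to_numpy(),
            "reason": reasons[drop].to_numpy(),
        }
    )
    retained = df.loc[~drop].copy()
    retained["mid_age"] = mids[~drop]
    retained["birth_cohort"] = cohorts[~drop]
    return retained, log


def flag_duplicates(sources: pd.DataFrame) -> list[pd.DataFrame]:
    """Group sources sharing (country, survey_year) as duplicate candidates.

    Flagging is advisory: groups of size >= 2 are returned for review,
    nothing is deleted.  ``sources`` needs one row per study with at least
    ``study_id, country, survey_year`` columns.
    """
    uniq = sources.drop_duplicates(subset=["study_id", "country", "survey_year"])
    groups = []
    for _, grp in uniq.groupby(["country", "survey_year"], sort=True):
        if grp["study_id"].nunique() >= 2:
            groups.append(grp.copy())
    return groups


def classify_data_availability(series: CohortSeries, sex: str | None = None) -> str:
    """Assign a country x sex to a data-availability stratum.

    data_rich: more than 25 cohorts with at least five cohorts after 1960.
    data_poor: up to and including 12 cohorts (women) / 8 cohorts (men).
    average:   13-25 cohorts (women), 9-25 (men), or more than 25 cohorts
               with fewer than five after 1960.
    """
    sex = sex or series.sex
    if sex not in SEXES:
        raise ValueError(f"unknown sex: {sex!r}")
    n = series.n_cohorts
    late = series.n_after_1960
    if n > 25:
        return "data_rich" if late >= 5 else "average"
    poor_max = 12 if sex == "female" else 8
    return "data_poor" if n <= poor_max else "average"


def cohort_series(df: pd.DataFrame) -> list[CohortSeries]:
    """Distinct observed cohorts per (country, sex) from a retained analysis set."""
    if "birth_cohort" not in df.columns:
        df, _ = filter_analysis_set(df)
    out = []
    for (country, sex), grp in df.groupby(["country", "sex"], sort=True):
        out.append(
            CohortSeries(
                country=country,
                sex=sex,
                cohorts_observed=frozenset(grp["birth_cohort"].tolist()),
            )
        )
    return out


def availability_table(df: pd.DataFrame) -> pd.DataFrame:
    """Data-availability stratum per (country, sex) with cohort counts."""
    rows = []
    for s in cohort_series(df):
        rows.append(
            {
                "country": s.country,
                "sex": s.sex,
                "n_cohorts": s.n_cohorts,
                "n_after_1960": s.n_after_1960,
                "stratum": classify_data_availability(s),
            }
        )
    return pd.DataFrame(rows, columns=["country", "sex", "n_cohorts", "n_after_1960", "stratum"])
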