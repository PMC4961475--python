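"""Synthetic country hierarchies, truth surfaces and survey databases.

The generator mirrors the generative structure the estimation model
assumes: a world line in birth cohort plus hierarchical intercept/slope
deviations (super-region, region, country), constrained RW2 non-linear
components at every level, a linear age-drift term, systematic offsets and
extra variance for non-nationally-representative sources, and sampling
error implied by the within-population SD of height and the cell sample
size.  It exists so fitting and validation can be exercised end-to-end with
no access to the real (non-public) survey database.

Default magnitudes emulate the composition of the real database: a
54/14/32 national/subnational/community mix, a right-skewed number of
sources per country, cross-country spread of roughly 20 cm, century gains
of 0-20 cm, and age-drift slopes of -0.2 (men) and -0.3 (women) cm per
decade of age.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from heightcurve.studies import (
    STANDARD_AGE_GROUPS,
    SEXES,
    CountryIndex,
    mid_age,
)
from heightcurve.model import CohortGrid, constrain_rw2


def make_hierarchy(
    n_countries: int, n_regions: int, n_super_regions: int, seed: int
) -> CountryIndex:
    """Random balanced-as-possible country -> region -> super-region nesting."""
    if not (n_countries >= n_regions >= n_super_regions >= 1):
        raise ValueError("need n_countries >= n_regions >= n_super_regions >= 1")
    rng = np.random.default_rng(seed)
    countries = tuple(f"C{i:03d}" for i in range(n_countries))
    regions = [f"R{i:02d}" for i in range(n_regions)]
    sregs = [f"SR{i:d}" for i in range(n_super_regions)]
    # Balanced assignment: cycle units through parents, then shuffle membership.
    c_perm = rng.permutation(n_countries)
    region_of = {countries[c_perm[i]]: regions[i % n_regions] for i in range(n_countries)}
    r_perm = rng.permutation(n_regions)
    super_region_of = {regions[r_perm[i]]: sregs[i % n_super_regions] for i in range(n_regions)}
    return CountryIndex(countries=countries, region_of=region_of, super_region_of=super_region_of)


@dataclasses.dataclass
class TruthParams:
    """Generative magnitudes for the synthetic truth surface.

    Hierarchical SDs are in cm (intercepts), cm/yr (slopes); RW2
    amplitudes are the root-mean-square size (cm) of the constrained
    non-linear component per unit at each level.
    """

    world_intercept: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"male": 168.0, "female": 156.0}
    )
    world_slope: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"male": 0.09, "female": 0.08}
    )
    sd_alpha: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"super_region": 4.5, "region": 2.0, "country": 0.6}
    )
    sd_beta: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"super_region": 0.05, "region": 0.02, "country": 0.004}
    )
    rw2_amplitude: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"world": 1.5, "super_region": 0.8, "region": 0.4, "country": 0.25}
    )
    age_slope: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"male": -0.02, "female": -0.03}
    )
    bias_sd_subnational: float = 1.0
    bias_sd_community: float = 1.5
    extra_sd_subnational: float = 0.5
    extra_sd_community: float = 1.0


@dataclasses.dataclass
class TruthSurface:
    """Ground-truth mean height at age 18 per country x cohort, by sex."""

    hierarchy: CountryIndex
    cohort_grid: np.ndarray  # integer cohort years
    height18: Mapping[str, np.ndarray]  # sex -> (n_countries, n_cohorts)
    age_slope: Mapping[str, float]
    bias_sd_subnational: float
    bias_sd_community: float
    extra_sd_subnational: float
    extra_sd_community: float

    def height_at(self, sex: str, country: str, cohort: float) -> float:
        ci = self.hierarchy.countries.index(country)
        return float(np.interp(cohort, self.cohort_grid, self.height18[sex][ci]))

    def bias_sd(self, coverage: str) -> float:
        return {
            "national": 0.0,
            "subnational": self.bias_sd_subnational,
            "community": self.bias_sd_community,
        }[coverage]

    def extra_sd(self, coverage: str) -> float:
        return {
            "national": 0.0,
            "subnational": self.extra_sd_subnational,
            "community": self.extra_sd_community,
        }[coverage]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sex in SEXES:
            h = self.height18[sex]
            for ci, country in enumerate(self.hierarchy.countries):
                for tj, t in enumerate(self.cohort_grid):
                    rows.append((country, sex, float(t), float(h[ci, tj])))
        return pd.DataFrame(rows, columns=["country", "sex", "cohort", "height18_cm"])


def _rw2_unit_scale(size: int) -> float:
    """RMS of a constrained RW2 draw with unit innovation SD.

    A draw integrates iid N(0,1) second differences twice and is then
    projected onto the doubly-constrained subspace; the factor is the
    square root of trace(P B B' P)/size for the integration matrix B.
    """
    B = np.zeros((size, size - 2))
    for k in range(2, size):
        B[k] = 2.0 * B[k - 1] - B[k - 2]
        B[k, k - 2] += 1.0
    A = np.vstack([np.ones(size), np.arange(size) - (size - 1) / 2.0])
    P = np.eye(size) - A.T @ np.linalg.solve(A @ A.T, A)
    M = P @ B
    return float(np.sqrt((M**2).sum() / size))


def draw_constrained_rw2(size: int, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Constrained RW2 draw scaled so its marginal RMS is ~amplitude."""
    if amplitude == 0.0:
        return np.zeros(size)
    s = amplitude / _rw2_unit_scale(size)
    d = rng.normal(0.0, s, size - 2)
    u = np.zeros(size)
    for k in range(2, size):
        u[k] = 2.0 * u[k - 1] - u[k - 2] + d[k - 2]
    return constrain_rw2(u)


def simulate_truth(
    hierarchy: CountryIndex,
    params: TruthParams | None = None,
    seed: int = 0,
    grid: CohortGrid | None = None,
) -> TruthSurface:
    """Draw a ground-truth height surface from the hierarchical model."""
    params = params or TruthParams()
    grid = grid or CohortGrid()
    rng = np.random.default_rng(seed)
    years = grid.years
    T = years.size
    ci, ri, gi = hierarchy.indices()
    height18: dict[str, np.ndarray] = {}
    for sex in SEXES:
        a_g = {g: rng.normal(0.0, params.sd_alpha["super_region"]) for g in hierarchy.super_regions}
        a_r = {r: rng.normal(0.0, params.sd_alpha["region"]) for r in hierarchy.regions}
        a_c = {c: rng.normal(0.0, params.sd_alpha["country"]) for c in hierarchy.countries}
        b_g = {g: rng.normal(0.0, params.sd_beta["super_region"]) for g in hierarchy.super_regions}
        b_r = {r: rng.normal(0.0, params.sd_beta["region"]) for r in hierarchy.regions}
        b_c = {c: rng.normal(0.0, params.sd_beta["country"]) for c in hierarchy.countries}
        u_w = draw_constrained_rw2(T, params.rw2_amplitude["world"], rng)
        u_g = {
            g: draw_constrained_rw2(T, params.rw2_amplitude["super_region"], rng)
            for g in hierarchy.super_regions
        }
        u_r = {
            r: draw_constrained_rw2(T, params.rw2_amplitude["region"], rng)
            for r in hierarchy.regions
        }
        u_c = {
            c: draw_constrained_rw2(T, params.rw2_amplitude["country"], rng)
            for c in hierarchy.countries
        }
        h = np.empty((len(hierarchy.countries), T))
        dt = years - grid.t0
        for c in hierarchy.countries:
            r = hierarchy.region_of[c]
            g = hierarchy.super_region_of[r]
            a = params.world_intercept[sex] + a_g[g] + a_r[r] + a_c[c]
            b = params.world_slope[sex] + b_g[g] + b_r[r] + b_c[c]
            h[ci[c]] = a + b * dt + u_w + u_g[g] + u_r[r] + u_c[c]
        height18[sex] = h
    return TruthSurface(
        hierarchy=hierarchy,
        cohort_grid=years,
        height18=height18,
        age_slope=dict(params.age_slope),
        bias_sd_subnational=params.bias_sd_subnational,
        bias_sd_community=params.bias_sd_community,
        extra_sd_subnational=params.extra_sd_subnational,
        extra_sd_community=params.extra_sd_community,
    )


@dataclasses.dataclass
class SurveyDesign:
    """Composition of the synthetic survey database.

    studies_per_country is a (lo, hi) range sampled log-uniformly (the real
    database is right-skewed: from ~2 to ~34 sources per country across
    regions).  Each study measures a contiguous window of the standard age
    groups, covers both sexes or one, and draws a per-cell sample size from
    a clipped log-normal.  within_sd_cm is the within-age-group SD of
    individual heights that sets sampling error se = within_sd/sqrt(n).
    """

    studies_per_country: tuple[int, int] = (3, 30)
    coverage_probs: tuple[float, float, float] = (0.54, 0.14, 0.32)
    year_range: tuple[int, int] = (1950, 2015)
    age_groups: Sequence[str] = STANDARD_AGE_GROUPS
    age_window: tuple[int, int] = (2, 6)
    n_per_cell_median: float = 200.0
    n_per_cell_log_sd: float = 0.7
    n_per_cell_range: tuple[int, int] = (25, 2000)
    within_sd_cm: float = 7.0
    sex_probs: tuple[float, float, float] = (0.75, 0.10, 0.15)  # both, male-only, female-only

    def __post_init__(self) -> None:
        if abs(sum(self.coverage_probs) - 1.0) > 1e-9:
            raise ValueError("coverage_probs must sum to 1")


def _sample_log_uniform_int(rng: np.random.Generator, lo: int, hi: int) -> int:
    ks = np.arange(lo, hi + 1)
    w = 1.0 / ks
    return int(rng.choice(ks, p=w / w.sum()))


def simulate_studies(
    truth: TruthSurface,
    design: SurveyDesign | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a synthetic observation table from a truth surface.

    For each study: a coverage level, a survey year, an age-group window
    and a sex composition; non-national studies get a per-sex systematic
    offset ~ N(0, bias_sd^2).  Each emitted cell observes

        mean = truth(cohort) + age_slope*(mid_age - 18) + offset
               + N(0, se^2 + extra_sd^2),   se = within_sd/sqrt(n).

    Cells whose birth cohort falls outside the truth grid are not emitted.
    Byte-identical tables for identical seeds.
    """
    design = design or SurveyDesign()
    rng = np.random.default_rng(seed)
    t_lo, t_hi = float(truth.cohort_grid[0]), float(truth.cohort_grid[-1])
    groups = [str(g) for g in design.age_groups]
    rows = []
    for country in truth.hierarchy.countries:
        n_studies = _sample_log_uniform_int(rng, *design.studies_per_country)
        for k in range(n_studies):
            study_id = f"{country}-S{k:03d}"
            coverage = ("national", "subnational", "community")[
                rng.choice(3, p=design.coverage_probs)
            ]
            scope = ("mixed", "urban", "rural")[rng.choice(3, p=[0.6, 0.25, 0.15])]
            year = int(rng.integers(design.year_range[0], design.year_range[1] + 1))
            w_lo, w_hi = design.age_window
            width = int(rng.integers(w_lo, w_hi + 1))
            start = int(rng.integers(0, max(1, len(groups) - width + 1)))
            window = groups[start : start + width]
            sex_kind = rng.choice(3, p=design.sex_probs)
            sexes = {0: ("male", "female"), 1: ("male",), 2: ("female",)}[sex_kind]
            bias_sd = truth.bias_sd(coverage)
            extra_sd = truth.extra_sd(coverage)
            for sex in sexes:
                offset = rng.normal(0.0, bias_sd) if bias_sd > 0 else 0.0
                for ag in window:
                    ma = mid_age(ag)
                    cohort = year - ma
                    if cohort < t_lo or cohort > t_hi:
                        continue
                    n = int(
                        np.clip(
                            np.round(
                                rng.lognormal(
                                    np.log(design.n_per_cell_median), design.n_per_cell_log_sd
                                )
                            ),
                            *design.n_per_cell_range,
                        )
                    )
                    se = design.within_sd_cm / np.sqrt(n)
                    mu = (
                        truth.height_at(sex, country, cohort)
                        + truth.age_slope[sex] * (ma - 18.0)
                        + offset
                    )
                    y = mu + rng.normal(0.0, np.sqrt(se**2 + extra_sd**2))
                    rows.append(
                        (
                            study_id,
                            country,
                            sex,
                            coverage,
                            scope,
                            year,
                            ag,
                            round(float(y), 4),
                            max(round(float(se), 6), 1e-6),
                            n,
                            True,
                        )
                    )
    return pd.DataFrame(
        rows,
        columns=[
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
        ],
    )


def simulate_world(
    n_countries: int = 60,
    n_regions: int = 12,
    n_super_regions: int = 4,
    seed: int = 0,
    truth_params: TruthParams | None = None,
    design: SurveyDesign | None = None,
    grid: CohortGrid | None = None,
) -> tuple[TruthSurface, pd.DataFrame]:
    """Hierarchy + truth surface + observation table in one call.

    Sub-seeds for the three stages are derived from ``seed`` so the stages
    are independently reproducible.
    """
    ss = np.random.SeedSequence(seed).spawn(3)
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    hierarchy = make_hierarchy(n_countries, n_regions, n_super_regions, sub[0])
    truth = simulate_truth(hierarchy, truth_params, sub[1], grid=grid)
    obs = simulate_studies(truth, design, sub[2])
    return truth, obs
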