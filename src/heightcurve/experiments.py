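"""Canned end-to-end experiments at desk scale.

These wire the full pipeline together at sizes that run on a single CPU
in minutes: a synthetic world of 60 countries in 12 regions and 4
super-regions, a cohort grid thinned to every second year, and short
chains (2 chains x 1500 retained draws after 500 burn-in).  The holdout
experiment is the package's replication, on its own synthetic data, of
the stratified 10%-of-countries external validation protocol.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from heightcurve import studies, synthetic, validation
from heightcurve.model import CohortGrid, ModelConfig
from heightcurve.inference import MCMCConfig


@dataclasses.dataclass
class HoldoutExperimentResult:
    report: validation.HoldoutReport
    availability: object
    min_subset_coverage_pct: float  # min over stratum x sex subsets
    max_abs_median_error_cm: float  # max over stratum x sex x rep subsets
    max_median_abs_error_cm: float  # max over stratum x sex subsets
    pooled: object


def run_scaled_holdout(
    seed: int = 1,
    n_countries: int = 60,
    n_regions: int = 12,
    n_super_regions: int = 4,
    fraction: float = 0.10,
    n_reps: int = 5,
    n_chains: int = 2,
    n_burnin: int = 500,
    n_samples: int = 1500,
    grid_step: int = 2,
    progress: bool = False,
) -> HoldoutExperimentResult:
    """Stratified holdout validation on a synthetic world.

    Generates the world, classifies countries into data-availability
    strata, withholds ~10% of countries per stratum and sex in each of
    five repetitions, refits, and scores predictions of the withheld
    observations.  Summary numbers: the minimum 95%-interval coverage
    across stratum x sex subsets, the maximum absolute median error
    across stratum x sex x repetition subsets, and the maximum median
    absolute error across stratum x sex subsets.
    """
    ss = np.random.SeedSequence(seed).spawn(3)
    world_seed, plan_seed, fit_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss)
    grid = CohortGrid(step=grid_step)
    truth, obs = synthetic.simulate_world(
        n_countries, n_regions, n_super_regions, seed=world_seed, grid=CohortGrid()
    )
    retained, _ = studies.filter_analysis_set(obs)
    availability = studies.availability_table(retained)
    plan = validation.make_holdout_plan(
        availability, fraction=fraction, n_reps=n_reps, seed=plan_seed
    )
    mcmc = MCMCConfig(
        n_chains=n_chains, n_burnin=n_burnin, n_samples=n_samples, seed=fit_seed
    )
    report = validation.run_holdout(
        retained,
        truth.hierarchy,
        plan,
        model_config=ModelConfig(grid=grid),
        mcmc=mcmc,
        mode="observation",
        progress=progress,
    )
    by_subset = report.subsets(("stratum", "sex"))
    by_rep = report.subsets(("stratum", "sex", "rep"))
    return HoldoutExperimentResult(
        report=report,
        availability=availability,
        min_subset_coverage_pct=float(by_subset["coverage_pct"].min()),
        max_abs_median_error_cm=float(by_rep["median_error"].abs().max()),
        max_median_abs_error_cm=float(by_subset["median_abs_error"].max()),
        pooled=report.pooled(),
    )
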