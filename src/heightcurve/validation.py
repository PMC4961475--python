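"""External validation: stratified country holdout and error/coverage metrics.

The protocol removes all data from ~10% of countries with data (creating
the appearance of no-data countries), refits on the remaining 90%, and
predicts the held-out observations.  Held-out countries are sampled within
data-availability strata (data_rich / data_poor / average), separately by
sex, and the test is repeated (default five times) with different subsets.
Reported metrics per subset: median error, 25th/75th percentile errors,
median absolute error, and the percentage of held-out values inside the
95% credible intervals.  Quantiles use linear interpolation between order
statistics.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from heightcurve.studies import SEXES, CountryIndex, filter_analysis_set
from heightcurve.model import ModelConfig
from heightcurve.inference import MCMCConfig, fit, predict_observations

STRATA = ("data_rich", "data_poor", "average")


@dataclasses.dataclass
class HoldoutPlan:
    """Stratified holdout assignments: one row per (rep, sex, country)."""

    assignments: pd.DataFrame  # columns: rep, sex, stratum, country
    fraction: float
    seed: int

    @property
    def n_reps(self) -> int:
        return int(self.assignments["rep"].max()) + 1

    def held_out(self, rep: int, sex: str) -> list[str]:
        a = self.assignments
        return a.loc[(a["rep"] == rep) & (a["sex"] == sex), "country"].tolist()


def make_holdout_plan(
    availability: pd.DataFrame,
    fraction: float = 0.10,
    n_reps: int = 5,
    seed: int = 0,
) -> HoldoutPlan:
    """Sample held-out countries within each stratum x sex, per repetition.

    ``availability`` is the per-(country, sex) stratum table from
    :func:`heightcurve.studies.availability_table`.  Within each stratum
    roughly ``fraction`` of its countries are withheld (at least one when
    the stratum is non-empty); a stratum smaller than its quota is used
    whole, with a warning.  Deterministic given ``seed``; repetitions use
    independent sub-streams so they differ.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_reps):
        for sex in SEXES:
            sub = availability[availability["sex"] == sex]
            for stratum in STRATA:
                pool = sorted(sub.loc[sub["stratum"] == stratum, "country"])
                if not pool:
                    continue
                quota = max(1, int(round(fraction * len(pool))))
                if quota > len(pool):
                    warnings.warn(
                        f"stratum {stratum}/{sex} smaller than its quota; holding out all"
                    )
                    quota = len(pool)
                picked = rng.choice(pool, size=quota, replace=False)
                for c in sorted(picked):
                    rows.append((rep, sex, stratum, c))
    return HoldoutPlan(
        assignments=pd.DataFrame(rows, columns=["rep", "sex", "stratum", "country"]),
        fraction=fraction,
        seed=seed,
    )


def coverage(lo, hi, values) -> float:
    """Percentage of values inside their closed intervals [lo, hi]."""
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    values = np.asarray(values, dtype=float)
    if not (lo.shape == hi.shape == values.shape):
        raise ValueError("lo, hi and values must have equal lengths")
    if (lo > hi).any():
        raise ValueError("interval with lo > hi")
    inside = (values >= lo) & (values <= hi)
    return float(100.0 * inside.mean())


def _error_summary(grp: pd.DataFrame) -> dict:
    e = grp["error"].to_numpy()
    return {
        "n_obs": len(grp),
        "n_countries": grp["country"].nunique(),
        "median_error": float(np.median(e)),
        "q25_error": float(np.percentile(e, 25)),
        "q75_error": float(np.percentile(e, 75)),
        "median_abs_error": float(np.median(np.abs(e))),
        "coverage_pct": float(100.0 * grp["covered"].mean()),
    }


@dataclasses.dataclass
class HoldoutReport:
    """Row-level errors plus per-subset and pooled summaries."""

    errors: pd.DataFrame  # rep, sex, stratum, country, observed, est, lo, hi, error, covered
    plan: HoldoutPlan

    def subsets(self, by: Sequence[str] = ("stratum", "sex")) -> pd.DataFrame:
        """Metrics per subset (default stratum x sex, pooled over reps)."""
        rows = []
        for key, grp in self.errors.groupby(list(by), sort=True):
            key = key if isinstance(key, tuple) else (key,)
            rows.append({**dict(zip(by, key)), **_error_summary(grp)})
        return pd.DataFrame(rows)

    def pooled(self) -> pd.Series:
        return pd.Series(_error_summary(self.errors))


def run_holdout(
    observations: pd.DataFrame,
    hierarchy: CountryIndex,
    plan: HoldoutPlan,
    model_config: ModelConfig | None = None,
    mcmc: MCMCConfig | None = None,
    mode: str = "observation",
    truth=None,
    progress: bool = False,
) -> HoldoutReport:
    """Run the holdout experiment: refit per repetition, predict withheld data.

    Errors are estimate minus held-out *observed* mean (the protocol's
    definition); pass a TruthSurface via ``truth`` to score against the
    synthetic ground truth instead (simulation studies).  Coverage uses
    observation-level intervals in ``observation`` mode (study-offset and
    residual variance included), population-level intervals otherwise.
    Each (repetition, sex) fit gets an independent seed sub-stream derived
    from ``mcmc.seed``.
    """
    model_config = model_config or ModelConfig()
    mcmc = mcmc or MCMCConfig()
    if "birth_cohort" not in observations.columns:
        observations, _ = filter_analysis_set(observations)
    strat = plan.assignments.set_index(["rep", "sex", "country"])["stratum"]
    ss = np.random.SeedSequence(mcmc.seed)
    n_tasks = plan.n_reps * len(SEXES)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2 * n_tasks)]
    out = []
    task = 0
    for rep in range(plan.n_reps):
        for sex in SEXES:
            held = set(plan.held_out(rep, sex))
            sex_obs = observations[observations["sex"] == sex]
            train = sex_obs[~sex_obs["country"].isin(held)]
            test = sex_obs[sex_obs["country"].isin(held)]
            fit_seed, pred_seed = seeds[2 * task], seeds[2 * task + 1]
            task += 1
            if len(test) == 0:
                continue
            if progress:
                print(f"[holdout] rep {rep} sex {sex}: fitting {len(train)} rows, "
                      f"predicting {len(test)} rows from {len(held)} countries")
            rep_mcmc = dataclasses.replace(mcmc, seed=fit_seed)
            draws = fit(train, hierarchy, model_config, rep_mcmc, check=False)
            pred = predict_observations(
                draws, test, rng=np.random.default_rng(pred_seed), mode=mode
            )
            if truth is not None:
                target = np.array(
                    [
                        truth.height_at(sex, r.country, r.birth_cohort)
                        + truth.age_slope[sex] * (r.mid_age - 18.0)
                        for r in pred.itertuples()
                    ]
                )
            else:
                target = pred["mean_cm"].to_numpy(dtype=float)
            err = pred["est_cm"].to_numpy() - target
            covered = (target >= pred["lo_cm"].to_numpy()) & (target <= pred["hi_cm"].to_numpy())
            out.append(
                pd.DataFrame(
                    {
                        "rep": rep,
                        "sex": sex,
                        "country": pred["country"].to_numpy(),
                        "stratum": [
                            strat.loc[(rep, sex, c)] for c in pred["country"]
                        ],
                        "observed": target,
                        "est": pred["est_cm"].to_numpy(),
                        "lo": pred["lo_cm"].to_numpy(),
                        "hi": pred["hi_cm"].to_numpy(),
                        "error": err,
                        "covered": covered,
                    }
                )
            )
    if not out:
        raise ValueError("holdout plan selected no observations")
    return HoldoutReport(errors=pd.concat(out, ignore_index=True), plan=plan)
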