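"""Sampler behaviour: determinism, diagnostics, summaries, pooling."""

import numpy as np
import pandas as pd
import pytest

from heightcurve import studies, synthetic
from heightcurve.model import CohortGrid, ModelConfig
from heightcurve.inference import (
    MCMCConfig,
    check_convergence,
    fit,
    psrf,
    summarize,
)

SMALL_CFG = ModelConfig(grid=CohortGrid(step=5))


def _small_dataset(seed=0, n_countries=6):
    truth, obs = synthetic.simulate_world(
        n_countries=n_countries, n_regions=2, n_super_regions=1, seed=seed
    )
    retained, _ = studies.filter_analysis_set(obs)
    return truth, retained[retained["sex"] == "male"]


class TestFitContracts:
    def test_same_seed_identical_draws(self):
        _, male = _small_dataset()
        mc = MCMCConfig(n_chains=2, n_burnin=20, n_samples=30, seed=5)
        a = fit(male, _small_dataset()[0].hierarchy, SMALL_CFG, mc, check=False)
        b = fit(male, _small_dataset()[0].hierarchy, SMALL_CFG, mc, check=False)
        np.testing.assert_array_equal(a.lin, b.lin)
        np.testing.assert_array_equal(a.gamma, b.gamma)
        np.testing.assert_array_equal(a.hyper, b.hyper)

    def test_empty_data_rejected(self, tiny_hierarchy):
        empty = pd.DataFrame(columns=studies.OBSERVATION_COLUMNS)
        with pytest.raises(ValueError):
            fit(empty, tiny_hierarchy)

    def test_mixed_sex_rejected(self):
        truth, retained = _small_dataset()[0], None
        truth, full = synthetic.simulate_world(4, 2, 1, seed=1)
        ret, _ = studies.filter_analysis_set(full)
        with pytest.raises(ValueError, match="single-sex"):
            fit(ret, truth.hierarchy, SMALL_CFG, MCMCConfig(n_chains=2, n_burnin=1, n_samples=1))

    def test_retained_rw2_draws_satisfy_constraints(self):
        truth, male = _small_dataset()
        mc = MCMCConfig(n_chains=2, n_burnin=30, n_samples=20, seed=2)
        d = fit(male, truth.hierarchy, SMALL_CFG, mc, check=False)
        params = d.params_at(1, 19)
        params.check_constraints()  # raises on violation

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            MCMCConfig(n_chains=1)


class TestPSRF:
    def test_exact_copies(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=5000)
        chains = np.vstack([x, x])
        r = psrf(chains)
        assert r <= 1.0 + 1e-6  # between-chain variance is zero

    def test_same_distribution_near_one(self):
        rng = np.random.default_rng(1)
        chains = rng.normal(size=(2, 10000))
        assert 0.99 <= psrf(chains) <= 1.05

    def test_separated_chains_flag(self):
        rng = np.random.default_rng(2)
        chains = rng.normal(size=(2, 1000))
        chains[1] += 10.0
        assert psrf(chains) > 1.1

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            psrf(np.zeros((1, 100)))


class TestCheckConvergence:
    def test_report_on_real_fit(self):
        truth, male = _small_dataset()
        mc = MCMCConfig(n_chains=2, n_burnin=150, n_samples=250, seed=3)
        d = fit(male, truth.hierarchy, SMALL_CFG, mc, check=False)
        rep = check_convergence(d)
        assert set(rep.table.columns) == {"parameter", "psrf", "flagged"}
        assert (rep.table["psrf"] > 0).all()
        assert "gamma" in rep.traces
        assert rep.traces["gamma"].shape == (2, 250)


class TestSummarize:
    @staticmethod
    def _draws_with_heights(values):
        """Fit-free PosteriorDraws stub: constant curves set via alpha0."""
        from heightcurve.inference import PosteriorDraws, HYPER_NAMES
        from heightcurve.model import constraint_basis

        h = studies.CountryIndex(("AA",), {"AA": "R0"}, {"R0": "S0"})
        grid = CohortGrid(step=5)
        n = len(values)
        G2 = grid.size - 2
        lin = np.zeros((1, n, 8))
        lin[0, :, 0] = values
        v = {
            lev: np.zeros((1, n, u, G2))
            for lev, u in (("world", 1), ("super_region", 1), ("region", 1), ("country", 1))
        }
        return PosteriorDraws(
            sex="male",
            hierarchy=h,
            grid=grid,
            Z=constraint_basis(grid.size),
            lin=lin,
            v=v,
            gamma=np.zeros((1, n)),
            b=np.zeros((1, n, 0)),
            hyper=np.ones((1, n, len(HYPER_NAMES))),
            study_ids=(),
            study_coverage=(),
            seed=0,
            config=ModelConfig(grid=grid),
            mcmc=MCMCConfig(n_chains=2, n_burnin=0, n_samples=n),
        )

    def test_constant_draws(self):
        d = self._draws_with_heights(np.full(100, 171.0))
        est = summarize(d, cohorts=[1946.0])
        row = est.iloc[0]
        assert row["mean_cm"] == row["lo_cm"] == row["hi_cm"] == pytest.approx(171.0)

    def test_normal_draws_interval(self):
        rng = np.random.default_rng(7)
        d = self._draws_with_heights(170.0 + rng.standard_normal(5000))
        est = summarize(d, cohorts=[1946.0]).iloc[0]
        # normal 2.5/97.5 quantile oracle: 170 +/- 1.96
        assert est["lo_cm"] == pytest.approx(170 - 1.96, abs=0.12)
        assert est["hi_cm"] == pytest.approx(170 + 1.96, abs=0.12)
        assert est["lo_cm"] <= est["mean_cm"] <= est["hi_cm"]

    def test_interval_ordering_everywhere(self):
        truth, male = _small_dataset()
        mc = MCMCConfig(n_chains=2, n_burnin=30, n_samples=40, seed=4)
        d = fit(male, truth.hierarchy, SMALL_CFG, mc, check=False)
        est = summarize(d)
        assert (est["lo_cm"] <= est["mean_cm"]).all()
        assert (est["mean_cm"] <= est["hi_cm"]).all()

    def test_off_grid_cohort_rejected(self):
        d = self._draws_with_heights(np.full(10, 170.0))
        with pytest.raises(ValueError):
            summarize(d, cohorts=[1850.0])


class TestPartialPooling:
    def test_no_data_country_tracks_its_region(self):
        """A country with no observations borrows its region's curve: its own
        deviations are drawn around zero and their spread matches the
        estimated country-level prior."""
        truth, male = _small_dataset(seed=3, n_countries=8)
        drop = truth.hierarchy.countries[0]
        train = male[male["country"] != drop]
        mc = MCMCConfig(n_chains=2, n_burnin=150, n_samples=400, seed=6)
        fixed = {"sigma2_alpha_country": 0.36, "sigma2_beta_country": 1.6e-5}
        d = fit(train, truth.hierarchy, SMALL_CFG, mc, fixed_hyper=fixed, check=False)
        ci = truth.hierarchy.countries.index(drop)
        cols = d._lin_cols(drop)
        alpha_c = d.lin.reshape(d.n_draws, -1)[:, cols[6]]
        # conditional given no data is exactly N(0, sigma2): prior recovery
        assert abs(alpha_c.mean()) < 4 * 0.6 / np.sqrt(200)
        assert alpha_c.std() == pytest.approx(0.6, rel=0.15)

    def test_added_precise_observation_narrows_interval(self):
        """More information at a cohort never widens its credible interval
        (checked over replicate seeds)."""
        widths_without, widths_with = [], []
        for seed in (0, 1, 2):
            truth, male = _small_dataset(seed=seed)
            country = truth.hierarchy.countries[0]
            extra = male.iloc[[0]].copy()
            extra["study_id"] = "extra-national"
            extra["country"] = country
            extra["coverage"] = "national"
            extra["survey_year"] = 1988
            extra["age_group"] = "18"
            extra["mean_cm"] = truth.height_at("male", country, 1970.0)
            extra["se_cm"] = 0.05
            extra["birth_cohort"] = 1970.0
            extra["mid_age"] = 18.0
            aug = pd.concat([male, extra], ignore_index=True)
            mc = MCMCConfig(n_chains=2, n_burnin=100, n_samples=200, seed=8 + seed)
            for data, out in ((male, widths_without), (aug, widths_with)):
                d = fit(data, truth.hierarchy, SMALL_CFG, mc, check=False)
                est = summarize(d, cohorts=[1970.0], countries=[country]).iloc[0]
                out.append(est["hi_cm"] - est["lo_cm"])
        assert np.mean(widths_with) <= np.mean(widths_without) + 0.05
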