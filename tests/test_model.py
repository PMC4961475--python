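"""Model components: RW2 kernel, constraints, mean function, densities."""

import numpy as np
import pandas as pd
import pytest

from heightcurve import studies
from heightcurve.model import (
    CohortGrid,
    HyperParams,
    ModelConfig,
    ModelParams,
    constrain_rw2,
    constraint_basis,
    log_likelihood,
    log_prior,
    mean_height,
    rw2_quadratic_form,
    rw2_structure_matrix,
)

GRID = CohortGrid()


def _hyper(**kwargs):
    base = dict(
        sigma2_alpha={"super_region": 4.0, "region": 1.0, "country": 0.25},
        sigma2_beta={"super_region": 1e-3, "region": 1e-3, "country": 1e-4},
        rw2_var={"world": 1e-3, "super_region": 1e-3, "region": 1e-4, "country": 1e-4},
        tau2={"subnational": 1.0, "community": 2.25},
        nu2={"subnational": 0.25, "community": 1.0},
        omega2=0.1,
    )
    base.update(kwargs)
    return HyperParams(**base)


class TestRW2Kernel:
    @pytest.mark.parametrize(
        "u, expected",
        [
            ((0, 0, 0, 0), 0.0),
            ((1, 2, 3, 4), 0.0),  # linear sequences are unpenalised
            ((0, 1, 4, 9), 8.0),  # second differences (2, 2)
        ],
    )
    def test_values(self, u, expected):
        assert rw2_quadratic_form(u) == expected

    def test_short_vector_rejected(self):
        with pytest.raises(ValueError):
            rw2_quadratic_form([1.0, 2.0])

    def test_matches_structure_matrix(self):
        rng = np.random.default_rng(0)
        u = rng.normal(size=20)
        K = rw2_structure_matrix(20)
        assert rw2_quadratic_form(u) == pytest.approx(u @ K @ u)


class TestConstrainRW2:
    def test_idempotent(self):
        rng = np.random.default_rng(1)
        u = rng.normal(size=15)
        once = constrain_rw2(u)
        np.testing.assert_allclose(constrain_rw2(once), once, atol=1e-12)
        assert abs(once.sum()) < 1e-10

    @pytest.mark.parametrize("u", [np.full(10, 3.0), np.arange(10.0)])
    def test_annihilates_constant_and_linear(self, u):
        np.testing.assert_allclose(constrain_rw2(u), 0.0, atol=1e-10)

    def test_basis_is_orthonormal_and_constrained(self):
        Z = constraint_basis(12)
        np.testing.assert_allclose(Z.T @ Z, np.eye(10), atol=1e-12)
        assert np.abs(Z.sum(axis=0)).max() < 1e-10
        t = np.arange(12.0)
        assert np.abs(t @ Z).max() < 1e-9


class TestMeanHeight:
    def test_linear_only(self, tiny_hierarchy):
        p = ModelParams.zeros(tiny_hierarchy, GRID, alpha0=160.0, beta0=0.05)
        mu = mean_height(p, tiny_hierarchy, GRID, "AA", GRID.t0 + 10, age=18)
        assert mu == pytest.approx(160.5)

    def test_age_drift_decade(self, tiny_hierarchy):
        p = ModelParams.zeros(tiny_hierarchy, GRID, alpha0=170.0, gamma=-0.02)
        at18 = mean_height(p, tiny_hierarchy, GRID, "AA", 1950, age=18)
        at28 = mean_height(p, tiny_hierarchy, GRID, "AA", 1950, age=28)
        assert at28 - at18 == pytest.approx(-0.2)

    def test_rw2_interpolation_half_integer(self, tiny_hierarchy):
        u = np.zeros(GRID.size)
        i = int(1975 - GRID.start)
        u[i], u[i + 1] = 1.0, 2.0
        p = ModelParams.zeros(tiny_hierarchy, GRID, u_glob=u)
        mu = mean_height(p, tiny_hierarchy, GRID, "AA", 1975.5)
        assert mu == pytest.approx(1.5)

    def test_grid_nodes_are_exact(self, tiny_hierarchy):
        rng = np.random.default_rng(2)
        u = constrain_rw2(rng.normal(size=GRID.size))
        p = ModelParams.zeros(tiny_hierarchy, GRID, u_glob=u)
        for i, t in enumerate(GRID.years[::17]):
            assert mean_height(p, tiny_hierarchy, GRID, "AA", t) == pytest.approx(
                u[17 * i], abs=1e-12
            )

    def test_off_grid_cohort_rejected(self, tiny_hierarchy):
        p = ModelParams.zeros(tiny_hierarchy, GRID)
        with pytest.raises(ValueError):
            mean_height(p, tiny_hierarchy, GRID, "AA", 1880)


def _one_obs(obs_factory, coverage="national", y=170.0, se=1.0):
    df = obs_factory([("s1", "AA", "male", coverage, 1970, "18", y, se, 100, True)])
    out, _ = studies.filter_analysis_set(df)
    return out


class TestLogLikelihood:
    def test_density_at_mean(self, tiny_hierarchy, obs_factory):
        obs = _one_obs(obs_factory, y=170.0, se=1.0)
        p = ModelParams.zeros(tiny_hierarchy, GRID, alpha0=170.0)
        h = _hyper(omega2=0.5, nu2={"subnational": 0.0, "community": 0.0})
        v = 1.0 + 0.5
        ll = log_likelihood(p, h, obs, tiny_hierarchy, GRID)
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi * v))

    def test_additivity(self, tiny_hierarchy, obs_factory):
        obs = _one_obs(obs_factory, y=168.0)
        doubled = pd.concat([obs, obs], ignore_index=True)
        p = ModelParams.zeros(tiny_hierarchy, GRID, alpha0=170.0)
        h = _hyper()
        assert log_likelihood(p, h, doubled, tiny_hierarchy, GRID) == pytest.approx(
            2 * log_likelihood(p, h, obs, tiny_hierarchy, GRID)
        )

    def test_community_extra_variance_flattens(self, tiny_hierarchy, obs_factory):
        """Same residual: the community row pays a smaller quadratic penalty."""
        p = ModelParams.zeros(tiny_hierarchy, GRID, alpha0=170.0)
        h = _hyper(omega2=0.1, nu2={"subnational": 0.0, "community": 1.5})
        nat = _one_obs(obs_factory, coverage="national", y=173.0)
        com = _one_obs(obs_factory, coverage="community", y=173.0)
        ll_nat = log_likelihood(p, h, nat, tiny_hierarchy, GRID)
        ll_com = log_likelihood(p, h, com, tiny_hierarchy, GRID)
        from scipy.stats import norm

        assert ll_nat == pytest.approx(norm.logpdf(173.0, 170.0, np.sqrt(1.0 + 0.1)))
        assert ll_com == pytest.approx(norm.logpdf(173.0, 170.0, np.sqrt(1.0 + 0.1 + 1.5)))
        # flatter density: smaller quadratic penalty for the same 3 cm residual
        resid_pen_nat = -0.5 * 9.0 / 1.1
        resid_pen_com = -0.5 * 9.0 / 2.6
        assert resid_pen_com > resid_pen_nat

    def test_negative_total_variance_rejected(self, tiny_hierarchy, obs_factory):
        obs = _one_obs(obs_factory)
        p = ModelParams.zeros(tiny_hierarchy, GRID, alpha0=170.0)
        h = _hyper()
        h.omega2 = -5.0
        with pytest.raises(ValueError):
            log_likelihood(p, h, obs, tiny_hierarchy, GRID)


class TestLogPrior:
    def test_country_deviation_scaling(self, tiny_hierarchy):
        """Doubling a deviation d changes its block by -3 d^2 / (2 sigma^2)."""
        h = _hyper()
        cfg = ModelConfig()
        d = 0.8
        p1 = ModelParams.zeros(tiny_hierarchy, GRID)
        p1.alpha_c = {"AA": d, "BB": 0.0}
        p2 = ModelParams.zeros(tiny_hierarchy, GRID)
        p2.alpha_c = {"AA": 2 * d, "BB": 0.0}
        delta = log_prior(p2, h, cfg) - log_prior(p1, h, cfg)
        assert delta == pytest.approx(-3 * d**2 / (2 * h.sigma2_alpha["country"]))

    def test_rw2_block_matches_dense_quadratic_form(self, tiny_hierarchy):
        rng = np.random.default_rng(3)
        u = constrain_rw2(rng.normal(size=GRID.size))
        h = _hyper()
        cfg = ModelConfig()
        p0 = ModelParams.zeros(tiny_hierarchy, GRID)
        p1 = ModelParams.zeros(tiny_hierarchy, GRID, u_glob=u)
        delta = log_prior(p1, h, cfg) - log_prior(p0, h, cfg)
        K = rw2_structure_matrix(GRID.size)
        assert delta == pytest.approx(-0.5 * (u @ K @ u) / h.rw2_var["world"])

    def test_constraint_violation_rejected(self, tiny_hierarchy):
        p = ModelParams.zeros(tiny_hierarchy, GRID, u_glob=np.ones(GRID.size))
        with pytest.raises(ValueError):
            log_prior(p, _hyper(), ModelConfig())

    def test_mode_at_zero_deviations(self, tiny_hierarchy):
        """Centered normal blocks peak at zero deviations."""
        h = _hyper()
        cfg = ModelConfig()
        p0 = ModelParams.zeros(tiny_hierarchy, GRID)
        lp0 = log_prior(p0, h, cfg)
        rng = np.random.default_rng(4)
        for _ in range(5):
            p = ModelParams.zeros(tiny_hierarchy, GRID)
            p.alpha_c = {"AA": rng.normal(0, 0.1), "BB": rng.normal(0, 0.1)}
            assert log_prior(p, h, cfg) <= lp0


def test_balanced_shift_identified_by_prior_not_likelihood(
    tiny_hierarchy, obs_factory
):
    """alpha_c -> alpha_c + d, alpha_r -> alpha_r - d leaves the likelihood
    exactly invariant; only the hierarchical prior distinguishes levels."""
    obs = obs_factory(
        [
            ("s1", "AA", "male", "national", 1970, "18", 172.0, 0.7, 50, True),
            ("s2", "BB", "male", "national", 1980, "30-39", 169.0, 0.9, 80, True),
        ]
    )
    obs, _ = studies.filter_analysis_set(obs)
    h = _hyper()
    cfg = ModelConfig()
    p = ModelParams.zeros(tiny_hierarchy, GRID, alpha0=170.0)
    p.alpha_c = {"AA": 1.0, "BB": -0.5}
    p.alpha_r = {"R0": 0.3}
    d = 0.9
    q = ModelParams.zeros(tiny_hierarchy, GRID, alpha0=170.0)
    q.alpha_c = {"AA": 1.0 + d, "BB": -0.5 + d}
    q.alpha_r = {"R0": 0.3 - d}
    ll_p = log_likelihood(p, h, obs, tiny_hierarchy, GRID)
    ll_q = log_likelihood(q, h, obs, tiny_hierarchy, GRID)
    assert ll_p == pytest.approx(ll_q, abs=1e-10)
    assert log_prior(p, h, cfg) != pytest.approx(log_prior(q, h, cfg))
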