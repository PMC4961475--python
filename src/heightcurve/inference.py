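"""Blocked Gibbs MCMC for the hierarchical height model.

The model is conditionally Gaussian given the variance parameters, so the
sampler alternates

* an exact multivariate-normal draw of the full linear block (world
  intercept/slope plus every hierarchical deviation) from its full
  conditional,
* exact joint draws of the constrained RW2 vectors, one hierarchy level at
  a time — units within a level touch disjoint observations, so all units
  of a level are drawn simultaneously from their full conditionals in one
  batched Cholesky,
* scalar conjugate draws for the age-drift slope and the study offsets,
* conjugate inverse-gamma draws for the hierarchical and RW2 variances and
  the study-offset variances, and
* a joint random-walk Metropolis step (log scale) for the residual
  variances (global plus the coverage-specific extra variances), which are
  not conjugate because sampling variances differ across observations.

RW2 vectors are parameterised in an orthonormal basis of the
doubly-constrained subspace (zero sum, zero linear moment), so every
retained draw satisfies the constraints exactly and the constrained RW2
precision is positive definite.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse

from heightcurve.studies import CountryIndex, filter_analysis_set
from heightcurve.model import (
    CohortGrid,
    ModelConfig,
    ModelParams,
    HyperParams,
    constraint_basis,
    rw2_structure_matrix,
)

LEVELS = ("world", "super_region", "region", "country")
COVERAGE_CODE = {"national": 0, "subnational": 1, "community": 2}

HYPER_NAMES = (
    "sigma2_alpha_super_region",
    "sigma2_alpha_region",
    "sigma2_alpha_country",
    "sigma2_beta_super_region",
    "sigma2_beta_region",
    "sigma2_beta_country",
    "rw2_var_world",
    "rw2_var_super_region",
    "rw2_var_region",
    "rw2_var_country",
    "tau2_subnational",
    "tau2_community",
    "nu2_subnational",
    "nu2_community",
    "omega2",
)

_INIT_HYPER = {
    "sigma2_alpha_super_region": 4.0,
    "sigma2_alpha_region": 1.0,
    "sigma2_alpha_country": 0.25,
    "sigma2_beta_super_region": 1.0e-3,
    "sigma2_beta_region": 2.5e-4,
    "sigma2_beta_country": 1.0e-4,
    "rw2_var_world": 1.0e-3,
    "rw2_var_super_region": 3.0e-4,
    "rw2_var_region": 1.0e-4,
    "rw2_var_country": 3.0e-5,
    "tau2_subnational": 1.0,
    "tau2_community": 1.0,
    "nu2_subnational": 0.25,
    "nu2_community": 0.25,
    "omega2": 0.25,
}


@dataclasses.dataclass
class MCMCConfig:
    """Chain settings.  Defaults: 4 chains, 2000 burn-in, 5000 retained."""

    n_chains: int = 4
    n_burnin: int = 2000
    n_samples: int = 5000
    thin: int = 1
    seed: int = 0
    psrf_threshold: float = 1.1

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("need at least 2 chains")
        if self.n_samples < 1 or self.thin < 1:
            raise ValueError("n_samples and thin must be >= 1")


@dataclasses.dataclass
class PosteriorDraws:
    """Post-burn-in draws of all model parameters, tagged by chain."""

    sex: str
    hierarchy: CountryIndex
    grid: CohortGrid
    Z: np.ndarray
    lin: np.ndarray  # (chains, samples, m)
    v: Mapping[str, np.ndarray]  # level -> (chains, samples, units, G-2)
    gamma: np.ndarray  # (chains, samples)
    b: np.ndarray  # (chains, samples, n_studies)
    hyper: np.ndarray  # (chains, samples, len(HYPER_NAMES))
    study_ids: tuple[str, ...]
    study_coverage: tuple[str, ...]
    seed: int
    config: ModelConfig
    mcmc: MCMCConfig
    converged: bool | None = None

    # ---- layout -----------------------------------------------------
    @property
    def n_chains(self) -> int:
        return self.lin.shape[0]

    @property
    def n_samples(self) -> int:
        return self.lin.shape[1]

    @property
    def n_draws(self) -> int:
        return self.n_chains * self.n_samples

    def _codes(self):
        ci, ri, gi = self.hierarchy.indices()
        return ci, ri, gi

    def _lin_cols(self, country: str) -> tuple[int, int, int, int, int, int, int, int]:
        ci, ri, gi = self._codes()
        S, R = len(gi), len(ri)
        region = self.hierarchy.region_of[country]
        sreg = self.hierarchy.super_region_of[region]
        g, r, c = gi[sreg], ri[region], ci[country]
        a_g = 2 + g
        b_g = 2 + S + g
        a_r = 2 + 2 * S + r
        b_r = 2 + 2 * S + R + r
        a_c = 2 + 2 * S + 2 * R + c
        b_c = 2 + 2 * S + 2 * R + len(ci) + c
        return 0, 1, a_g, b_g, a_r, b_r, a_c, b_c

    # ---- posterior functionals --------------------------------------
    def height_draws(self, country: str, cohorts, age: float = 18.0) -> np.ndarray:
        """Draws of population-level mean height, shape (n_draws, n_cohorts)."""
        cohorts = np.atleast_1d(np.asarray(cohorts, dtype=float))
        ci, ri, gi = self._codes()
        region = self.hierarchy.region_of[country]
        sreg = self.hierarchy.super_region_of[region]
        lin = self.lin.reshape(self.n_draws, -1)
        c0, c1, a_g, b_g, a_r, b_r, a_c, b_c = self._lin_cols(country)
        a = lin[:, c0] + lin[:, a_g] + lin[:, a_r] + lin[:, a_c]
        b = lin[:, c1] + lin[:, b_g] + lin[:, b_r] + lin[:, b_c]
        G2 = self.Z.shape[1]
        vsum = (
            self.v["world"].reshape(self.n_draws, -1, G2)[:, 0]
            + self.v["super_region"].reshape(self.n_draws, -1, G2)[:, gi[sreg]]
            + self.v["region"].reshape(self.n_draws, -1, G2)[:, ri[region]]
            + self.v["country"].reshape(self.n_draws, -1, G2)[:, ci[country]]
        )
        curve = vsum @ self.Z.T  # (n_draws, G)
        i0, w0, w1 = self.grid.interp_weights(cohorts)
        u = curve[:, i0] * w0 + curve[:, i0 + 1] * w1
        gam = self.gamma.reshape(self.n_draws)
        out = (
            a[:, None]
            + b[:, None] * (cohorts - self.grid.t0)[None, :]
            + u
            + gam[:, None] * (age - 18.0)
        )
        return out

    def hyper_draws(self, name: str) -> np.ndarray:
        return self.hyper[..., HYPER_NAMES.index(name)]

    def params_at(self, chain: int, draw: int) -> ModelParams:
        """Materialise one draw as a ModelParams (for cross-checks)."""
        ci, ri, gi = self._codes()
        S, R, C = len(gi), len(ri), len(ci)
        lin = self.lin[chain, draw]
        sl = lambda o, n: lin[o : o + n]
        a_g = sl(2, S)
        b_g = sl(2 + S, S)
        a_r = sl(2 + 2 * S, R)
        b_r = sl(2 + 2 * S + R, R)
        a_c = sl(2 + 2 * S + 2 * R, C)
        b_c = sl(2 + 2 * S + 2 * R + C, C)
        mk = lambda keys, vals: {k: float(vals[i]) for k, i in keys.items()}
        mku = lambda keys, arr: {k: self.Z @ arr[i] for k, i in keys.items()}
        return ModelParams(
            alpha0=float(lin[0]),
            beta0=float(lin[1]),
            gamma=float(self.gamma[chain, draw]),
            alpha_g=mk(gi, a_g),
            alpha_r=mk(ri, a_r),
            alpha_c=mk(ci, a_c),
            beta_g=mk(gi, b_g),
            beta_r=mk(ri, b_r),
            beta_c=mk(ci, b_c),
            u_glob=self.Z @ self.v["world"][chain, draw, 0],
            u_g=mku(gi, self.v["super_region"][chain, draw]),
            u_r=mku(ri, self.v["region"][chain, draw]),
            u_c=mku(ci, self.v["country"][chain, draw]),
            offsets={
                sid: float(self.b[chain, draw, j]) for j, sid in enumerate(self.study_ids)
            },
            offset_coverage=dict(zip(self.study_ids, self.study_coverage)),
        )

    def hyper_at(self, chain: int, draw: int) -> HyperParams:
        h = dict(zip(HYPER_NAMES, self.hyper[chain, draw]))
        return HyperParams(
            sigma2_alpha={
                "super_region": h["sigma2_alpha_super_region"],
                "region": h["sigma2_alpha_region"],
                "country": h["sigma2_alpha_country"],
            },
            sigma2_beta={
                "super_region": h["sigma2_beta_super_region"],
                "region": h["sigma2_beta_region"],
                "country": h["sigma2_beta_country"],
            },
            rw2_var={lev: h[f"rw2_var_{lev}"] for lev in LEVELS},
            tau2={"subnational": h["tau2_subnational"], "community": h["tau2_community"]},
            nu2={"subnational": h["nu2_subnational"], "community": h["nu2_community"]},
            omega2=h["omega2"],
        )


class _GibbsSampler:
    """One-sex sampler state; arrays are indexed per observation row."""

    def __init__(
        self,
        obs: pd.DataFrame,
        hierarchy: CountryIndex,
        config: ModelConfig,
        fixed_hyper: Mapping[str, float] | None,
    ):
        self.config = config
        self.grid = config.grid
        self.hierarchy = hierarchy
        G = self.grid.size
        self.G = G
        self.G2 = G - 2
        self.Z = constraint_basis(G)
        K = rw2_structure_matrix(G)
        self.Ktil = self.Z.T @ K @ self.Z

        ci, ri, gi = hierarchy.indices()
        self.S, self.R, self.C = len(gi), len(ri), len(ci)
        self.m = 2 + 2 * self.S + 2 * self.R + 2 * self.C

        self.y = obs["mean_cm"].to_numpy(dtype=float)
        self.n = self.y.size
        self.se2 = obs["se_cm"].to_numpy(dtype=float) ** 2
        self.x_age = obs["mid_age"].to_numpy(dtype=float) - 18.0
        t = obs["birth_cohort"].to_numpy(dtype=float)
        self.dt = t - self.grid.t0
        self.i0, self.w0, self.w1 = self.grid.interp_weights(t)
        self.cov = obs["coverage"].map(COVERAGE_CODE).to_numpy(dtype=int)

        self.c_idx = obs["country"].map(ci).to_numpy(dtype=int)
        region = obs["country"].map(hierarchy.region_of)
        self.r_idx = region.map(ri).to_numpy(dtype=int)
        self.g_idx = region.map(hierarchy.super_region_of).map(gi).to_numpy(dtype=int)

        studies = obs[["study_id", "coverage"]].drop_duplicates("study_id")
        self.study_ids = tuple(studies["study_id"].astype(str))
        self.study_cov = tuple(studies["coverage"])
        sidx = {s: j for j, s in enumerate(self.study_ids)}
        self.s_idx = obs["study_id"].astype(str).map(sidx).to_numpy(dtype=int)
        self.J = len(self.study_ids)
        self.study_cov_code = np.array([COVERAGE_CODE[c] for c in self.study_cov])
        self.study_national = self.study_cov_code == 0

        self.unit_idx = {
            "world": np.zeros(self.n, dtype=int),
            "super_region": self.g_idx,
            "region": self.r_idx,
            "country": self.c_idx,
        }
        self.n_units = {"world": 1, "super_region": self.S, "region": self.R, "country": self.C}

        # Sparse design of the linear block: 8 entries per row.
        rows = np.repeat(np.arange(self.n), 8)
        cols = np.empty((self.n, 8), dtype=int)
        vals = np.empty((self.n, 8))
        S, R, C = self.S, self.R, self.C
        cols[:, 0] = 0
        cols[:, 1] = 1
        cols[:, 2] = 2 + self.g_idx
        cols[:, 3] = 2 + S + self.g_idx
        cols[:, 4] = 2 + 2 * S + self.r_idx
        cols[:, 5] = 2 + 2 * S + R + self.r_idx
        cols[:, 6] = 2 + 2 * S + 2 * R + self.c_idx
        cols[:, 7] = 2 + 2 * S + 2 * R + C + self.c_idx
        vals[:, 0::2] = 1.0
        vals[:, 1::2] = self.dt[:, None]
        self.X = scipy.sparse.csr_matrix(
            (vals.ravel(), (rows, cols.ravel())), shape=(self.n, self.m)
        )
        self.X_row = rows  # row index of each stored entry
        self.Xdata0 = self.X.data.copy()

        # map from linear-block column to its hyper variance
        self.col_hyper = np.array(
            ["alpha0", "beta0"]
            + ["sigma2_alpha_super_region"] * S
            + ["sigma2_beta_super_region"] * S
            + ["sigma2_alpha_region"] * R
            + ["sigma2_beta_region"] * R
            + ["sigma2_alpha_country"] * C
            + ["sigma2_beta_country"] * C
        )

        self.fixed = dict(fixed_hyper or {})
        for k in self.fixed:
            if k not in HYPER_NAMES:
                raise ValueError(f"unknown hyperparameter {k!r}")

        # scale-matched IG hyperprior (shape, scale) per variance
        cfg = config
        self.ig = {}
        for name in HYPER_NAMES:
            if name.startswith("sigma2_alpha"):
                scale = cfg.ig_scale_sigma2_alpha
            elif name.startswith("sigma2_beta"):
                scale = cfg.ig_scale_sigma2_beta
            elif name.startswith("rw2_var"):
                scale = cfg.ig_scale_rw2
            elif name.startswith("tau2"):
                scale = cfg.ig_scale_tau2
            elif name.startswith("nu2"):
                scale = cfg.ig_scale_nu2
            else:
                scale = cfg.ig_scale_omega2
            self.ig[name] = (cfg.ig_shape, scale)

    # ---- state ------------------------------------------------------
    def init_state(self, chain_factor: float) -> None:
        self.lin = np.zeros(self.m)
        self.v = {lev: np.zeros((self.n_units[lev], self.G2)) for lev in LEVELS}
        self.gamma = 0.0
        self.b = np.zeros(self.J)
        self.hyper = {}
        for name in HYPER_NAMES:
            if name in self.fixed:
                self.hyper[name] = float(self.fixed[name])
            else:
                self.hyper[name] = _INIT_HYPER[name] * chain_factor
        self.lin_fit = np.zeros(self.n)
        self.rw2_fit = {lev: np.zeros(self.n) for lev in LEVELS}
        self.rw2_total = np.zeros(self.n)
        self.b_fit = np.zeros(self.n)
        self._refresh_w()
        self.mh_accept = 0
        self.mh_tries = 0

    def _refresh_w(self) -> None:
        nu2 = np.array(
            [0.0, self.hyper["nu2_subnational"], self.hyper["nu2_community"]]
        )
        self.V = self.se2 + self.hyper["omega2"] + nu2[self.cov]
        self.w = 1.0 / self.V

    # ---- block updates ----------------------------------------------
    def _prior_prec_lin(self) -> np.ndarray:
        p = np.empty(self.m)
        p[0] = 1.0 / self.config.alpha0_prior_var
        p[1] = 1.0 / self.config.beta0_prior_var
        for j in range(2, self.m):
            p[j] = 1.0 / self.hyper[self.col_hyper[j]]
        return p

    def update_linear(self, rng: np.random.Generator) -> None:
        r = self.y - self.rw2_total - self.gamma * self.x_age - self.b_fit
        Xw = self.X.copy()
        Xw.data = self.Xdata0 * self.w[self.X_row]
        Q = (self.X.T @ Xw).toarray()
        Q[np.diag_indices_from(Q)] += self._prior_prec_lin()
        rhs = self.X.T @ (self.w * r)
        L = scipy.linalg.cholesky(Q, lower=True)
        mean = scipy.linalg.cho_solve((L, True), rhs)
        z = rng.standard_normal(self.m)
        self.lin = mean + scipy.linalg.solve_triangular(L, z, lower=True, trans="T")
        self.lin_fit = self.X @ self.lin

    def update_rw2_level(self, lev: str, rng: np.random.Generator) -> None:
        U, G, G2 = self.n_units[lev], self.G, self.G2
        uidx = self.unit_idx[lev]
        s2 = self.hyper[f"rw2_var_{lev}"]
        r = (
            self.y
            - self.lin_fit
            - self.gamma * self.x_age
            - self.b_fit
            - (self.rw2_total - self.rw2_fit[lev])
        )
        wa = self.w * self.w0
        wb = self.w * self.w1
        k0 = uidx * G + self.i0
        L = U * G
        d = np.bincount(k0, wa * self.w0, minlength=L) + np.bincount(
            k0 + 1, wb * self.w1, minlength=L
        )
        off = np.bincount(k0, wa * self.w1, minlength=L)
        rhs = np.bincount(k0, wa * r, minlength=L) + np.bincount(k0 + 1, wb * r, minlength=L)
        d = d.reshape(U, G)
        off = off.reshape(U, G)
        rhs = rhs.reshape(U, G)
        Z = self.Z
        MZ = d[:, :, None] * Z[None]
        MZ[:, :-1] += off[:, :-1, None] * Z[None, 1:]
        MZ[:, 1:] += off[:, :-1, None] * Z[None, :-1]
        Q = (self.Ktil / s2)[None] + np.einsum("gk,ugl->ukl", Z, MZ, optimize=True)
        rhs_v = rhs @ Z
        Lc = np.linalg.cholesky(Q)
        mean = np.linalg.solve(Q, rhs_v[..., None])[..., 0]
        z = rng.standard_normal((U, G2))
        pert = np.linalg.solve(np.swapaxes(Lc, 1, 2), z[..., None])[..., 0]
        v = mean + pert
        self.v[lev] = v
        u = v @ Z.T
        fit = u[uidx, self.i0] * self.w0 + u[uidx, self.i0 + 1] * self.w1
        self.rw2_total += fit - self.rw2_fit[lev]
        self.rw2_fit[lev] = fit

    def update_gamma(self, rng: np.random.Generator) -> None:
        r = self.y - self.lin_fit - self.rw2_total - self.b_fit
        q = 1.0 / self.config.gamma_prior_var + float(self.w @ (self.x_age**2))
        mean = float(self.w @ (self.x_age * r)) / q
        self.gamma = mean + rng.standard_normal() / np.sqrt(q)

    def update_offsets(self, rng: np.random.Generator) -> None:
        if self.J == 0:
            return
        r = self.y - self.lin_fit - self.rw2_total - self.gamma * self.x_age
        sw = np.bincount(self.s_idx, self.w, minlength=self.J)
        swr = np.bincount(self.s_idx, self.w * r, minlength=self.J)
        tau2 = np.array(
            [np.inf, self.hyper["tau2_subnational"], self.hyper["tau2_community"]]
        )
        prior_prec = np.where(self.study_national, 0.0, 1.0 / tau2[self.study_cov_code])
        q = prior_prec + sw
        q = np.where(q > 0, q, 1.0)
        b = swr / q + rng.standard_normal(self.J) / np.sqrt(q)
        b[self.study_national] = 0.0
        self.b = b
        self.b_fit = b[self.s_idx]

    def _ig_draw(self, name: str, n_eff: float, ss: float, rng) -> float:
        shape0, scale0 = self.ig[name]
        shape = shape0 + 0.5 * n_eff
        scale = scale0 + 0.5 * ss
        return float(scale / rng.gamma(shape))

    def update_variances(self, rng: np.random.Generator) -> None:
        S, R, C = self.S, self.R, self.C
        slices = {
            "sigma2_alpha_super_region": slice(2, 2 + S),
            "sigma2_beta_super_region": slice(2 + S, 2 + 2 * S),
            "sigma2_alpha_region": slice(2 + 2 * S, 2 + 2 * S + R),
            "sigma2_beta_region": slice(2 + 2 * S + R, 2 + 2 * S + 2 * R),
            "sigma2_alpha_country": slice(2 + 2 * S + 2 * R, 2 + 2 * S + 2 * R + C),
            "sigma2_beta_country": slice(2 + 2 * S + 2 * R + C, self.m),
        }
        for name, sl in slices.items():
            if name in self.fixed:
                continue
            devs = self.lin[sl]
            self.hyper[name] = self._ig_draw(name, devs.size, float(devs @ devs), rng)
        for lev in LEVELS:
            name = f"rw2_var_{lev}"
            if name in self.fixed:
                continue
            v = self.v[lev]
            ss = float(np.einsum("uk,kl,ul->", v, self.Ktil, v))
            self.hyper[name] = self._ig_draw(name, v.shape[0] * self.G2, ss, rng)
        for cov, code in (("subnational", 1), ("community", 2)):
            name = f"tau2_{cov}"
            if name in self.fixed:
                continue
            mask = self.study_cov_code == code
            bs = self.b[mask]
            self.hyper[name] = self._ig_draw(name, bs.size, float(bs @ bs), rng)

    def update_residual_variances(self, rng: np.random.Generator) -> None:
        names = [n for n in ("omega2", "nu2_subnational", "nu2_community") if n not in self.fixed]
        if not names:
            self._refresh_w()
            return
        resid = self.y - self.lin_fit - self.rw2_total - self.gamma * self.x_age - self.b_fit

        def logpost(vals: dict) -> float:
            nu2 = np.array(
                [
                    0.0,
                    vals.get("nu2_subnational", self.hyper["nu2_subnational"]),
                    vals.get("nu2_community", self.hyper["nu2_community"]),
                ]
            )
            om = vals.get("omega2", self.hyper["omega2"])
            V = self.se2 + om + nu2[self.cov]
            lp = -0.5 * float(np.log(V).sum() + (resid**2 / V).sum())
            for n in names:
                shape0, scale0 = self.ig[n]
                x = vals[n]
                # IG log-density plus log-scale Jacobian
                lp += -(shape0 + 1.0) * np.log(x) - scale0 / x + np.log(x)
            return lp

        cur = {n: self.hyper[n] for n in names}
        prop = {n: cur[n] * np.exp(0.15 * rng.standard_normal()) for n in names}
        self.mh_tries += 1
        if np.log(rng.random()) < logpost(prop) - logpost(cur):
            for n in names:
                self.hyper[n] = prop[n]
            self.mh_accept += 1
        self._refresh_w()

    def iterate(self, rng: np.random.Generator) -> None:
        self.update_linear(rng)
        for lev in LEVELS:
            self.update_rw2_level(lev, rng)
        self.update_gamma(rng)
        self.update_offsets(rng)
        self.update_variances(rng)
        self.update_residual_variances(rng)


def _chain_factor(i: int) -> float:
    exp = (i + 1) // 2 * (1 if i % 2 == 1 else -1)
    return 4.0**exp


def fit(
    observations: pd.DataFrame,
    hierarchy: CountryIndex,
    model_config: ModelConfig | None = None,
    mcmc: MCMCConfig | None = None,
    fixed_hyper: Mapping[str, float] | None = None,
    check: bool = True,
) -> PosteriorDraws:
    """Fit the model to a single-sex analysis set by blocked Gibbs MCMC.

    ``observations`` must carry ``birth_cohort``/``mid_age`` columns (run
    :func:`heightcurve.studies.filter_analysis_set` first; it is applied
    automatically if the columns are absent).  Countries in the hierarchy
    without observations are still sampled — their effects come from the
    hierarchical prior given the current variances, which is exactly the
    partial-pooling prediction for a no-data country.

    Fully reproducible given ``mcmc.seed``.  If ``check`` is true, the
    Brooks–Gelman–Rubin diagnostic is evaluated on the result and its
    outcome stored in ``converged`` (never silently discarded).
    """
    model_config = model_config or ModelConfig()
    mcmc = mcmc or MCMCConfig()
    if "birth_cohort" not in observations.columns:
        observations, _ = filter_analysis_set(observations)
    if len(observations) == 0:
        raise ValueError("no observations to fit")
    sexes = set(observations["sex"])
    if len(sexes) != 1:
        raise ValueError(f"fit expects a single-sex table, got {sorted(sexes)}")
    sex = sexes.pop()
    unknown = set(observations["country"]) - set(hierarchy.countries)
    if unknown:
        raise ValueError(f"countries absent from hierarchy: {sorted(unknown)}")

    sampler = _GibbsSampler(observations, hierarchy, model_config, fixed_hyper)
    nc, ns = mcmc.n_chains, mcmc.n_samples
    lin = np.empty((nc, ns, sampler.m))
    v = {lev: np.empty((nc, ns, sampler.n_units[lev], sampler.G2)) for lev in LEVELS}
    gamma = np.empty((nc, ns))
    b = np.empty((nc, ns, sampler.J))
    hyper = np.empty((nc, ns, len(HYPER_NAMES)))

    seeds = np.random.SeedSequence(mcmc.seed).spawn(nc)
    for chain in range(nc):
        rng = np.random.default_rng(seeds[chain])
        sampler.init_state(_chain_factor(chain))
        for _ in range(mcmc.n_burnin):
            sampler.iterate(rng)
        for s in range(ns):
            for _ in range(mcmc.thin):
                sampler.iterate(rng)
            lin[chain, s] = sampler.lin
            for lev in LEVELS:
                v[lev][chain, s] = sampler.v[lev]
            gamma[chain, s] = sampler.gamma
            b[chain, s] = sampler.b
            hyper[chain, s] = [sampler.hyper[n] for n in HYPER_NAMES]

    draws = PosteriorDraws(
        sex=sex,
        hierarchy=hierarchy,
        grid=model_config.grid,
        Z=sampler.Z,
        lin=lin,
        v=v,
        gamma=gamma,
        b=b,
        hyper=hyper,
        study_ids=sampler.study_ids,
        study_coverage=sampler.study_cov,
        seed=mcmc.seed,
        config=model_config,
        mcmc=mcmc,
    )
    if check and nc >= 2:
        report = check_convergence(draws, threshold=mcmc.psrf_threshold)
        draws.converged = bool(report.converged)
    return draws


# ---------------------------------------------------------------------
# Convergence diagnostics
# ---------------------------------------------------------------------


@dataclasses.dataclass
class ConvergenceReport:
    table: pd.DataFrame  # parameter, psrf, flagged
    converged: bool
    threshold: float
    traces: Mapping[str, np.ndarray]  # parameter -> (chains, samples)

    @property
    def flagged(self) -> list[str]:
        return self.table.loc[self.table["flagged"], "parameter"].tolist()


def psrf(chains: np.ndarray) -> float:
    """Brooks–Gelman–Rubin potential scale reduction factor.

    ``chains`` has shape (n_chains, n_samples).  Between/within variance
    ratio sqrt(((n-1)/n W + B/n)/W); values near 1 indicate convergence.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("PSRF needs >= 2 chains")
    m, n = chains.shape
    if n < 2:
        raise ValueError("PSRF needs >= 2 samples per chain")
    W = chains.var(axis=1, ddof=1).mean()
    B_over_n = chains.mean(axis=1).var(ddof=1)
    if W <= 0:
        return 1.0
    var_plus = (n - 1) / n * W + B_over_n
    return float(np.sqrt(var_plus / W))


def check_convergence(
    draws: PosteriorDraws,
    threshold: float | None = None,
    cohorts: Sequence[float] | None = None,
) -> ConvergenceReport:
    """PSRF per scalar summary, plus trace series for inspection.

    Summaries: mean height at age 18 at selected cohorts for every country,
    the age-drift slope gamma, and the log residual/offset variances.
    """
    threshold = threshold or draws.mcmc.psrf_threshold
    if draws.n_chains < 2:
        raise ValueError("convergence check needs >= 2 chains")
    grid = draws.grid
    if cohorts is None:
        cohorts = [grid.years[0], grid.t0, grid.years[-1]]
    rows = []
    traces: dict[str, np.ndarray] = {}
    for country in draws.hierarchy.countries:
        h = draws.height_draws(country, cohorts)  # (n_draws, k)
        h = h.reshape(draws.n_chains, draws.n_samples, -1)
        for k, t in enumerate(cohorts):
            name = f"height[{country},{t:.0f}]"
            rows.append((name, psrf(h[:, :, k])))
    traces["gamma"] = draws.gamma
    rows.append(("gamma", psrf(draws.gamma)))
    for hname in ("omega2", "nu2_subnational", "nu2_community", "tau2_subnational"):
        arr = draws.hyper_draws(hname)
        if np.all(arr == arr.flat[0]):  # fixed by the caller
            continue
        traces[hname] = arr
        rows.append((f"log_{hname}", psrf(np.log(arr))))
    table = pd.DataFrame(rows, columns=["parameter", "psrf"])
    table["flagged"] = table["psrf"] > threshold
    return ConvergenceReport(
        table=table,
        converged=not table["flagged"].any(),
        threshold=threshold,
        traces=traces,
    )


# ---------------------------------------------------------------------
# Posterior summaries and predictions
# ---------------------------------------------------------------------


def summarize(
    draws: PosteriorDraws,
    cohorts: Sequence[float] | None = None,
    countries: Sequence[str] | None = None,
    age: float = 18.0,
) -> pd.DataFrame:
    """Posterior mean and 2.5th–97.5th percentile interval per country x cohort.

    Population-level prediction (study offset zero) at age 18 by default.
    """
    grid = draws.grid
    cohorts = np.atleast_1d(
        np.asarray(grid.years if cohorts is None else cohorts, dtype=float)
    )
    countries = list(countries) if countries is not None else list(draws.hierarchy.countries)
    frames = []
    for country in countries:
        h = draws.height_draws(country, cohorts, age=age)
        lo, hi = np.percentile(h, [2.5, 97.5], axis=0)
        frames.append(
            pd.DataFrame(
                {
                    "country": country,
                    "sex": draws.sex,
                    "birth_cohort": cohorts,
                    "mean_cm": h.mean(axis=0),
                    "lo_cm": lo,
                    "hi_cm": hi,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def predict_observations(
    draws: PosteriorDraws,
    observations: pd.DataFrame,
    rng: np.random.Generator | None = None,
    mode: str = "observation",
) -> pd.DataFrame:
    """Posterior predictions for observation rows (e.g. held-out data).

    The point estimate is the posterior mean of the population-level mean
    height at the row's cohort and age.  In ``observation`` mode the
    prediction interval additionally integrates study-offset uncertainty
    (a fresh offset per study per draw, shared across the study's rows)
    and residual noise se^2 + omega^2 + nu^2; in ``population`` mode the
    interval covers the population mean only.

    Returns a copy of ``observations`` with ``est_cm, lo_cm, hi_cm``.
    """
    if mode not in ("observation", "population"):
        raise ValueError("mode must be 'observation' or 'population'")
    rng = rng or np.random.default_rng(0)
    if "birth_cohort" not in observations.columns:
        observations, _ = filter_analysis_set(observations)
    obs = observations.reset_index(drop=True)
    nd = draws.n_draws
    mu = np.empty((nd, len(obs)))
    for country, grp in obs.groupby("country", sort=False):
        h = draws.height_draws(country, grp["birth_cohort"].to_numpy())
        gam = draws.gamma.reshape(nd)
        mu[:, grp.index] = h + gam[:, None] * (grp["mid_age"].to_numpy() - 18.0)[None, :]
    est = mu.mean(axis=0)

    if mode == "observation":
        tau2_sn = draws.hyper_draws("tau2_subnational").reshape(nd)
        tau2_co = draws.hyper_draws("tau2_community").reshape(nd)
        nu2_sn = draws.hyper_draws("nu2_subnational").reshape(nd)
        nu2_co = draws.hyper_draws("nu2_community").reshape(nd)
        omega2 = draws.hyper_draws("omega2").reshape(nd)
        for sid, grp in obs.groupby("study_id", sort=False):
            cov = grp["coverage"].iloc[0]
            if cov == "national":
                boff = np.zeros(nd)
            else:
                tau2 = tau2_sn if cov == "subnational" else tau2_co
                boff = rng.standard_normal(nd) * np.sqrt(tau2)
            nu2 = (
                np.zeros(nd)
                if cov == "national"
                else (nu2_sn if cov == "subnational" else nu2_co)
            )
            se2 = grp["se_cm"].to_numpy(dtype=float) ** 2
            noise = rng.standard_normal((nd, len(grp))) * np.sqrt(
                se2[None, :] + omega2[:, None] + nu2[:, None]
            )
            mu[:, grp.index] += boff[:, None] + noise
    lo, hi = np.percentile(mu, [2.5, 97.5], axis=0)
    out = obs.copy()
    out["est_cm"] = est
    out["lo_cm"] = lo
    out["hi_cm"] = hi
    return out
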