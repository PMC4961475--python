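"""Model definition: mean function, hierarchical priors, RW2 trend priors.

Mean height for an observation from country c, birth cohort t, measured at
age a, in study j:

    mu = (a0 + a_g + a_r + a_c) + (b0 + b_g + b_r + b_c) (t - t0)
         + [u_world + u_g + u_r + u_c](t) + gamma (a - 18) + offset_j

where the a/b terms are hierarchical intercepts and linear cohort slopes
(world, super-region, region, country), the u terms are non-linear cohort
components with second-order random-walk (RW2) smoothness priors on a fixed
cohort grid, gamma is the linear age-drift slope, and offset_j is a random
study offset for non-nationally-representative sources (zero for national
ones).  Observations carry sampling variance se^2 plus a global residual
variance and coverage-specific extra variance.

Each RW2 vector carries two linear constraints (zero sum, zero linear
moment) so the non-linear component is identified against the explicit
intercept and slope.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from heightcurve.studies import CountryIndex

RW2_CONSTRAINT_TOL = 1e-8


@dataclasses.dataclass(frozen=True)
class CohortGrid:
    """Regular grid of birth-cohort years with a centering reference t0."""

    start: int = 1896
    stop: int = 1996
    step: int = 1
    t0: float = 1946.0

    def __post_init__(self) -> None:
        if (self.stop - self.start) % self.step != 0:
            raise ValueError("grid step must divide the grid span")
        if self.size < 3:
            raise ValueError("cohort grid needs at least 3 points")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start, self.stop + 1, self.step, dtype=float)

    @property
    def size(self) -> int:
        return (self.stop - self.start) // self.step + 1

    def interp_weights(self, t) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Indices and weights for linear interpolation of grid vectors at t.

        Returns (i0, w0, w1) with value(t) = w0*u[i0] + w1*u[i0+1].  Cohorts
        must lie within the grid span; grid points land exactly on a node.
        """
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if (t < self.start).any() or (t > self.stop).any():
            raise ValueError("cohort outside the model grid")
        pos = (t - self.start) / self.step
        i0 = np.minimum(pos.astype(int), self.size - 2)
        w1 = pos - i0
        return i0, 1.0 - w1, w1


def rw2_quadratic_form(u) -> float:
    """Sum of squared second differences, the RW2 log-density kernel.

    The kernel annihilates constant and linear sequences, penalising only
    curvature.
    """
    u = np.asarray(u, dtype=float)
    if u.ndim != 1 or u.size < 3:
        raise ValueError("RW2 quadratic form needs a vector of length >= 3")
    d2 = np.diff(u, n=2)
    return float(d2 @ d2)


def rw2_structure_matrix(size: int) -> np.ndarray:
    """Dense structure matrix K = D'D with D the second-difference operator."""
    if size < 3:
        raise ValueError("RW2 structure matrix needs size >= 3")
    D = np.zeros((size - 2, size))
    for i in range(size - 2):
        D[i, i : i + 3] = (1.0, -2.0, 1.0)
    return D.T @ D


def _constraint_rows(size: int) -> np.ndarray:
    idx = np.arange(size, dtype=float)
    return np.vstack([np.ones(size), idx - idx.mean()])


def constrain_rw2(u) -> np.ndarray:
    """Project a grid vector onto {v : sum(v) = 0, sum(t*v) = 0}.

    Removes the constant and linear span, leaving the identifiable
    non-linear part.  Idempotent.
    """
    u = np.asarray(u, dtype=float)
    A = _constraint_rows(u.size)
    coef = np.linalg.solve(A @ A.T, A @ u)
    return u - A.T @ coef


def rw2_constraint_ok(u, tol: float = RW2_CONSTRAINT_TOL) -> bool:
    u = np.asarray(u, dtype=float)
    A = _constraint_rows(u.size)
    return bool(np.all(np.abs(A @ u) <= tol * max(1.0, np.abs(u).max())))


def constraint_basis(size: int) -> np.ndarray:
    """Orthonormal basis Z (size x size-2) of the doubly-constrained subspace.

    Columns span the orthogonal complement of {constant, linear}; any
    constrained RW2 vector is u = Z v, and Z'KZ is positive definite.
    """
    A = _constraint_rows(size)
    # Null space of A via full QR of A'.
    q, _ = np.linalg.qr(A.T, mode="complete")
    return q[:, 2:]


@dataclasses.dataclass
class ModelParams:
    """One point in effect space (all units of one sex's model).

    RW2 vectors are stored on the full grid; hierarchical deviations are
    keyed by unit code.  Study offsets are keyed by study_id and are zero
    for national studies.
    """

    alpha0: float
    beta0: float
    gamma: float
    alpha_g: Mapping[str, float]
    alpha_r: Mapping[str, float]
    alpha_c: Mapping[str, float]
    beta_g: Mapping[str, float]
    beta_r: Mapping[str, float]
    beta_c: Mapping[str, float]
    u_glob: np.ndarray
    u_g: Mapping[str, np.ndarray]
    u_r: Mapping[str, np.ndarray]
    u_c: Mapping[str, np.ndarray]
    offsets: Mapping[str, float] = dataclasses.field(default_factory=dict)
    offset_coverage: Mapping[str, str] = dataclasses.field(default_factory=dict)

    def rw2_vectors(self):
        yield self.u_glob
        for d in (self.u_g, self.u_r, self.u_c):
            yield from d.values()

    def check_constraints(self, tol: float = RW2_CONSTRAINT_TOL) -> None:
        for u in self.rw2_vectors():
            if not rw2_constraint_ok(u, tol):
                raise ValueError("RW2 vector violates its linear constraints")

    @classmethod
    def zeros(cls, hierarchy: CountryIndex, grid: CohortGrid, **kwargs) -> "ModelParams":
        z = lambda keys: {k: 0.0 for k in keys}
        zu = lambda keys: {k: np.zeros(grid.size) for k in keys}
        base = dict(
            alpha0=0.0,
            beta0=0.0,
            gamma=0.0,
            alpha_g=z(hierarchy.super_regions),
            alpha_r=z(hierarchy.regions),
            alpha_c=z(hierarchy.countries),
            beta_g=z(hierarchy.super_regions),
            beta_r=z(hierarchy.regions),
            beta_c=z(hierarchy.countries),
            u_glob=np.zeros(grid.size),
            u_g=zu(hierarchy.super_regions),
            u_r=zu(hierarchy.regions),
            u_c=zu(hierarchy.countries),
        )
        base.update(kwargs)
        return cls(**base)


@dataclasses.dataclass
class HyperParams:
    """Variance parameters (all on the variance scale, cm^2 except slopes).

    sigma2_* are hierarchical deviation variances per level; rw2_var_* are
    RW2 innovation variances per level (shared across units within a
    level); tau2_* are study-offset variances; nu2_* coverage-specific
    extra residual variances (national fixed at zero); omega2 the global
    residual variance.
    """

    sigma2_alpha: Mapping[str, float]  # keys: super_region, region, country
    sigma2_beta: Mapping[str, float]
    rw2_var: Mapping[str, float]  # keys: world, super_region, region, country
    tau2: Mapping[str, float]  # keys: subnational, community
    nu2: Mapping[str, float]  # keys: subnational, community
    omega2: float

    def check(self) -> None:
        for m in (self.sigma2_alpha, self.sigma2_beta, self.rw2_var, self.tau2, self.nu2):
            if any(v < 0 for v in m.values()):
                raise ValueError("variances must be non-negative")
        if self.omega2 < 0:
            raise ValueError("omega2 must be non-negative")

    def extra_var(self, coverage: str) -> float:
        return 0.0 if coverage == "national" else float(self.nu2[coverage])


@dataclasses.dataclass
class ModelConfig:
    """Grid bounds and prior scales; the defaults are weakly informative.

    Inverse-gamma hyperpriors are parameterised (shape, scale) and scale-
    matched to each parameter type: intercept deviations live on a cm
    scale, slope deviations on cm/yr (~0.01), RW2 innovations are small
    curvature increments.
    """

    grid: CohortGrid = dataclasses.field(default_factory=CohortGrid)
    alpha0_prior_var: float = 1.0e4
    beta0_prior_var: float = 1.0
    gamma_prior_var: float = 1.0
    ig_shape: float = 1.0
    ig_scale_sigma2_alpha: float = 0.1
    ig_scale_sigma2_beta: float = 1.0e-4
    ig_scale_rw2: float = 1.0e-4
    ig_scale_tau2: float = 0.1
    ig_scale_nu2: float = 0.05
    ig_scale_omega2: float = 0.05

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid"] = dataclasses.asdict(self.grid)
        return d


def _ig_logpdf(x: float, shape: float, scale: float) -> float:
    if x <= 0:
        return -np.inf
    return -(shape + 1.0) * np.log(x) - scale / x


def mean_height(
    params: ModelParams,
    hierarchy: CountryIndex,
    grid: CohortGrid,
    country: str,
    cohort: float,
    age: float = 18.0,
    coverage: str = "national",
    study_id: str | None = None,
) -> float:
    """Model mean height (cm) for one country/cohort/age cell.

    RW2 vectors are evaluated at half-integer cohorts by linear
    interpolation between adjacent grid nodes.  The study offset enters
    only for non-national studies whose id has an offset; population-level
    prediction (the default) uses offset zero.
    """
    if age < 18:
        raise ValueError("age must be >= 18")
    region = hierarchy.region_of[country]
    sreg = hierarchy.super_region_of[region]
    i0, w0, w1 = grid.interp_weights(cohort)
    i0, w0, w1 = int(i0[0]), float(w0[0]), float(w1[0])

    def at(u):
        return w0 * u[i0] + w1 * u[i0 + 1]

    a = params.alpha0 + params.alpha_g[sreg] + params.alpha_r[region] + params.alpha_c[country]
    b = params.beta0 + params.beta_g[sreg] + params.beta_r[region] + params.beta_c[country]
    u = at(params.u_glob) + at(params.u_g[sreg]) + at(params.u_r[region]) + at(params.u_c[country])
    mu = a + b * (float(cohort) - grid.t0) + u + params.gamma * (float(age) - 18.0)
    if coverage != "national" and study_id is not None:
        mu += float(params.offsets.get(study_id, 0.0))
    return float(mu)


def log_likelihood(
    params: ModelParams,
    hyper: HyperParams,
    observations: pd.DataFrame,
    hierarchy: CountryIndex,
    grid: CohortGrid,
) -> float:
    """Gaussian log-likelihood of an analysis-set observation table.

    Each row contributes logN(y | mu, se^2 + omega^2 + nu^2_coverage) with
    mu the model mean including the row's study offset.
    """
    total = 0.0
    for _, row in observations.iterrows():
        cohort = row["birth_cohort"] if "birth_cohort" in row else None
        if cohort is None:
            raise ValueError("observations must carry birth_cohort (run filter_analysis_set)")
        age = row["mid_age"]
        mu = mean_height(
            params,
            hierarchy,
            grid,
            row["country"],
            cohort,
            age,
            coverage=row["coverage"],
            study_id=str(row["study_id"]),
        )
        v = float(row["se_cm"]) ** 2 + hyper.omega2 + hyper.extra_var(row["coverage"])
        if v <= 0:
            raise ValueError("non-positive total observation variance")
        resid = float(row["mean_cm"]) - mu
        total += -0.5 * (np.log(2.0 * np.pi * v) + resid * resid / v)
    return float(total)


def log_prior(
    params: ModelParams,
    hyper: HyperParams,
    config: ModelConfig,
) -> float:
    """Joint log-density of effects given variances, plus hyperpriors.

    Normal kernels for the hierarchical intercept/slope deviations and
    study offsets, RW2 kernels -1/2 * (1/var) * quad_form(u) per unit, a
    diffuse normal on the world line and gamma, and inverse-gamma
    hyperpriors on every variance.  Constant terms independent of all
    parameters are dropped; normalising terms in the variances are kept so
    hyperparameter conditionals are correct.
    """
    params.check_constraints()
    hyper.check()
    lp = 0.0
    lp += -0.5 * params.alpha0**2 / config.alpha0_prior_var
    lp += -0.5 * params.beta0**2 / config.beta0_prior_var
    lp += -0.5 * params.gamma**2 / config.gamma_prior_var

    def normal_block(values, var):
        vals = np.asarray(list(values), dtype=float)
        if var <= 0:
            return -np.inf if np.any(vals != 0) else 0.0
        return -0.5 * (vals**2).sum() / var - 0.5 * vals.size * np.log(var)

    level_keys = ("super_region", "region", "country")
    for key, dev in zip(level_keys, (params.alpha_g, params.alpha_r, params.alpha_c)):
        lp += normal_block(dev.values(), hyper.sigma2_alpha[key])
    for key, dev in zip(level_keys, (params.beta_g, params.beta_r, params.beta_c)):
        lp += normal_block(dev.values(), hyper.sigma2_beta[key])

    rank = params.u_glob.size - 2
    for key, units in (
        ("world", [params.u_glob]),
        ("super_region", list(params.u_g.values())),
        ("region", list(params.u_r.values())),
        ("country", list(params.u_c.values())),
    ):
        var = hyper.rw2_var[key]
        for u in units:
            q = rw2_quadratic_form(u)
            if var <= 0:
                if q > 1e-12:
                    return -np.inf
                continue
            lp += -0.5 * q / var - 0.5 * rank * np.log(var)

    lp += _offsets_log_prior(params, hyper)

    sh = config.ig_shape
    for key in level_keys:
        lp += _ig_logpdf(hyper.sigma2_alpha[key], sh, config.ig_scale_sigma2_alpha)
        lp += _ig_logpdf(hyper.sigma2_beta[key], sh, config.ig_scale_sigma2_beta)
    for key in ("world", "super_region", "region", "country"):
        lp += _ig_logpdf(hyper.rw2_var[key], sh, config.ig_scale_rw2)
    for cov in ("subnational", "community"):
        lp += _ig_logpdf(hyper.tau2[cov], sh, config.ig_scale_tau2)
        lp += _ig_logpdf(hyper.nu2[cov], sh, config.ig_scale_nu2)
    lp += _ig_logpdf(hyper.omega2, sh, config.ig_scale_omega2)
    return float(lp)


def _offsets_log_prior(params: ModelParams, hyper: HyperParams) -> float:
    """Normal prior for study offsets; coverage per study from offset_coverage."""
    cov_of = params.offset_coverage
    lp = 0.0
    for sid, b in params.offsets.items():
        cov = cov_of.get(sid, "subnational") if cov_of else "subnational"
        var = hyper.tau2[cov]
        if var <= 0:
            if b != 0:
                return -np.inf
            continue
        lp += -0.5 * b * b / var - 0.5 * np.log(var)
    return lp
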