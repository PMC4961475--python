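# Methods

## The estimation problem

The quantity of interest is mean height at age 18, `H_{c,s}(t)`, for each
country `c`, sex `s` and birth cohort `t` on a fixed grid (1896–1996 by
default). The data are study-level summaries: one row per study × sex ×
standard age group (18, 19, 20–29, then ten-year groups to 80+) carrying
a mean measured height, its standard error and the cell sample size, plus
study metadata (country, survey year, national/subnational/community
coverage, urban/rural scope). Self-reported heights are excluded, as are
rows whose implied birth cohort (survey year minus the age group's
mid-age) falls outside the cohort range or whose mid-age is below 18.
Height level itself is never grounds for exclusion. Urban/rural scope is
carried as metadata only and does not enter the model.

The mid-age of the open-ended 80+ group is fixed at 85.0 (the symmetric
ten-year convention) and is configurable; ten-year groups use the closed
integer-range midpoint ((20+29)/2 = 24.5), which is what makes cohorts
half-integers.

## Model

Writing `t0` for the grid reference year (1946, the grid midpoint, for
numerical conditioning), the mean for observation `i` in country `c`,
study `j` is

    mu_i = A_c + B_c (t_i - t0) + U_c(t_i) + gamma (a_i - 18) + b_j

with

* `A_c = alpha0 + alpha_g + alpha_r + alpha_c` and likewise `B_c`: world
  intercept/slope plus normal deviations at super-region, region and
  country level, one variance per level and term
  (`sigma2_alpha_level`, `sigma2_beta_level`).
* `U_c(t) = u_world(t) + u_g(t) + u_r(t) + u_c(t)`: second-order
  random-walk vectors on the cohort grid, one per unit per level, with
  one innovation variance per level shared across that level's units.
  The RW2 kernel is `-1/(2 var) * sum_t (u_{t+1} - 2 u_t + u_{t-1})^2`;
  it leaves constant and linear sequences unpenalised, so each vector is
  doubly constrained (zero sum and zero linear moment) to separate it
  from the explicit intercept and slope. Off-grid (half-integer) cohorts
  evaluate the vectors by linear interpolation between adjacent nodes.
* `gamma`: a single linear age-drift slope per sex. The estimated ageing
  effect in population data is close to linear (about -0.2 cm/decade for
  men, -0.3 for women), so a linear term is used rather than a spline;
  survivorship effects are absorbed by the same term.
* `b_j ~ N(0, tau2_cov)` for subnational and community studies (zero for
  national ones), modelling systematic deviation of non-representative
  sampling frames; their extra residual dispersion enters as `nu2_cov`
  in the observation variance `se_i^2 + omega2 + nu2_cov`. National
  studies carry no extra variance beyond the global residual `omega2`.

Priors: diffuse normals on `alpha0` (SD 100 cm), `beta0` (SD 1 cm/yr) and
`gamma` (SD 1 cm/yr); scale-matched inverse-gamma hyperpriors (shape 1)
on every variance, with scales 0.1 cm² for intercept-deviation variances,
1e-4 (cm/yr)² for slope-deviation variances, 1e-4 for RW2 innovation
variances, 0.1 cm² for study-offset variances and 0.05 cm² for the
residual variances. These are weakly informative at the scales the
corresponding parameters live on; all are configurable (`ModelConfig`).

Design choices that were genuinely open and how they were fixed:

* One RW2 innovation variance per level, shared across units within the
  level (rather than per-country precisions): countries with sparse data
  then borrow the smoothness scale from the rest of their level. Flagged
  as a sensitivity-analysis candidate.
* RW2 identifiability via the double linear constraint at every level.
* `nu2_national = 0` with a global `omega2 > 0`: national studies are
  treated as unbiased with only a shared non-sampling variance.
* Sex is a stratification variable, never pooled: men's and women's
  models are fitted independently.

## Sampling

The model is conditionally Gaussian given the variances, so the sampler
is a blocked Gibbs scheme:

1. the full linear block (world line plus all hierarchical deviations,
   dimension 2 + 2(G + R + C)) is drawn exactly from its multivariate
   normal full conditional via one sparse cross-product and a Cholesky
   factorisation;
2. RW2 vectors are drawn level by level. Each vector is parameterised in
   an orthonormal basis Z of the constrained subspace, where the
   constrained prior precision `Z'KZ` is positive definite, so draws are
   exact and satisfy the constraints to machine precision. Units within
   a level touch disjoint observations and are conditionally
   independent, so all units of a level are drawn simultaneously with
   batched Cholesky factorisations (the observation cross-products are
   tridiagonal in the grid because interpolation touches two nodes);
3. `gamma` and the study offsets have scalar normal conditionals;
4. hierarchical, RW2 and offset variances have conjugate inverse-gamma
   conditionals; the residual variances (`omega2`, `nu2_*`) are not
   conjugate (sampling variances differ by row) and use a joint
   random-walk Metropolis step on the log scale (step 0.15);
5. countries present in the hierarchy but absent from the data are still
   sampled — their conditionals reduce to the hierarchical prior given
   the current variances, which is exactly the partial-pooling
   prediction for a no-data country and is what the holdout experiment
   relies on.

Defaults: 4 chains, 2000 burn-in, 5000 retained draws, thinning 1;
chains start from zero effects with variances dispersed by factors
{1, 4, 1/4, 16, ...}. Convergence is monitored with the
Brooks–Gelman–Rubin PSRF on country heights at the grid ends and centre,
`gamma`, and log residual variances; the flag threshold is 1.1 (the
diagnostic's customary cutoff; fits record, never silently discard, a
non-converged state). Summaries are posterior means with 2.5th–97.5th
percentile intervals (linear interpolation between order statistics,
here and in all quantile computations).

## Synthetic world

`heightcurve.synthetic` draws ground truth from the model's own
generative structure and then simulates the survey process on top of it.
Defaults (all configurable) and their rationale:

* world lines: men 168 cm at the 1946 cohort with +0.09 cm/yr, women
  156 cm with +0.08 cm/yr — century gains near 8 cm, with
  super-region/region slope SDs (0.05, 0.02 cm/yr) spreading country
  gains over roughly 0–20 cm, the range seen in real national data.
* intercept deviation SDs 4.5 / 2.0 / 0.6 cm (super-region / region /
  country) give a cross-country spread of ~20 cm. The country-level SD
  of 0.6 cm (with slope SD 0.004 cm/yr and country RW2 amplitude
  0.25 cm) is sized so that the prediction error for a held-out, no-data
  country — which is dominated by exactly this deviation — has the
  magnitude the published validation of the full-scale analysis reports
  (median absolute errors around 0.5 cm); regional groupings are
  homogeneous by construction, which is what makes hierarchical
  prediction work at all.
* RW2 amplitudes (RMS of the constrained non-linear component) 1.5 /
  0.8 / 0.4 / 0.25 cm from world to country: visible mid-century
  accelerations and plateaus at the world and super-region level, mild
  country-specific wiggles.
* age-drift slopes -0.02 (men) and -0.03 (women) cm/yr.
* survey process: studies per country log-uniform on [3, 30] (the real
  evidence base is right-skewed, from ~2 to ~34 sources per country
  across regions, and this populates all three data-availability
  strata); coverage mix 54% national / 14% subnational / 32% community;
  survey years uniform on 1950–2015; each study measures a contiguous
  window of 2–6 standard age groups and covers both sexes with
  probability 0.75 (men-only 0.10, women-only 0.15); cell sample sizes
  log-normal (median 200, log-SD 0.7, clipped to [25, 2000]); within-cell
  SD of individual heights 7.0 cm, so se = 7/sqrt(n); non-national
  offsets N(0, 1.0²) (subnational) and N(0, 1.5²) (community) with extra
  residual SDs 0.5 and 1.0 cm. The non-national bias and extra-variance
  magnitudes are not published for the real database; these are
  placeholder scales intended for sensitivity analysis.

What the generator does *not* emulate: temporal clustering of surveys,
non-response, measurement-protocol drift, migration, or the idiosyncratic
age windows of specific real survey programmes. Passing tests on this
world therefore demonstrate correctness of the estimation machinery and
calibration *under the model's assumptions*, not robustness to the ways
real data violate them.

## Validation protocol

`validation.make_holdout_plan` withholds ~10% of countries with data,
sampled without replacement within each data-availability stratum
(data-rich: >25 cohorts with ≥5 after 1960; data-poor: ≤12 cohorts for
women, ≤8 for men; average: the rest), separately by sex, repeated five
times. `validation.run_holdout` refits on the remaining countries and
predicts every withheld observation at its actual cohort and age with
the population-level (offset-zero) mean; the prediction interval in
observation mode additionally integrates study-offset uncertainty and
residual noise, which is the right target when scoring coverage against
observed study means (a truth-scoring mode exists for simulation
studies). Errors are estimate minus held-out observed mean; values on an
interval bound count as covered.

## Problem sizes

The canonical desk-scale experiment (`experiments.run_scaled_holdout`,
also behind `scripts/acceptance.py`) uses 60 countries / 12 regions / 4
super-regions, the cohort grid thinned to every second year, five
repetitions of the 10% holdout, and 2 chains × 1500 retained draws after
500 burn-in per fit (~8 minutes on one CPU). The test suite uses smaller
worlds (6–12 countries, grid steps 2–5, hundreds of draws) chosen so the
whole suite stays well under the sampler's asymptotic regime's cost
while Monte-Carlo tolerances (3 standard errors with a conservative
effective-sample-size discount of 20 for Gibbs autocorrelation) remain
meaningful.

## Known limitations

* At desk scale, per-repetition withheld subsets contain ~2 countries
  per stratum and sex, so subset medians of prediction errors carry the
  full country-level deviation (~0.5–0.7 cm SD) rather than averaging it
  away; only the pooled and per-stratum (across-repetition) medians are
  comparable to full-scale results, and even these are noisier.
* Shared-per-level RW2 precisions may over-smooth a country whose true
  curve is unusually wiggly relative to its level.
* The Metropolis step for residual variances uses a fixed proposal
  scale; acceptance rates are reasonable across the sizes used here but
  are not adapted.
* No spatial (neighbouring-country) correlation, covariates, or
  non-normal likelihoods; complex-survey weighting is assumed to have
  been applied upstream when the study summaries were produced.
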