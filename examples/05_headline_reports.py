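"""Headline summaries: century change, country ranks, male-female gap.

The century change is computed on the posterior sample of the difference
height(1996) - height(1896), draw by draw, so its credible interval
correctly accounts for the correlation between the endpoints.
"""

from heightcurve import studies, synthetic
from heightcurve.model import CohortGrid, ModelConfig
from heightcurve.inference import MCMCConfig, fit, summarize
from heightcurve.reporting import century_change, rank_countries, sex_gap

truth, obs = synthetic.simulate_world(
    n_countries=10, n_regions=3, n_super_regions=1, seed=19
)
retained, _ = studies.filter_analysis_set(obs)
config = ModelConfig(grid=CohortGrid(step=2))
mcmc = MCMCConfig(n_chains=2, n_burnin=300, n_samples=600, seed=2)

tables = {}
draws_by_sex = {}
for sex in ("male", "female"):
    d = fit(retained[retained["sex"] == sex], truth.hierarchy, config, mcmc)
    draws_by_sex[sex] = d
    tables[sex] = summarize(d, cohorts=[1896.0, 1996.0])

country = truth.hierarchy.countries[0]
change, (lo, hi) = century_change(draws_by_sex["male"], country)
print(f"{country}, men: change 1896 -> 1996 = {change:.1f} cm (95% CrI {lo:.1f}-{hi:.1f})")

ranks = rank_countries(tables["male"], 1996.0, "male")
print("\ntallest men, 1996 cohort (rank 1 = tallest posterior mean):")
print(ranks.head(3).round(1).to_string(index=False))

gaps, summary = sex_gap(tables["male"], tables["female"], 1996.0)
print(f"\nmale-female gap at the 1996 cohort: mean {summary['mean_gap_cm']:.1f} cm,")
print(f"cross-country correlation of men's vs women's heights: {summary['correlation']:.2f}")
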