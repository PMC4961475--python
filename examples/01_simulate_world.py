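"""Generate a synthetic survey world and inspect its composition.

Builds a country -> region -> super-region hierarchy, draws a ground-truth
height surface (hierarchical linear trends plus smooth RW2 components),
and simulates a study-level survey database with the 54/14/32
national/subnational/community mix and realistic sampling error.
"""

from heightcurve import studies, synthetic

truth, obs = synthetic.simulate_world(
    n_countries=20, n_regions=5, n_super_regions=2, seed=7
)

print(f"observations: {len(obs)} rows from {obs['study_id'].nunique()} studies")
per_study = obs.drop_duplicates("study_id")
print("coverage mix (share of studies):")
print(per_study["coverage"].value_counts(normalize=True).round(3).to_string())

retained, excluded = studies.filter_analysis_set(obs)
print(f"\nanalysis set: {len(retained)} rows retained, {len(excluded)} excluded")

h = truth.height18["male"]
print("\ntruth, men: mean height at age 18 across countries")
print(f"  1896 cohort: {h[:, 0].mean():.1f} cm (range {h[:, 0].min():.1f}-{h[:, 0].max():.1f})")
print(f"  1996 cohort: {h[:, -1].mean():.1f} cm (range {h[:, -1].min():.1f}-{h[:, -1].max():.1f})")
print("cross-country spread comes mostly from region and super-region draws")
print("(few of either here); at 60 countries / 4 super-regions the generator's")
print("defaults produce the ~20 cm spread and 0-20 cm century gains seen in")
print("real national height data.")
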