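"""The deterministic data-preparation rules on hand-built rows.

Birth cohorts come from survey year minus the mid-age of the measured age
group; the analysis set keeps measured heights of adults born 1896-1996;
duplicate candidates share (country, survey year); countries are
classified into data-availability strata used to stratify validation.
"""

import pandas as pd

from heightcurve import studies

print("cohort arithmetic: survey year minus mid-age of the age group")
for year, group in [(2000, "20-29"), (1914, "18"), (2014, "18"), (1990, "80+")]:
    print(f"  survey {year}, ages {group:>5}: cohort {studies.birth_cohort(year, group)}")

rows = pd.DataFrame(
    [
        ("a", "AA", "male", "national", "mixed", 2000, "20-29", 175.0, 0.5, 900, True),
        ("b", "AA", "male", "national", "mixed", 1930, "60-69", 168.0, 0.5, 100, True),
        ("c", "AA", "male", "national", "mixed", 2000, "30-39", 174.0, 0.5, 400, False),
    ],
    columns=list(studies.OBSERVATION_COLUMNS),
)
retained, log = studies.filter_analysis_set(rows)
print(f"\nfiltering 3 rows -> {len(retained)} retained; exclusions:")
print(log.to_string(index=False))
print("(row b is a 1865.5 cohort, row c is self-reported; heights are never")
print(" a reason for exclusion)")

dups = studies.flag_duplicates(
    pd.DataFrame(
        {
            "study_id": ["s1", "s2", "s3"],
            "country": ["AA", "AA", "AA"],
            "survey_year": [1990, 1990, 1995],
        }
    )
)
print(f"\nduplicate candidates (same country and year): {len(dups)} group(s):")
print(dups[0].to_string(index=False))

series = studies.CohortSeries("AA", "female", frozenset(range(1935, 1965)))
print(
    f"\n{series.n_cohorts} cohorts, {series.n_after_1960} after 1960 ->",
    studies.classify_data_availability(series),
)
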