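"""Simulate a multi-hospital perioperative cohort with realistic
missingness and inspect its marginals.

The generator reproduces the study conditions: ~11.3% in-hospital
mortality, 186 hospitals (here scaled down), lactate missing in ~36% of
cases and albumin in ~59%, with lab missingness depending on observed
severity (sicker patients are more likely to be measured).
"""

import riskdist as rd

config = rd.GeneratorConfig(n_cases=10_000, n_hospitals=60, seed=1)
cohort, true_risks, true_model = rd.generate_cohort(config)
observed = rd.inject_missingness(cohort, config)

df = observed.df
print(f"cases: {len(df)}, hospitals: {df.hospital_id.nunique()}")
print(f"mortality: {df.died.mean():.3f} (target {config.prevalence_target})")
print("medians:", {v: round(float(df[v].median()), 2)
                   for v in ("age", "sodium", "lactate", "albumin", "bun")})
print("missingness:", {v: round(observed.missing_fraction(v), 3)
                       for v in ("lactate", "albumin", "indication")})
# Missingness tracks severity: compare ASA in measured vs unmeasured cases.
measured = df[df.lactate.notna()]["asa"].mean()
unmeasured = df[df.lactate.isna()]["asa"].mean()
print(f"mean ASA, lactate measured {measured:.2f} vs missing {unmeasured:.2f}"
      " -> unwell patients get measured more often")
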