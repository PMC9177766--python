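"""The clinical vignette: how measuring lactate and albumin updates the
predicted risk distribution.

An 81-year-old with small bowel obstruction and mildly raised urea is
first assessed before lactate/albumin are measured: the model imputes
them prospectively and predicts a wide distribution. When the labs come
back deranged (albumin 25 g/L, lactate 3.2 mmol/L), the distribution
narrows and shifts to higher risk — a confident prediction inside the
earlier, less-confident one.
"""

import warnings

import riskdist as rd
from riskdist.pipeline import run_case_study

warnings.simplefilter("ignore")

gen = rd.GeneratorConfig(n_cases=12_000, n_hospitals=60, seed=21)
cohort, _, _ = rd.generate_cohort(gen)
observed = rd.inject_missingness(cohort, gen)
bundle = rd.run_fit(rd.RunConfig(seed=22, imputation={"m_mice": 3,
                                                      "k_lab": 2}),
                    cohort=observed)

dense = rd.ImputationConfig(m_mice=14, k_lab=3, n_coef_draws=5, seed=0)
report = run_case_study(bundle, seed=0, imputation=dense)
for phase in ("pre", "post"):
    r = report[phase]
    print(f"{phase:>4}-measurement: median {r['median']:.3f}, "
          f"95% span [{r['p2.5']:.3f}, {r['p97.5']:.3f}], rdr {r['rdr']:.3f}")
print("measurement narrowed the distribution "
      f"({report['pre']['rdr']:.3f} -> {report['post']['rdr']:.3f}) and "
      "raised the median: deranged labs confirmed the pessimistic tail.")
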