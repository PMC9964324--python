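"""Kaplan-Meier prognosis for an expression-dichotomized cohort.

Simulates a 200-subject cohort whose hazard rises with a gene's expression
(log-HR 0.7 per SD), splits at the median expression, and compares the two
Kaplan-Meier curves with the log-rank test.
"""

import ferrocup as fc

cfg = fc.SurvivalSimConfig(
    n_subjects=200, log_hazard_ratio_per_sd=0.7, censoring_rate=0.2, seed=11
)
records = fc.simulate_survival(cfg)
groups = fc.dichotomize_by_expression(records)

for g in ("low", "high"):
    curve = fc.km_fit([r for r, gg in zip(records, groups) if gg == g], group=g)
    print(f"{g} expression: n={sum(1 for x in groups if x == g)}, "
          f"median survival {curve.median_survival:.2f}")

res = fc.logrank_test(records, groups)
print(f"\nlog-rank: chi-sq={res.chi_sq:.2f}, p={res.p:.3g}")
print("High expressors die sooner (shorter median survival), matching the "
      "planted positive log hazard ratio.")
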