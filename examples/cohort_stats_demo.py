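"""Cohort statistics demo.

Simulates a 200-patient breast-cancer cohort in which the p120-3/p120-1
isoform ratio rises with grade and size and carries a survival hazard, then
runs the three cohort analyses: Spearman ratio-grade correlation,
Kruskal-Wallis across size categories, and a median-split log-rank test.
"""

from cateno_iso import (
    CohortSimConfig,
    ratio_vs_size,
    simulate_cohort,
    spearman_assoc,
    survival_by_ratio,
)

records, truth = simulate_cohort(CohortSimConfig(), seed=42)

grade = spearman_assoc(records["ratio"], records["grade"])
size = ratio_vs_size(records)
surv = survival_by_ratio(records)

print(f"patients: {len(records)}, events: {int(records['event'].sum())}")
print(f"Spearman ratio vs grade: rho = {grade.rho:.3f}, p = {grade.p:.4f}")
print(f"Kruskal-Wallis ratio vs size: H = {size.H:.2f}, p = {size.p:.4f}")
print(f"log-rank, high vs low ratio: chi2 = {surv.chi2:.2f}, p = {surv.p:.2e}")
print()
print(f"The generator gave high-ratio patients a {truth['hazard_ratio']}x")
print("hazard, which the log-rank test detects; the positive rho mirrors")
print("the ratio-grade association built into the simulated strata.")
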