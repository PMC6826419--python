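"""Exon-usage demo: recover tumor/normal exon-expression folds.

Simulates a 200-samples-per-group cohort for a 14-exon gene in which
cassette exon B is included in 90% of tumor transcripts but only 28% of
normal ones, then runs the RPKM -> relative-usage -> group-ratio chain.
"""

from cateno_iso import ExonSimConfig, exon_usage_pipeline, simulate_exon_counts

table, truth = simulate_exon_counts(ExonSimConfig(), seed=42)
result = exon_usage_pipeline(table)

print("exon   tumor/normal fold   generator expectation")
for exon in ("4.1", "4.3", "A", "B", "C", "D"):
    print(f"{exon:>4}   {result.ratios[exon]:17.3f}   "
          f"{truth['expected_ratio'][exon]:21.3f}")
print()
print("A fold > 1 means the exon is included more often in tumor tissue;")
print("exon B lands near 3.2 while the unchanged exons sit near 1.0.")
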