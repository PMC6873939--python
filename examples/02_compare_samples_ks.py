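"""Compare sample compositions with the discrete KS distance.

Simulates a cohort of two healthy-like and two disease-like samples that
were clustered jointly, then compares the fraction of cells per cluster
within and between conditions.
"""

import scdiversity as sd

spec = sd.preset_scenarios(seed=11, n_cells=1500)["aml-vs-healthy"]
_, table, _ = sd.simulate_cohort(spec)

per_sample = sd.pairwise_ks(table, by="sample")
pooled = sd.pairwise_ks(table, by="condition")

print("pairwise KS distance between samples (shared 14-cluster space):")
print(per_sample.round(3))
print()
print("pooled by condition:")
print(pooled.round(3))
print()
print(f"within healthy: {per_sample.loc['healthy_1', 'healthy_2']:.3f}; "
      f"within disease: {per_sample.loc['aml_1', 'aml_2']:.3f}; "
      f"between conditions pooled: {pooled.loc['aml', 'healthy']:.3f}")
print("replicate samples of one condition are nearly indistinguishable, while")
print("conditions occupy the shared clusters very differently — the same")
print("within-small / between-large pattern the score is built to expose.")
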