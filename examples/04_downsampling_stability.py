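"""Stability of the diversity score under 50% cell downsampling.

Removes half of a sample's cells at random 1,000 times, recomputes qD at
the anchor orders each time, and summarises the absolute and
mean-normalised changes — the protocol used to establish confidence in a
diversity score before interpreting differences between samples.
"""

import scdiversity as sd

table = sd.annotation_table_from_proportions(
    sd.synthetic_data.HEALTHY_LIKE_P, n_cells=4000, seed=3
)
result = sd.downsample_spectrum(
    table, fraction=0.5, n_replicates=1000, seed=3, label="healthy-like"
)
change = sd.relative_change(result)

print("q        baseline qD   mean qD   sd      max |change| (diversity units)")
for _, row in change.summary.iterrows():
    print(f"{row['q']:<8g} {row['baseline_d']:<13.4f} {row['mean_d']:<9.4f} "
          f"{row['sd_d']:<7.4f} {row['max_abs_change']:.4f}")

worst = change.summary["max_abs_change"].max()
print(f"\nlargest movement across all orders: {worst:.3f} effective clusters,")
print("so conclusions drawn from gaps larger than that are robust to having")
print("sequenced only half the cells. Lower orders move least: richness-like")
print("scores barely notice subsampling when no cluster is rare enough to drop out.")
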