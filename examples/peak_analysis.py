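"""Characteristic-peak detection and significance tiers.

Detects the nine characteristic bands of the synthetic species profiles,
tabulates per-species band intensities, and tests each band for
between-species differences (Kruskal-Wallis), encoding p-values as tiers
0-4 (0: p > 0.05 ... 4: p <= 0.0001).
"""

from ramanid import (SyntheticConfig, generate_ramanome, preprocess_set,
                     summarize_mean_sd)
from ramanid.features import (detect_characteristic_peaks,
                              merge_peak_positions, peak_intensity_table,
                              peak_significance)
from ramanid.synthetic import PEAK_ASSIGNMENTS

data = preprocess_set(generate_ramanome(
    SyntheticConfig(n_replicates=1, cells_per_replicate=30, seed=7)))

positions = set()
for mean_spec in summarize_mean_sd(data):
    positions.update(detect_characteristic_peaks(mean_spec,
                                                 min_prominence=0.05))
merged = merge_peak_positions(positions)
print(f"detected {len(merged)} distinct peak positions across species")

table = peak_significance(
    peak_intensity_table(data, merged, half_width=5.0,
                         assignments=PEAK_ASSIGNMENTS))
cols = ["position", "p_value", "tier", "assignment"]
print(table.table[cols].to_string(index=False,
                                  float_format=lambda v: f"{v:.3g}"))
print("Tier 4 peaks (p <= 1e-4) are the bands that discriminate the species;")
print("they drive both the visual clustering and the classifiers.")
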