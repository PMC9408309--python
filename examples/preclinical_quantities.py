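"""The preclinical formulas: tumor volume, sample size, group comparison.

Prints the ellipsoid caliper volume of a 10x10x10 mm tumor, the minimum
per-group sample sizes for the behavioural (sigma = 5.5 g, delta = 8.0 g)
and tumor-growth (sigma = 145, delta = 210 mm^3) experiments at alpha = 0.05
and power 80%, and an ANOVA + Tukey-Kramer comparison of three simulated
treatment groups.
"""

import numpy as np

from oipnkit import (
    SampleSizeSpec,
    TumorMeasurement,
    group_compare,
    min_sample_size,
    tumor_volume,
)

v = tumor_volume(TumorMeasurement(length=10, width=10, thickness=10))
print(f"tumor volume (10 x 10 x 10 mm): {v:.4f} mm^3  [= pi/6 * 1000]")

for label, sigma, delta in [("von Frey threshold (g)", 5.5, 8.0), ("tumor volume (mm^3)", 145, 210)]:
    n = min_sample_size(SampleSizeSpec(sigma=sigma, delta=delta))
    print(f"minimum n per group, {label}: {n}")

rng = np.random.default_rng(0)
vehicle = rng.normal(15.0, 3.0, size=8)       # healthy withdrawal thresholds, g
drug = rng.normal(6.0, 3.0, size=8)           # hypersensitive group
drug_plus = rng.normal(12.0, 3.0, size=8)     # protected group
res = group_compare([vehicle, drug, drug_plus])
print(f"one-way ANOVA: F = {res.f_statistic:.2f}, p = {res.p_value:.2g}")
print(f"Tukey-Kramer p (vehicle vs drug):      {res.pair(0, 1):.4f}")
print(f"Tukey-Kramer p (drug vs drug+rescue):  {res.pair(1, 2):.4f}")
print("Small pairwise p-values flag which group means differ after the omnibus test.")
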