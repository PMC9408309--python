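"""Estimate a 50% paw-withdrawal threshold from an up-down filament series.

Simulates a staircase test of an animal whose true threshold is 4 g on the
standard rat filament ladder, then reduces the trial sequence to the 50%
threshold with the pattern-table estimator.
"""

from oipnkit import CHAPLAN_LADDER, simulate_updown_series, updown_threshold

series = simulate_updown_series(true_threshold_g=4.0, seed=7)
forces = [CHAPLAN_LADDER[i] for i, _ in series.trials]
print("filaments presented (g):", forces)
print("responses (X=withdraw):  ", series.responses)

res = updown_threshold(series)
print(f"estimated 50% threshold: {res.threshold_g:.2f} g (pattern {res.pattern}, k = {res.k:+.3f})")
print(
    "The estimate is the final tested force shifted by k ladder steps on the\n"
    "log10 scale; a drop in this threshold over treatment weeks indicates\n"
    "mechanical hypersensitivity."
)
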