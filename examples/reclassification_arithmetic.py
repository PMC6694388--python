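"""Worked example: hospital-category shift accounting.

Given one model's category counts (lower / no different / higher than the
national mean) and the between-model shifts, the 3x3 shift table yields
the reclassification percentage and the second model's category counts,
and the accounting identity pins down the direction of any
lower<->higher shifts. The counts below are the published AMI tallies.
"""

import pandas as pd

import payrisk as pr

counts = pd.DataFrame(
    # model B:  lower   no_different  higher
    [[161 - 24,     24,      0],   # model A: lower  (161 hospitals)
     [90,         1726,     45],   # model A: no different (1861)
     [0,            73,     86]],  # model A: higher (159)
    index=["lower", "no_different", "higher"],
    columns=["lower", "no_different", "higher"])

tab = pr.shift_table_from_counts(counts)
print(tab.counts)
print(f"hospitals: {tab.n_hospitals}")
print(f"reclassified: {tab.pct_reclassified:.1f}% "
      "(share of hospitals changing category between the two models)")
print("model B category counts:", tab.model_b_counts.to_dict())

lh, hl = pr.infer_extreme_shifts(lower_a=713, lower_b=807, lower_to_no=285,
                                 no_to_lower=365, extreme_total=14)
print(f"pneumonia lower<->higher split forced by the accounting: "
      f"{lh} lower->higher, {hl} higher->lower")
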