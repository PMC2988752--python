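"""Signed Z scores, Stouffer combination and cross-group balancing.

Builds tiny in-memory tables and walks the three primitives every later
stage is made of: converting (p, direction) to a signed deviate, combining
deviates across studies, and rescaling groups to a common mean |Z|.
"""

import pandas as pd

from zmeta import SignedZTable, balance_groups, combine_stouffer, p_to_signed_z

# One gene observed in two studies: p = 0.05 up-regulated, p = 0.01 up.
z1 = p_to_signed_z(0.05, "up")
z2 = p_to_signed_z(0.01, "up")
combined = combine_stouffer({"KLK3": [z1, z2]})
print(f"z(p=0.05, up) = {z1:.4f}")
print(f"z(p=0.01, up) = {z2:.4f}")
print(f"Stouffer-combined Z = {combined.z['KLK3']:.4f}  (sum / sqrt(2))")
# The combined Z exceeds either input: concordant evidence accumulates.

# Balancing: two cancer types whose mean |Z| are 1.87 and 2.85.  The common
# target is their mean, 2.36, and each group is rescaled onto it so that
# neither type dominates a pooled score.
groups = {
    "breast": SignedZTable.from_series(
        pd.Series([1.87, -1.87], index=["A", "B"]), 1
    ),
    "lung": SignedZTable.from_series(
        pd.Series([2.85, -2.85], index=["A", "B"]), 1
    ),
}
adjusted, factors, target = balance_groups(groups)
print(f"\ncommon target mean |Z| = {target:.2f}")
for name, factor in factors.items():
    print(f"  {name}: adjustment factor {factor:.2f} "
          f"-> mean |Z| {adjusted[name].mean_abs_z():.2f}")
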