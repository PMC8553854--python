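"""Reverse power analysis and a median split of stimulus ratings.

The minimal detectable effect tells a reader the smallest standardized
paired difference a study of a given size could have seen with 80% power.
The median split divides stimuli into high/low groups on a rating scale.
"""

import numpy as np

from erpstates import achieved_power, median_split, minimal_detectable_effect

d = minimal_detectable_effect(n=107, alpha=0.05, power=0.80)
print(f"n = 107 pairs, two-sided alpha = 0.05, power = 0.80 -> "
      f"minimal detectable d = {d:.4f} (~{d:.2f})")
print(f"round trip: achieved power at that d = {achieved_power(107, 0.05, d):.6f}")

rng = np.random.default_rng(0)
ratings = np.round(rng.uniform(1, 9, size=12), 1)
ids = [f"stim{i + 1:02d}" for i in range(12)]
res = median_split(ratings, ids)
print(f"\nratings: {dict(zip(ids, ratings.tolist()))}")
print(f"median = {res.median}")
print(f"high ({len(res.high)}): {res.high}")
print(f"low  ({len(res.low)}): {res.low}")
print("Items above the median form the high-arousal group; ties go low.")
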