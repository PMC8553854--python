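"""Permutation TANOVA: which microstates differ between conditions?

Epochs of both conditions are pooled across subjects; per microstate the
cosine between the two condition topography vectors is compared with a
3000-permutation epoch-shuffling null. Smaller cos theta = greater
topographic dissimilarity = smaller p.
"""

import numpy as np

from erpstates import segment_microstates, simulate_dataset, tanova_test, time_axis
from examples_common import demo_manifest

manifest = demo_manifest()
epoch_sets = simulate_dataset(manifest)
t = time_axis(manifest.timeline.window)

# ground-truth segmentation (see example 02 for deriving it by clustering)
seg = segment_microstates(manifest.timeline.segment_index_per_timepoint(t) + 1, t)

pool = lambda c: np.concatenate(
    [es.data for es in epoch_sets if es.condition == c], axis=0
)
result = tanova_test(pool("A"), pool("B"), seg, t, n_perm=3000, seed=11)

print(result.to_frame().to_string(index=False))
print(f"\nalpha_adj = {result.alpha_adj:.4f} (0.05 / {len(seg)} microstates)")
print(f"significant microstates: {result.significant_microstates}")
print("Only microstate 3 — the segment carrying the injected 60-degree "
      "rotation — shows a cos theta far below its null (p = 1/3001 is the "
      "smallest attainable p at 3000 permutations).")
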