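"""Localize a significant global difference to channels.

For each TANOVA-significant microstate, epoch counts are equalized and a
two-sided paired t-test runs per channel on microstate-averaged epoch data;
alpha is divided by the 30 channels (-> 0.0017). A globally significant
microstate can legitimately end with no single significant channel.
"""

import numpy as np

from erpstates import (
    channel_ttests, equalize_epochs, segment_microstates, simulate_dataset,
    tanova_test, time_axis,
)
from examples_common import demo_manifest

manifest = demo_manifest()
epoch_sets = simulate_dataset(manifest)
t = time_axis(manifest.timeline.window)
seg = segment_microstates(manifest.timeline.segment_index_per_timepoint(t) + 1, t)

pool = lambda c: np.concatenate(
    [es.data for es in epoch_sets if es.condition == c], axis=0
)
tanova = tanova_test(pool("A"), pool("B"), seg, t, n_perm=1000, seed=11)
print(f"TANOVA-significant microstates: {tanova.significant_microstates}")

eq_a, eq_b = equalize_epochs(pool("A"), pool("B"), seed=5)
table = channel_ttests(
    eq_a, eq_b, seg, t, tanova.significant_microstates,
    epoch_sets[0].montage, alpha=0.05, seed=5,
)
print(f"alpha_adj = {table.alpha_adj:.4f} (0.05 / 30 channels), "
      f"n = {table.n_equalized} equalized epochs per condition")
for ms in tanova.significant_microstates:
    sig = table.significant_channels(ms)
    print(f"MS{ms}: {len(sig)} significant channels: {sig}")
print("direction +1 means condition A more positive than B at that channel; "
      "an empty channel list would mean the difference is global in nature.")
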