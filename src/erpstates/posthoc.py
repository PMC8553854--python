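"""Channel-wise post-hoc tests for TANOVA-significant microstates.

A significant TANOVA says *that* two conditions differ in a microstate's
topography but not *where*; two-sided paired t-tests per channel localize
the difference. Epoch counts are first equalized by randomly subsampling
the larger condition. Epochs are then averaged over the microstate's
timepoints (not across epochs) and paired by epoch index across conditions
— preserved from the study design for fidelity even though the pairing is
statistically arbitrary; an unpaired variant is available. The significance
level is alpha divided by the number of channels (0.05/30 -> 0.0017).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import Segmentation
from .tanova import adjust_alpha


def equalize_epochs(
    epochs_a: np.ndarray, epochs_b: np.ndarray, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Subsample the larger condition to the smaller one's epoch count.

    Selection is without replacement, seeded; the retained epochs keep
    their original order and the smaller side is returned unchanged.
    """
    epochs_a = np.asarray(epochs_a, dtype=float)
    epochs_b = np.asarray(epochs_b, dtype=float)
    if epochs_a.shape[0] < 1 or epochs_b.shape[0] < 1:
        raise ValueError("both conditions need at least one epoch")
    n = min(epochs_a.shape[0], epochs_b.shape[0])
    rng = np.random.default_rng(seed)

    def subsample(x: np.ndarray) -> np.ndarray:
        if x.shape[0] == n:
            return x
        keep = np.sort(rng.choice(x.shape[0], size=n, replace=False))
        return x[keep]

    return subsample(epochs_a), subsample(epochs_b)


@dataclass
class PosthocTable:
    """One row per tested microstate x channel."""

    table: pd.DataFrame
    alpha: float
    alpha_adj: float
    seed: int
    n_equalized: int
    paired: bool = True

    def significant_channels(self, microstate: int) -> list[str]:
        t = self.table
        sel = t[(t["microstate"] == microstate) & t["significant"]]
        return list(sel["channel"])


def channel_ttests(
    epochs_a: np.ndarray,
    epochs_b: np.ndarray,
    segmentation: Segmentation,
    time_ms: np.ndarray,
    significant_microstates: Sequence[int],
    montage: Sequence[str],
    alpha: float = 0.05,
    seed: int = 0,
    paired: bool = True,
) -> PosthocTable:
    """Two-sided t-test per channel of every TANOVA-significant microstate.

    epochs_a/epochs_b are (n_epochs, channels, timepoints) with *equal*
    epoch counts (use :func:`equalize_epochs` first). Microstate indices
    are 1-based. Channels whose paired differences have zero variance are
    flagged degenerate and reported with direction 0 and p = 1 rather than
    crashing.
    """
    epochs_a = np.asarray(epochs_a, dtype=float)
    epochs_b = np.asarray(epochs_b, dtype=float)
    if epochs_a.shape != epochs_b.shape:
        raise ValueError("conditions must have equal epoch counts and dimensions")
    n_channels = epochs_a.shape[1]
    if len(montage) != n_channels:
        raise ValueError("montage length must equal the channel dimension")
    time_ms = np.asarray(time_ms, dtype=float)
    masks = segmentation.timepoint_masks(time_ms)
    alpha_adj = adjust_alpha(alpha, n_channels)
    rows = []
    for ms in significant_microstates:
        if not 1 <= ms <= len(masks):
            raise ValueError(f"microstate index {ms} out of range 1..{len(masks)}")
        mask = masks[ms - 1]
        a = epochs_a[:, :, mask].mean(axis=2)  # (n_epochs, n_channels)
        b = epochs_b[:, :, mask].mean(axis=2)
        diff = a - b
        degenerate = np.isclose(diff.std(axis=0), 0.0) if paired else np.zeros(
            n_channels, dtype=bool
        )
        if paired:
            with np.errstate(invalid="ignore", divide="ignore"):
                t_stat, p_val = stats.ttest_rel(a, b, axis=0)
        else:
            t_stat, p_val = stats.ttest_ind(a, b, axis=0)
        t_stat = np.asarray(t_stat, dtype=float)
        p_val = np.asarray(p_val, dtype=float)
        direction = np.sign(diff.mean(axis=0))
        # identical-sample convention: t = 0, p = 1, no direction
        t_stat[degenerate] = 0.0
        p_val[degenerate] = 1.0
        direction[degenerate] = 0.0
        for c in range(n_channels):
            rows.append(
                {
                    "microstate": ms,
                    "channel": montage[c],
                    "t": float(t_stat[c]),
                    "p": float(p_val[c]),
                    "direction": int(direction[c]),
                    "significant": bool(p_val[c] < alpha_adj),
                    "degenerate": bool(degenerate[c]),
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "microstate", "channel", "t", "p", "direction", "significant", "degenerate",
        ],
    )
    return PosthocTable(
        table=table,
        alpha=alpha,
        alpha_adj=alpha_adj,
        seed=seed,
        n_equalized=epochs_a.shape[0],
        paired=paired,
    )
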