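"""Core ERP operations: epoch averaging, baseline correction, GFP.

The global field power (GFP) of a scalp topography is its spatial standard
deviation — the population standard deviation of the potential across
channels at one timepoint (Lehmann & Skrandies). Dividing every channel by
the per-timepoint GFP removes overall amplitude so that only the *shape* of
the scalp distribution remains; all topographic statistics downstream
operate on such GFP-normalized data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: GFP below this is treated as a degenerate (flat) topography.
DEGENERATE_GFP = 1e-12

#: The 30 scalp channels of the default 10-20 montage (mastoid reference
#: excluded), in the order used throughout.
DEFAULT_MONTAGE: tuple[str, ...] = (
    "Fp1", "Fp2", "Fz", "F3", "F4", "F7", "F8", "F9", "F10",
    "Cz", "C1", "C2", "C3", "C4", "T7", "T8",
    "CPz", "CP1", "CP2", "CP3", "CP4",
    "Pz", "P1", "P2", "P3", "P4", "P7", "P8", "O1", "O2",
)


class DegenerateTopographyError(ValueError):
    """Raised when a timepoint's GFP is too small to normalize by."""


@dataclass
class EpochSet:
    """Epochs of one subject x condition cell.

    data is (n_epochs, n_channels, n_timepoints) in microvolts; time_ms is
    the shared time axis, strictly increasing with a constant step.
    """

    subject_id: str
    condition: str
    data: np.ndarray
    time_ms: np.ndarray
    montage: tuple[str, ...] = DEFAULT_MONTAGE
    sampling_rate_hz: float = 250.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("EpochSet data must be (epochs, channels, timepoints)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EpochSet data contains non-finite values")
        if len(self.montage) != self.data.shape[1]:
            raise ValueError(
                f"montage has {len(self.montage)} labels for "
                f"{self.data.shape[1]} channels"
            )
        if self.time_ms.shape != (self.data.shape[2],):
            raise ValueError("time axis length must equal the timepoint dimension")
        steps = np.diff(self.time_ms)
        if len(steps) and (np.any(steps <= 0) or not np.allclose(steps, steps[0])):
            raise ValueError("time axis must be strictly increasing with constant step")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]


@dataclass
class ERPMatrix:
    """A channels x timepoints average, optionally GFP-normalized."""

    data: np.ndarray
    time_ms: np.ndarray
    montage: tuple[str, ...] = DEFAULT_MONTAGE
    normalized: bool = False
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("ERPMatrix data must be (channels, timepoints)")
        if self.time_ms.shape != (self.data.shape[1],):
            raise ValueError("time axis length must equal the timepoint dimension")


def compute_gfp(topography: np.ndarray) -> float:
    """Global field power of one topography: population SD across channels."""
    v = np.asarray(topography, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("topography must be a vector of >= 2 channels")
    return float(np.sqrt(np.mean((v - v.mean()) ** 2)))


def gfp_curve(data: np.ndarray) -> np.ndarray:
    """Per-timepoint GFP of a (channels, timepoints) matrix."""
    data = np.asarray(data, dtype=float)
    return np.sqrt(np.mean((data - data.mean(axis=0, keepdims=True)) ** 2, axis=0))


def baseline_correct(
    epoch: np.ndarray, time_ms: np.ndarray, baseline_window: tuple[float, float]
) -> np.ndarray:
    """Subtract each channel's mean over the baseline window from all timepoints.

    The window is half-open, [t0, t1), on the epoch's own time axis.
    """
    epoch = np.asarray(epoch, dtype=float)
    time_ms = np.asarray(time_ms, dtype=float)
    t0, t1 = baseline_window
    mask = (time_ms >= t0) & (time_ms < t1)
    if not mask.any():
        raise ValueError(f"baseline window [{t0}, {t1}) selects no timepoints")
    return epoch - epoch[:, mask].mean(axis=1, keepdims=True)


def average_epochs(epochs: EpochSet) -> ERPMatrix:
    """Elementwise mean over the epoch dimension (the subject's ERP)."""
    if epochs.n_epochs < 1:
        raise ValueError("cannot average an empty EpochSet")
    return ERPMatrix(
        data=epochs.data.mean(axis=0),
        time_ms=epochs.time_ms,
        montage=epochs.montage,
        normalized=False,
        provenance=f"{epochs.subject_id}/{epochs.condition}",
    )


def normalize_by_gfp(erp: ERPMatrix, tolerance: float = DEGENERATE_GFP) -> ERPMatrix:
    """Divide every timepoint's topography by its own GFP.

    After normalization the GFP at every timepoint is exactly 1, so
    between-condition differences can only reflect a change in the spatial
    distribution of activity, never overall amplitude.
    """
    gfp = gfp_curve(erp.data)
    bad = np.flatnonzero(gfp <= tolerance)
    if bad.size:
        raise DegenerateTopographyError(
            f"GFP <= {tolerance} at timepoint index {bad[0]} "
            f"(t = {erp.time_ms[bad[0]]:g} ms): degenerate topography"
        )
    return ERPMatrix(
        data=erp.data / gfp[np.newaxis, :],
        time_ms=erp.time_ms,
        montage=erp.montage,
        normalized=True,
        provenance=erp.provenance,
    )


def grand_grandmean(
    normalized_erps: Sequence[ERPMatrix], renormalize: bool = False
) -> ERPMatrix:
    """Average GFP-normalized subject ERPs across participants and conditions.

    The result is the clustering substrate. It is *not* re-normalized by
    default (averaging unit-GFP topographies yields GFP <= 1 wherever
    subjects disagree); pass renormalize=True to restore unit GFP.
    """
    if not normalized_erps:
        raise ValueError("need at least one ERP")
    flags = {e.normalized for e in normalized_erps}
    if flags != {True}:
        raise ValueError("all inputs must be GFP-normalized (mixed or missing flags)")
    ref = normalized_erps[0]
    for e in normalized_erps[1:]:
        if e.data.shape != ref.data.shape:
            raise ValueError("shape mismatch across subject ERPs")
    mean = np.mean([e.data for e in normalized_erps], axis=0)
    out = ERPMatrix(
        data=mean,
        time_ms=ref.time_ms,
        montage=ref.montage,
        normalized=False,
        provenance="grand-grandmean",
    )
    if renormalize:
        out = normalize_by_gfp(out)
        out.provenance = "grand-grandmean"
    return out
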