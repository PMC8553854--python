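"""Topographic k-means and temporal microstate segmentation.

Timepoint topographies of the grand-grandmean ERP are clustered with
polarity-sensitive squared-Euclidean k-means (ERPs are phase-locked, so a
polarity reversal is a real difference, unlike in resting-state microstate
practice). Microstates are then the maximal runs of consecutive timepoints
assigned to one cluster — a cluster may recur, so there are usually more
microstates than clusters.

k-means details, all deterministic given the seed:

* restarts initialize centroids from k distinct timepoint topographies
  sampled without replacement;
* assignment ties break toward the lowest cluster id;
* a restart that converges with an empty cluster is re-seeded (counted in
  ``n_reseeds``);
* the best of ``n_restarts`` solutions by inner-distance sum is kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .erp import ERPMatrix
from .synthetic import SAMPLE_STEP_MS


@dataclass
class ClusterModel:
    k: int
    centroids: np.ndarray  # (k, n_channels)
    labels: np.ndarray  # (n_timepoints,), values in 1..k
    inner_distance_sum: float
    n_restarts: int
    max_iter: int
    seed: int
    n_reseeds: int = 0


@dataclass(frozen=True)
class Microstate:
    index: int  # 1-based temporal order
    start_ms: float
    end_ms: float  # half-open
    cluster_id: int

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms


@dataclass
class Segmentation:
    microstates: list[Microstate]
    window: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.microstates:
            raise ValueError("segmentation needs at least one microstate")
        if (
            self.microstates[0].start_ms != self.window[0]
            or self.microstates[-1].end_ms != self.window[1]
        ):
            raise ValueError("microstates must cover the window exactly")
        for a, b in zip(self.microstates, self.microstates[1:]):
            if a.end_ms != b.start_ms:
                raise ValueError("microstates must be contiguous")
            if a.cluster_id == b.cluster_id:
                raise ValueError("adjacent microstates must differ in cluster id")

    def __len__(self) -> int:
        return len(self.microstates)

    def durations_ms(self) -> list[float]:
        return [m.duration_ms for m in self.microstates]

    def timepoint_masks(self, time_ms: np.ndarray) -> list[np.ndarray]:
        """Boolean mask over the time axis for each microstate, in order."""
        return [
            (time_ms >= m.start_ms) & (time_ms < m.end_ms) for m in self.microstates
        ]

    def to_json_dict(self) -> dict:
        return {
            "window": list(self.window),
            "microstates": [
                {
                    "index": m.index,
                    "start_ms": m.start_ms,
                    "end_ms": m.end_ms,
                    "cluster_id": m.cluster_id,
                }
                for m in self.microstates
            ],
        }


def _lloyd(
    points: np.ndarray, init_idx: np.ndarray, max_iter: int
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """One k-means run; returns (labels0, centroids, inertia, had_empty)."""
    centroids = points[init_idx].copy()
    labels = np.full(points.shape[0], -1)
    for _ in range(max_iter):
        # squared Euclidean distances; argmin ties go to the lowest id
        d2 = ((points[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        new_labels = np.argmin(d2, axis=1)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(centroids.shape[0]):
            mask = labels == j
            if mask.any():
                centroids[j] = points[mask].mean(axis=0)
    counts = np.bincount(labels, minlength=centroids.shape[0])
    if (counts == 0).any():
        return labels, centroids, np.inf, True
    d2 = ((points[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    inertia = float(d2[np.arange(points.shape[0]), labels].sum())
    return labels, centroids, inertia, False


def _relabel_by_first_appearance(
    labels: np.ndarray, centroids: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Renumber clusters 1..k by temporal order of first appearance."""
    order = []
    for lab in labels:
        if lab not in order:
            order.append(lab)
    mapping = {old: new + 1 for new, old in enumerate(order)}
    new_labels = np.array([mapping[lab] for lab in labels])
    new_centroids = centroids[np.array(order)]
    return new_labels, new_centroids


def kmeans_topographies(
    erp: ERPMatrix,
    k: int,
    n_restarts: int = 50,
    max_iter: int = 100,
    seed: int = 0,
    max_reseeds: int = 100,
) -> ClusterModel:
    """Best-of-restarts k-means over the timepoint topographies of an ERP."""
    points = erp.data.T  # (n_timepoints, n_channels)
    n_t = points.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n_t:
        raise ValueError(f"k = {k} exceeds the number of timepoints ({n_t})")
    if n_restarts < 1 or max_iter < 1:
        raise ValueError("n_restarts and max_iter must be >= 1")
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    n_reseeds = 0
    for _ in range(n_restarts):
        reseeds_this_restart = 0
        while True:
            init_idx = rng.choice(n_t, size=k, replace=False)
            labels, centroids, inertia, had_empty = _lloyd(points, init_idx, max_iter)
            if not had_empty:
                break
            n_reseeds += 1
            reseeds_this_restart += 1
            if reseeds_this_restart > max_reseeds:
                raise RuntimeError(
                    f"k-means produced empty clusters in > {max_reseeds} re-seeded "
                    f"attempts of one restart (k = {k}, {n_t} timepoints)"
                )
        if best is None or inertia < best[0]:
            best = (inertia, labels, centroids)
    assert best is not None
    inertia, labels, centroids = best
    labels, centroids = _relabel_by_first_appearance(labels, centroids)
    return ClusterModel(
        k=k,
        centroids=centroids,
        labels=labels,
        inner_distance_sum=inertia,
        n_restarts=n_restarts,
        max_iter=max_iter,
        seed=seed,
        n_reseeds=n_reseeds,
    )


def segment_microstates(labels: np.ndarray, time_ms: np.ndarray) -> Segmentation:
    """Run-length encode cluster labels into temporally ordered microstates.

    The window is half-open; the last microstate ends one sampling step
    after the final timepoint.
    """
    labels = np.asarray(labels)
    time_ms = np.asarray(time_ms, dtype=float)
    if labels.shape != time_ms.shape:
        raise ValueError("labels and time axis must have equal length")
    step = float(time_ms[1] - time_ms[0]) if len(time_ms) > 1 else SAMPLE_STEP_MS
    boundaries = np.flatnonzero(np.diff(labels) != 0) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [len(labels)]))
    microstates = [
        Microstate(
            index=i + 1,
            start_ms=float(time_ms[s]),
            end_ms=float(time_ms[e - 1] + step),
            cluster_id=int(labels[s]),
        )
        for i, (s, e) in enumerate(zip(starts, ends))
    ]
    return Segmentation(
        microstates=microstates,
        window=(float(time_ms[0]), float(time_ms[-1] + step)),
    )


def apply_segmentation(erp: ERPMatrix, seg: Segmentation) -> np.ndarray:
    """Average an ERP over each microstate's timepoints.

    Returns (n_microstates, n_channels): one topography vector per
    microstate.
    """
    step = float(erp.time_ms[1] - erp.time_ms[0]) if len(erp.time_ms) > 1 else SAMPLE_STEP_MS
    erp_window = (float(erp.time_ms[0]), float(erp.time_ms[-1] + step))
    if erp_window != tuple(seg.window):
        raise ValueError(
            f"ERP window {erp_window} does not match segmentation window {tuple(seg.window)}"
        )
    out = np.empty((len(seg), erp.data.shape[0]))
    for i, mask in enumerate(seg.timepoint_masks(erp.time_ms)):
        out[i] = erp.data[:, mask].mean(axis=1)
    return out


def merge_short_microstates(
    labels: np.ndarray, time_ms: np.ndarray, min_duration_ms: float
) -> np.ndarray:
    """Optionally absorb runs shorter than a floor into their longer neighbor.

    Not applied by default — short microstates are legitimate in task data —
    but available for users who want the resting-state duration convention.
    """
    labels = np.asarray(labels).copy()
    step = float(time_ms[1] - time_ms[0]) if len(time_ms) > 1 else SAMPLE_STEP_MS
    while True:
        seg = segment_microstates(labels, time_ms)
        short = [
            m for m in seg.microstates
            if m.duration_ms < min_duration_ms and len(seg) > 1
        ]
        if not short:
            return labels
        m = min(short, key=lambda s: (s.duration_ms, s.index))
        i = m.index - 1
        neighbors = []
        if i > 0:
            neighbors.append(seg.microstates[i - 1])
        if i < len(seg) - 1:
            neighbors.append(seg.microstates[i + 1])
        target = max(neighbors, key=lambda s: s.duration_ms)
        mask = (time_ms >= m.start_ms) & (time_ms < m.end_ms)
        labels[mask] = target.cluster_id


@dataclass
class SweepResult:
    """Per-k diagnostics of the elbow sweep."""

    models: dict[int, ClusterModel]
    segmentations: dict[int, Segmentation]

    @property
    def table(self) -> pd.DataFrame:
        rows = [
            {
                "k": k,
                "inner_distance_sum": self.models[k].inner_distance_sum,
                "n_microstates": len(self.segmentations[k]),
                "durations_ms": self.segmentations[k].durations_ms(),
            }
            for k in sorted(self.models)
        ]
        return pd.DataFrame(rows)

    def suggest_k_elbow(self) -> int:
        """Knee heuristic: k maximizing the second difference of the
        inner-distance curve. Diagnostic only — never applied silently;
        choose k by inspecting the elbow and duration tables."""
        t = self.table.sort_values("k")
        ks = t["k"].to_numpy()
        y = t["inner_distance_sum"].to_numpy()
        if len(ks) < 3:
            return int(ks[0])
        second = y[:-2] - 2 * y[1:-1] + y[2:]
        return int(ks[1:-1][np.argmax(second)])


def sweep_k(
    erp: ERPMatrix,
    k_range: range | list[int] = range(2, 21),
    n_restarts: int = 50,
    max_iter: int = 100,
    seed: int = 0,
) -> SweepResult:
    """Cluster at every k in the range and collect elbow/duration diagnostics."""
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k range")
    models: dict[int, ClusterModel] = {}
    segs: dict[int, Segmentation] = {}
    for k in ks:
        model = kmeans_topographies(erp, k, n_restarts, max_iter, seed)
        models[k] = model
        segs[k] = segment_microstates(model.labels, erp.time_ms)
    return SweepResult(models=models, segmentations=segs)
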