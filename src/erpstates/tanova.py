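"""Permutation TANOVA: global topographic differences per microstate.

For two conditions A and B, each microstate yields one 30-dimensional (more
generally, channel-space) topography vector per condition: epochs are
averaged, the average is GFP-normalized, and the normalized ERP is averaged
over the microstate's timepoints. The test statistic is the cosine of the
angle between the two vectors,

    cos theta = (A . B) / (|A| |B|),

which is 1 for identical shapes, 0 for orthogonal ones and -1 for a polarity
reversal. The null distribution is built by pooling the epochs of both
conditions, shuffling, relabeling the first n_A as condition A, and
recomputing the statistic — the whole averaging/normalizing chain included —
for each of ``n_perm`` permutations (3000 by default). Greater dissimilarity
means *smaller* cos theta, so the p-value is the lower-tail rank of the
observed value in its null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import Segmentation
from .erp import DEGENERATE_GFP, DegenerateTopographyError

DEFAULT_N_PERM = 3000


def cos_theta(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two channel-space vectors.

    Dot product over the product of Euclidean norms; clipped to [-1, 1]
    against roundoff. Zero vectors are rejected.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be vectors of equal dimension")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cos theta is undefined for a zero vector")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def adjust_alpha(alpha: float, m: int) -> float:
    """Bonferroni-adjust a significance level over m comparisons."""
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / m


def tanova_p(cos_theta_obs: float, null: np.ndarray, convention: str = "add_one") -> float:
    """Lower-tail permutation p-value of an observed cos theta.

    ``add_one`` (default): p = (1 + #{null <= obs}) / (n_perm + 1), never
    exactly zero; with 3000 permutations the smallest attainable p is
    1/3001. ``rank``: p = #{null <= obs} / n_perm, which can reach 0. Ties
    count as <= observed (conservative).
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("null distribution is empty")
    count = int(np.sum(null <= cos_theta_obs))
    if convention == "add_one":
        return (1 + count) / (null.size + 1)
    if convention == "rank":
        return count / null.size
    raise ValueError(f"unknown p-value convention {convention!r}")


def _normalized_mean_erp(stack_sum: np.ndarray, n: int) -> np.ndarray:
    """Mean over epochs, then per-timepoint GFP normalization.

    stack_sum is the summed epoch data, (..., channels, timepoints); the
    leading axes broadcast (used for vectorized permutations).
    """
    mean = stack_sum / n
    centered = mean - mean.mean(axis=-2, keepdims=True)
    gfp = np.sqrt((centered ** 2).mean(axis=-2, keepdims=True))
    if np.any(gfp <= DEGENERATE_GFP):
        raise DegenerateTopographyError(
            "GFP-degenerate timepoint in a permutation average"
        )
    return mean / gfp


def microstate_vectors(
    epochs: np.ndarray, segmentation: Segmentation, time_ms: np.ndarray
) -> np.ndarray:
    """Condition topography vectors: average epochs, normalize GFP,
    average over each microstate's timepoints.

    epochs is (n_epochs, channels, timepoints); returns (n_microstates,
    channels).
    """
    epochs = np.asarray(epochs, dtype=float)
    if epochs.ndim != 3 or epochs.shape[0] < 1:
        raise ValueError("epochs must be a nonempty (epochs, channels, timepoints) array")
    norm = _normalized_mean_erp(epochs.sum(axis=0), epochs.shape[0])
    masks = segmentation.timepoint_masks(np.asarray(time_ms, dtype=float))
    return np.stack([norm[:, m].mean(axis=1) for m in masks])


def _microstate_cosines(
    mean_a: np.ndarray, mean_b: np.ndarray, masks: list[np.ndarray]
) -> np.ndarray:
    """cos theta per microstate for (possibly batched) normalized ERPs.

    mean_a/mean_b are (..., channels, timepoints) GFP-normalized arrays;
    returns (..., n_microstates).
    """
    out = []
    for m in masks:
        va = mean_a[..., m].mean(axis=-1)
        vb = mean_b[..., m].mean(axis=-1)
        num = (va * vb).sum(axis=-1)
        den = np.linalg.norm(va, axis=-1) * np.linalg.norm(vb, axis=-1)
        out.append(np.clip(num / den, -1.0, 1.0))
    return np.stack(out, axis=-1)


def permutation_null(
    pool_a: np.ndarray,
    pool_b: np.ndarray,
    segmentation: Segmentation,
    time_ms: np.ndarray,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    subject_ids: np.ndarray | None = None,
    chunk: int = 250,
) -> np.ndarray:
    """Epoch-shuffling null distributions of cos theta, one per microstate.

    Epochs of both conditions are pooled; per permutation the pool is
    shuffled, the first n_A epochs relabeled as condition A and the rest as
    B, each pseudo-condition is averaged, GFP-normalized and reduced to
    microstate vectors, and cos theta is recorded. Returns (n_perm,
    n_microstates); bit-reproducible given the seed.

    If ``subject_ids`` (one id per pooled epoch, A's then B's) is given, the
    shuffle is stratified within subject — an option, not the default; the
    study design pools epochs of all participants.
    """
    pool_a = np.asarray(pool_a, dtype=float)
    pool_b = np.asarray(pool_b, dtype=float)
    if pool_a.ndim != 3 or pool_b.ndim != 3 or not pool_a.shape[0] or not pool_b.shape[0]:
        raise ValueError("both pools must be nonempty (epochs, channels, timepoints)")
    if pool_a.shape[1:] != pool_b.shape[1:]:
        raise ValueError("pools must share channel and time dimensions")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    time_ms = np.asarray(time_ms, dtype=float)
    masks = segmentation.timepoint_masks(time_ms)
    n_a, n_b = pool_a.shape[0], pool_b.shape[0]
    pool = np.concatenate([pool_a, pool_b], axis=0)
    n, n_ch, n_t = pool.shape
    flat = pool.reshape(n, n_ch * n_t)
    total = flat.sum(axis=0)
    rng = np.random.default_rng(seed)
    if subject_ids is not None:
        subject_ids = np.asarray(subject_ids)
        if subject_ids.shape != (n,):
            raise ValueError("need one subject id per pooled epoch")
    nulls = np.empty((n_perm, len(masks)))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        indicator = np.zeros((m, n))
        for i in range(m):
            if subject_ids is None:
                perm = rng.permutation(n)
                indicator[i, perm[:n_a]] = 1.0
            else:
                for sid in np.unique(subject_ids):
                    rows = np.flatnonzero(subject_ids == sid)
                    k_a = int(np.sum(rows < n_a))
                    take = rng.permutation(rows)[:k_a]
                    indicator[i, take] = 1.0
        sum_a = indicator @ flat
        mean_a = _normalized_mean_erp(sum_a.reshape(m, n_ch, n_t), n_a)
        mean_b = _normalized_mean_erp(
            (total[np.newaxis] - sum_a).reshape(m, n_ch, n_t), n_b
        )
        nulls[done : done + m] = _microstate_cosines(mean_a, mean_b, masks)
        done += m
    return nulls


@dataclass
class TanovaResult:
    """Per-microstate TANOVA outcome for one condition comparison."""

    comparison: tuple[str, str]
    cos_theta_obs: np.ndarray  # (n_microstates,)
    null: np.ndarray  # (n_perm, n_microstates)
    p_values: np.ndarray
    alpha: float
    alpha_adj: float
    n_perm: int
    seed: int
    convention: str = "add_one"

    @property
    def significant(self) -> np.ndarray:
        return self.p_values < self.alpha_adj

    @property
    def significant_microstates(self) -> list[int]:
        """1-based indices of microstates significant at alpha_adj."""
        return [int(i) + 1 for i in np.flatnonzero(self.significant)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "microstate": np.arange(1, len(self.cos_theta_obs) + 1),
                "cos_theta": self.cos_theta_obs,
                "p": self.p_values,
                "alpha_adj": np.round(self.alpha_adj, 4),
                "significant": self.significant,
            }
        )


def tanova_test(
    pool_a: np.ndarray,
    pool_b: np.ndarray,
    segmentation: Segmentation,
    time_ms: np.ndarray,
    n_perm: int = DEFAULT_N_PERM,
    alpha: float = 0.05,
    seed: int = 0,
    comparison: tuple[str, str] = ("A", "B"),
    convention: str = "add_one",
    subject_ids: np.ndarray | None = None,
) -> TanovaResult:
    """Observed statistic plus permutation null and Bonferroni-adjusted test.

    The significance level is alpha divided by the number of microstates.
    """
    obs_a = microstate_vectors(pool_a, segmentation, time_ms)
    obs_b = microstate_vectors(pool_b, segmentation, time_ms)
    obs = np.array([cos_theta(a, b) for a, b in zip(obs_a, obs_b)])
    null = permutation_null(
        pool_a, pool_b, segmentation, time_ms, n_perm=n_perm, seed=seed,
        subject_ids=subject_ids,
    )
    p = np.array(
        [tanova_p(o, null[:, i], convention) for i, o in enumerate(obs)]
    )
    return TanovaResult(
        comparison=comparison,
        cos_theta_obs=obs,
        null=null,
        p_values=p,
        alpha=alpha,
        alpha_adj=adjust_alpha(alpha, len(segmentation)),
        n_perm=n_perm,
        seed=seed,
        convention=convention,
    )
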