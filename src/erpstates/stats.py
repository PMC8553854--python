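"""Statistics around the pipeline: paired-t power analysis, median split,
and small design-summary helpers.

The reverse power analysis treats the paired t-test as a one-sample t-test
on the paired differences (the standard reduction): with n pairs, the test
has n - 1 degrees of freedom and noncentrality d * sqrt(n) under effect
size d. The minimal detectable effect is the d at which the two-sided test
attains the target power, found by monotone root-finding on the
noncentral-t power function.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Sequence

import numpy as np
from scipy import optimize
from scipy import stats as sps


@dataclass(frozen=True)
class PowerQuery:
    """A reverse power question for a two-sided paired t-test."""

    n: int
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must lie in (0, 1)")


def achieved_power(n: int, alpha: float, d: float) -> float:
    """Power of the two-sided paired t-test at effect size d with n pairs."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if d < 0:
        raise ValueError("d must be >= 0")
    df = n - 1
    nc = d * np.sqrt(n)
    tcrit = sps.t.ppf(1 - alpha / 2, df)
    return float(sps.nct.sf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc))


def minimal_detectable_effect(
    q: PowerQuery | None = None,
    *,
    n: int | None = None,
    alpha: float = 0.05,
    power: float = 0.80,
) -> float:
    """Smallest standardized effect size d reaching the target power.

    Accepts either a :class:`PowerQuery` or keyword arguments. The root of
    achieved_power(n, alpha, d) - power is bracketed and solved to
    |delta power| < 1e-8.
    """
    if q is None:
        if n is None:
            raise ValueError("provide a PowerQuery or n=")
        q = PowerQuery(n=n, alpha=alpha, power=power)

    def gap(d: float) -> float:
        return achieved_power(q.n, q.alpha, d) - q.power

    hi = 0.1
    while gap(hi) < 0:
        hi *= 2
        if hi > 1e4:  # pragma: no cover - unreachable for valid queries
            raise RuntimeError("failed to bracket the effect size")
    d = float(optimize.brentq(gap, 0.0, hi, xtol=1e-12, rtol=1e-14))
    assert abs(gap(d)) < 1e-8
    return d


@dataclass
class MedianSplit:
    high: list[Hashable]
    low: list[Hashable]
    median: float
    degenerate: bool  # all values equal: the high group is empty


def median_split(
    values: Sequence[float], ids: Sequence[Hashable] | None = None
) -> MedianSplit:
    """Split items at the median: strictly above -> high, the rest -> low.

    Items exactly at the median go to the low group (a convention; with an
    even count and distinct values the median falls between items and the
    split is exact halves).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    if ids is None:
        ids = list(range(values.size))
    if len(ids) != values.size:
        raise ValueError("need one id per value")
    med = float(np.median(values))
    high = [i for i, v in zip(ids, values) if v > med]
    low = [i for i, v in zip(ids, values) if v <= med]
    return MedianSplit(high=high, low=low, median=med, degenerate=not high)


def total_overlap_ms(
    intervals_a: Sequence[tuple[float, float]],
    intervals_b: Sequence[tuple[float, float]],
) -> float:
    """Total length of the intersection of two sets of time intervals.

    Useful for quantifying how much two studies' significant microstate
    spans coincide. Intervals are half-open (start, end) in ms; each side
    is merged into a union first.
    """

    def merge(iv: Sequence[tuple[float, float]]) -> list[tuple[float, float]]:
        iv = sorted((float(a), float(b)) for a, b in iv)
        out: list[tuple[float, float]] = []
        for a, b in iv:
            if b <= a:
                raise ValueError(f"empty or inverted interval ({a}, {b})")
            if out and a <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], b))
            else:
                out.append((a, b))
        return out

    total = 0.0
    for a0, a1 in merge(intervals_a):
        for b0, b1 in merge(intervals_b):
            total += max(0.0, min(a1, b1) - max(a0, b0))
    return total


@dataclass(frozen=True)
class RetentionSummary:
    mean_per_participant: float
    retention_fraction: float


def epoch_retention(
    n_retained: int, n_recorded: int, n_participants: int
) -> RetentionSummary:
    """Artifact-rejection bookkeeping: retained epochs per participant and
    the overall retention fraction."""
    if n_participants < 1 or n_recorded < 1 or not 0 <= n_retained <= n_recorded:
        raise ValueError("invalid epoch counts")
    return RetentionSummary(
        mean_per_participant=n_retained / n_participants,
        retention_fraction=n_retained / n_recorded,
    )


def mean_trial_duration_ms(phase_means_ms: Sequence[float]) -> float:
    """Expected trial duration as the sum of the mean durations of its
    phases (e.g. jittered fixation, stimulus, inter-trial blank)."""
    phases = [float(p) for p in phase_means_ms]
    if any(p < 0 for p in phases):
        raise ValueError("phase durations must be >= 0")
    return float(sum(phases))
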