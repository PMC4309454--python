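"""Poisson test of marker distribution along the linkage map.

If mapped loci were placed at random, the number falling in a fixed-length
cM interval would be Poisson distributed with mean equal to the average
count per interval.  Each linkage group is cut independently into
half-open intervals [start, end) from position 0, the observed counts are
compared with the Poisson expectation (lambda estimated by the sample
mean), and a chi-square goodness-of-fit test is run after pooling sparse
tail categories.  The standard interval lengths are 1, 2.5, 5, 10, 20 and
40 cM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "IntervalCounts",
    "PoissonTestResult",
    "partition_map",
    "poisson_pmf",
    "poisson_gof",
    "gof_all_intervals",
    "STANDARD_INTERVALS",
]

STANDARD_INTERVALS = (1.0, 2.5, 5.0, 10.0, 20.0, 40.0)


@dataclass(frozen=True)
class IntervalCounts:
    interval_cm: float
    counts: np.ndarray             # markers per interval, all groups pooled

    @property
    def n_intervals(self) -> int:
        return len(self.counts)

    @property
    def n_markers(self) -> int:
        return int(self.counts.sum())

    @property
    def lam(self) -> float:
        return float(self.counts.mean())


@dataclass(frozen=True)
class PoissonTestResult:
    interval_cm: float
    lam: float
    observed: np.ndarray           # per pooled category
    expected: np.ndarray
    categories: list[str]
    chisq: float
    df: int
    p: float
    computable: bool = True


def partition_map(groups, interval_cm: float) -> IntervalCounts:
    """Count markers per fixed-length interval, each group cut from 0 cM.

    ``groups`` is an iterable of (positions, length) pairs; ``length`` may
    be None, in which case the last position defines the group length.  A
    marker at a bin boundary belongs to the right-open bin starting there;
    a marker exactly at the group end falls into the final partial bin.
    """
    if interval_cm <= 0:
        raise ValueError("interval length must be positive")
    all_counts = []
    for positions, length in groups:
        pos = np.sort(np.asarray(positions, dtype=float))
        L = float(length) if length is not None else (pos[-1] if len(pos) else 0.0)
        n_bins = max(int(np.ceil(L / interval_cm)), 1)
        idx = np.minimum((pos / interval_cm).astype(int), n_bins - 1)
        counts = np.bincount(idx, minlength=n_bins)
        all_counts.append(counts)
    return IntervalCounts(interval_cm, np.concatenate(all_counts)
                          if all_counts else np.zeros(0, dtype=int))


def poisson_pmf(x: int, lam: float) -> float:
    """Poisson probability of exactly x events at mean lam."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if x < 0 or int(x) != x:
        raise ValueError("x must be a non-negative integer")
    return float(stats.poisson.pmf(int(x), lam))


def poisson_gof(interval_counts: IntervalCounts, min_expected: float = 5.0) -> PoissonTestResult:
    """Chi-square goodness of fit of interval counts to a Poisson law.

    lambda is the sample mean; category x collects intervals holding
    exactly x markers, with the open tail x >= K carrying the remaining
    Poisson mass.  Tail categories are pooled upward until every expected
    frequency reaches ``min_expected``.  Degrees of freedom are the pooled
    category count minus two (one for the totals, one for the estimated
    lambda).  Fewer than three pooled categories leave the test undefined.
    """
    counts = interval_counts.counts
    n = len(counts)
    if n < 2 or counts.sum() == 0:
        return PoissonTestResult(interval_counts.interval_cm, 0.0, np.zeros(0),
                                 np.zeros(0), [], np.nan, 0, np.nan, computable=False)
    lam = interval_counts.lam
    kmax = int(counts.max())
    observed = np.bincount(counts, minlength=kmax + 2).astype(float)
    pmf = stats.poisson.pmf(np.arange(kmax + 2), lam)
    pmf[-1] = stats.poisson.sf(kmax, lam)          # open tail x > kmax
    expected = n * pmf
    # pool from the top until the tail expectation is big enough
    while len(expected) > 1 and expected[-1] < min_expected:
        expected[-2] += expected[-1]
        observed[-2] += observed[-1]
        expected = expected[:-1]
        observed = observed[:-1]
    if len(expected) < 3:
        return PoissonTestResult(interval_counts.interval_cm, lam, observed,
                                 expected, [], np.nan, 0, np.nan, computable=False)
    labels = [str(x) for x in range(len(expected) - 1)] + [f">={len(expected) - 1}"]
    chisq = float(np.sum((observed - expected) ** 2 / expected))
    df = len(expected) - 2
    p = float(stats.chi2.sf(chisq, df))
    return PoissonTestResult(interval_counts.interval_cm, lam, observed,
                             expected, labels, chisq, df, p)


def gof_all_intervals(groups, intervals=STANDARD_INTERVALS,
                       min_expected: float = 5.0) -> list[PoissonTestResult]:
    """Run the goodness-of-fit test at every standard interval length."""
    return [poisson_gof(partition_map(groups, il), min_expected) for il in intervals]
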