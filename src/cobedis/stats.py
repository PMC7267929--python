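"""Shared two-sample helpers for the comparison batteries."""

from __future__ import annotations

import math

import numpy as np
import scipy.stats

__all__ = ["two_sample_test", "sem"]


def sem(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        return float("nan")
    return float(x.std(ddof=1) / math.sqrt(len(x)))


def two_sample_test(
    a: np.ndarray, b: np.ndarray, method: str = "welch"
) -> tuple[float, float, bool]:
    """Two-sided comparison of two samples.

    Returns (statistic, p, degenerate).  ``degenerate`` marks the
    zero-variance corner: equal constant groups give statistic 0 and p = 1,
    unequal constant groups give an infinite statistic and p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0, True
        return math.copysign(math.inf, a.mean() - b.mean()), 0.0, True
    if method == "welch":
        stat, p = scipy.stats.ttest_ind(a, b, equal_var=False)
    elif method == "mannwhitney":
        stat, p = scipy.stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(stat), float(p), False
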