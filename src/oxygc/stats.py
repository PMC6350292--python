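"""Nonparametric tests: Wilcoxon signed-rank and Mann–Whitney U.

Both tests carry an exact small-sample path and a normal approximation with
continuity and tie corrections. The exact Wilcoxon null distribution is the
distribution of the positive-rank sum over all 2^n equiprobable sign
assignments; it is computed by convolution over the (mid-)ranks, which is
algebraically identical to literal enumeration but feasible throughout the
exact regime. Two-tailed p is min(1, 2 · min(lower tail, upper tail)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps

EXACT_WILCOXON_MAX = 25
EXACT_MANNWHITNEY_MAX = 20


class DegenerateDataError(ValueError):
    """All paired differences are zero — no signed ranks to test."""


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_two_tailed: float
    n_effective: int
    method: str  # "exact" | "normal-approximation"


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def _two_tailed(lower: float, upper: float) -> float:
    return min(1.0, 2.0 * min(lower, upper))


def wilcoxon_signed_rank(
    diffs: Sequence[float], exact_max: int = EXACT_WILCOXON_MAX
) -> TestResult:
    """Two-tailed Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (Wilcoxon's original convention); ties in
    |difference| get mid-ranks. Exact p by full null enumeration of sign
    assignments when n_effective ≤ ``exact_max``, otherwise a normal
    approximation with continuity and tie corrections. The statistic is the
    positive-rank sum W+.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size and not np.all(np.isfinite(d)):
        raise ValueError("differences must be finite")
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise DegenerateDataError("all differences are zero")
    ranks = _midranks(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= exact_max:
        # distribution of W+ over all 2^n sign vectors, via convolution on
        # doubled ranks (mid-ranks are half-integers)
        r2 = np.rint(2 * ranks).astype(int)
        total = int(r2.sum())
        counts = np.zeros(total + 1)
        counts[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(counts)
            shifted[r:] = counts[: total + 1 - r]
            counts = counts + shifted
        counts /= 2.0 ** n
        w2 = int(round(2 * w_plus))
        lower = float(counts[: w2 + 1].sum())
        upper = float(counts[w2:].sum())
        return TestResult(w_plus, _two_tailed(lower, upper), n, "exact")

    mean = n * (n + 1) / 4.0
    tie_counts = np.unique(ranks, return_counts=True)[1]
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(
        tie_counts ** 3 - tie_counts
    ) / 48.0
    cc = 0.5 * np.sign(w_plus - mean)
    z = (w_plus - mean - cc) / math.sqrt(var)
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return TestResult(w_plus, float(p), n, "normal-approximation")


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    exact_max: int = EXACT_MANNWHITNEY_MAX,
) -> TestResult:
    """Two-tailed Mann–Whitney U test of two independent samples.

    Ties get mid-ranks. Exact p by enumeration of all C(n1+n2, n1) group
    labellings of the pooled ranks when n1 + n2 ≤ ``exact_max``, otherwise a
    normal approximation with continuity and tie corrections. The statistic
    is U of the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    n = n1 + n2

    if n <= exact_max:
        base = n1 * (n1 + 1) / 2.0
        us = np.fromiter(
            (sum(ranks[i] for i in comb) - base for comb in combinations(range(n), n1)),
            dtype=float,
        )
        eps = 1e-9
        lower = float(np.mean(us <= u1 + eps))
        upper = float(np.mean(us >= u1 - eps))
        return TestResult(u1, _two_tailed(lower, upper), n, "exact")

    mean = n1 * n2 / 2.0
    tie_counts = np.unique(ranks, return_counts=True)[1]
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    cc = 0.5 * np.sign(u1 - mean)
    z = (u1 - mean - cc) / math.sqrt(var)
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return TestResult(u1, float(p), n, "normal-approximation")
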