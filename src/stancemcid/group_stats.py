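"""Supporting hypothesis tests.

Thin, contract-checked wrappers over scipy.stats: a two-sample rank
test for between-group comparisons, a paired signed-rank test for
T0 → follow-up change, and Fisher's exact test for 2×2 categorical
baselines.  All tests are two-sided.

The exact-vs-approximate regime is pinned down here rather than left to
library defaults: exact null distributions are used for small samples
without ties (Mann–Whitney up to n = 20 per group, Wilcoxon up to
n = 25 nonzero pairs), and the tie-corrected normal approximation
otherwise.  Zero differences are dropped before ranking; tied absolute
differences receive midranks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import DegenerateDataError, EstimationError, ValidationError

MANN_WHITNEY_EXACT_MAX_N = 20
WILCOXON_EXACT_MAX_N = 25


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n1: int
    n2: int


def _has_ties(values: np.ndarray) -> bool:
    return np.unique(values).size < values.size


def mann_whitney(group_a, group_b) -> TestResult:
    """Two-sided Mann–Whitney U test.

    Exact enumeration when both groups have at most 20 values and the
    pooled sample is tie-free; otherwise the tie-corrected normal
    approximation (with continuity correction).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise EstimationError("Mann-Whitney requires two nonempty groups")
    pooled = np.concatenate([a, b])
    exact = (
        a.size <= MANN_WHITNEY_EXACT_MAX_N
        and b.size <= MANN_WHITNEY_EXACT_MAX_N
        and not _has_ties(pooled)
    )
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method="mann_whitney",
        n1=a.size,
        n2=b.size,
    )


def wilcoxon_signed_rank(t0, d15) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired scores.

    Differences are ``d15 − t0``; zero differences are dropped before
    ranking and tied absolute differences are midranked.  The exact
    distribution is used for at most 25 nonzero, tie-free differences;
    the normal approximation otherwise.
    """
    t0 = np.asarray(t0, dtype=float)
    d15 = np.asarray(d15, dtype=float)
    if t0.shape != d15.shape:
        raise ValidationError("paired samples must have equal length")
    diffs = d15 - t0
    diffs = diffs[diffs != 0]
    if diffs.size == 0:
        raise DegenerateDataError(
            "all paired differences are zero; signed-rank test undefined"
        )
    exact = diffs.size <= WILCOXON_EXACT_MAX_N and not _has_ties(np.abs(diffs))
    res = stats.wilcoxon(
        diffs,
        zero_method="wilcox",
        alternative="two-sided",
        method="exact" if exact else "approx",
        correction=False,
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method="wilcoxon_signed_rank",
        n1=diffs.size,
        n2=diffs.size,
    )


def fisher_exact(table) -> TestResult:
    """Two-sided Fisher's exact test on a 2×2 contingency table."""
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValidationError(f"expected a 2x2 table, got shape {arr.shape}")
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
        if np.any(arr < 0) or np.any(arr != np.floor(arr)):
            raise ValidationError("counts must be non-negative integers")
        arr = arr.astype(int)
    res = stats.fisher_exact(arr, alternative="two-sided")
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method="fisher_exact",
        n1=int(arr[0].sum()),
        n2=int(arr[1].sum()),
    )
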