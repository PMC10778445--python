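"""Independent brute-force oracles used to verify the implementations.

Everything here is deliberately naive — exhaustive enumeration and
pairwise counting — and shares no code with the package.
"""

from __future__ import annotations

from itertools import combinations, product
from math import comb

import numpy as np


def pairwise_auc(pos, neg) -> float:
    """AUC as the fraction of (pos, neg) pairs with pos < neg (ties half).

    'Positive' units signal improvement through more-negative change
    scores, so a win is pos strictly below neg.
    """
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p < q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def exhaustive_youden(pos, neg):
    """Scan every candidate threshold (midpoints + sentinels) for the
    maximal J = sens + spec - 1; tie-break: highest sensitivity, then
    most negative threshold.  Returns (threshold, sens, spec, J)."""
    pooled = sorted(set(list(pos) + list(neg)))
    cands = [pooled[0] - 1.0]
    cands += [(a + b) / 2.0 for a, b in zip(pooled[:-1], pooled[1:])]
    cands += [pooled[-1] + 1.0]
    best = None
    for t in cands:
        sens = sum(1 for p in pos if p <= t) / len(pos)
        spec = sum(1 for q in neg if q > t) / len(neg)
        j = sens + spec - 1.0
        key = (j, sens, -t)  # maximize j, then sens, then prefer smaller t
        if best is None or key > best[0]:
            best = (key, t, sens, spec, j)
    _, t, sens, spec, j = best
    return t, sens, spec, j


def exact_mannwhitney_p(a, b) -> float:
    """Two-sided exact Mann-Whitney p by enumerating all group
    assignments of the pooled sample (requires no ties)."""
    a, b = list(a), list(b)
    pooled = a + b
    n1 = len(a)

    def u_stat(idx_a):
        av = [pooled[i] for i in idx_a]
        bv = [pooled[i] for i in range(len(pooled)) if i not in idx_a]
        return sum(1 for x in av for y in bv if x > y)

    observed = sum(1 for x in a for y in b if x > y)
    n_total = comb(len(pooled), n1)
    count = 0
    for idx in combinations(range(len(pooled)), n1):
        u = u_stat(set(idx))
        # two-sided: as or more extreme in either tail
        if min(u, n1 * len(b) - u) <= min(observed, n1 * len(b) - observed):
            count += 1
    return count / n_total


def exact_wilcoxon_p(diffs) -> float:
    """Two-sided exact signed-rank p by enumerating all sign patterns
    (requires nonzero, tie-free absolute differences)."""
    diffs = [d for d in diffs if d != 0]
    n = len(diffs)
    ranks = {}
    for r, d in enumerate(sorted(diffs, key=abs), start=1):
        ranks[abs(d)] = r
    w_plus_obs = sum(ranks[abs(d)] for d in diffs if d > 0)
    total = n * (n + 1) / 2
    stat_obs = min(w_plus_obs, total - w_plus_obs)
    count = 0
    for signs in product([1, -1], repeat=n):
        w = sum(ranks[abs(d)] for d, s in zip(diffs, signs) if s > 0)
        if min(w, total - w) <= stat_obs:
            count += 1
    return count / 2**n


def exact_fisher_p(table) -> float:
    """Two-sided Fisher p by hypergeometric enumeration over all tables
    with the observed margins."""
    (a, b), (c, d) = table
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def prob(x):
        # P(first cell = x) under fixed margins
        if x < max(0, col1 - row2) or x > min(row1, col1):
            return 0.0
        return comb(row1, x) * comb(row2, col1 - x) / comb(n, col1)

    p_obs = prob(a)
    total = 0.0
    for x in range(0, min(row1, col1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def mean_oracle(values) -> float:
    """Plain summation mean (no numpy), for arithmetic cross-checks."""
    values = list(values)
    total = 0.0
    for v in values:
        total += v
    return total / len(values)


def trapezoid_auc(points) -> float:
    """Area under the (1-specificity, sensitivity) polyline by the
    trapezoid rule; points may arrive in any threshold order."""
    pts = sorted((1.0 - sp, se) for _, se, sp in points)
    pts = [(0.0, 0.0)] + pts + [(1.0, 1.0)]
    area = 0.0
    for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
        area += (x1 - x0) * (y0 + y1) / 2.0
    return area


def rng_instances(n_instances, max_n, seed, allow_ties=True):
    """Random small two-group instances for oracle comparisons."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_instances):
        n1 = int(rng.integers(1, max_n + 1))
        n2 = int(rng.integers(1, max_n + 1))
        if allow_ties:
            # integer-valued changes force plenty of ties
            pos = rng.integers(-6, 3, size=n1).astype(float)
            neg = rng.integers(-4, 5, size=n2).astype(float)
        else:
            pos = rng.normal(-2, 2, size=n1)
            neg = rng.normal(0, 2, size=n2)
        out.append((pos, neg))
    return out
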