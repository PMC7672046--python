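"""Independent brute-force oracles used to check the statistical routines.

Everything here is computed from first principles (exact integer
combinatorics, full enumeration), never by calling the package's own
implementations.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p by full margin-fixed enumeration, exact rational.

    Sums the hypergeometric probabilities of every table with the observed
    margins whose probability does not exceed the observed table's.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    t = r1 + r2
    if min(r1, r2, c1, t - c1) == 0:
        return Fraction(1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    # P(table) = C(r1,x) C(r2,c1-x) / C(t,c1): numerators order probabilities.
    nums = {x: math.comb(r1, x) * math.comb(r2, c1 - x) for x in range(lo, hi + 1)}
    obs = nums[a]
    total = math.comb(t, c1)
    return Fraction(sum(n for n in nums.values() if n <= obs), total)


def hypergeom_upper_tail_oracle(k: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), exact rational."""
    total = math.comb(N, n)
    acc = 0
    for i in range(k, min(K, n) + 1):
        acc += math.comb(K, i) * math.comb(N - K, n - i)
    return Fraction(acc, total)


def bh_stepup_oracle(pvalues) -> list[float]:
    """Benjamini-Hochberg q-values straight from the step-up definition:
    q_(i) = min_{j >= i} m p_(j) / j, clipped to 1, in input order."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q_sorted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * pvalues[i] / rank)
        q_sorted[rank - 1] = running
    out = [0.0] * m
    for rank, i in enumerate(order):
        out[i] = min(q_sorted[rank], 1.0)
    return out


def wilcoxon_exact_oracle(values_a, values_b) -> float:
    """Exact two-sided rank-sum p by enumerating every rank split.

    Requires tie-free data.  p = P(|W - E W| >= |w_obs - E W|) over all
    C(n_a + n_b, n_a) equally likely assignments of ranks to group A.
    """
    pooled = sorted(values_a) + sorted(values_b)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    n_a = len(values_a)
    w_obs = sum(ranks[v] for v in values_a)
    all_ranks = list(range(1, len(pooled) + 1))
    mean_w = n_a * (len(pooled) + 1) / 2
    dev = abs(w_obs - mean_w)
    hits = total = 0
    for combo in itertools.combinations(all_ranks, n_a):
        total += 1
        if abs(sum(combo) - mean_w) >= dev - 1e-12:
            hits += 1
    return hits / total
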