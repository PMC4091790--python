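"""Independent brute-force oracles used to pin down the statistical routines.

Each oracle takes the slow, literal path (full enumeration or closed form)
and never shares code with the implementation it checks.
"""

import math
from itertools import product
from statistics import median


def rank_abs(values):
    """Average ranks of |values| computed by literal sorting."""
    order = sorted(range(len(values)), key=lambda i: abs(values[i]))
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and abs(values[order[j + 1]]) == abs(values[order[i]]):
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def wilcoxon_enumeration(differences):
    """Exact two-sided signed-rank p by enumerating all 2^n sign patterns."""
    d = [x for x in differences if x != 0]
    n = len(d)
    ranks = rank_abs(d)
    w_obs = sum(r for r, x in zip(ranks, d) if x > 0)
    sums = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in product([0, 1], repeat=n)
    ]
    total = 2**n
    le = sum(1 for s in sums if s <= w_obs + 1e-9) / total
    ge = sum(1 for s in sums if s >= w_obs - 1e-9) / total
    return min(1.0, 2.0 * min(le, ge))


def walsh_median(values):
    """Hodges-Lehmann pseudo-median by explicit double loop."""
    walsh = [
        (values[i] + values[j]) / 2
        for i in range(len(values))
        for j in range(i, len(values))
    ]
    return median(walsh)


def fisher_enumeration(a, b, c, d):
    """Two-sided Fisher exact p by summing hypergeometric point masses."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    denom = math.comb(n, c1)
    p_obs = math.comb(r1, a) * math.comb(n - r1, c1 - a) / denom
    total = 0.0
    for k in range(max(0, c1 - (n - r1)), min(r1, c1) + 1):
        pk = math.comb(r1, k) * math.comb(n - r1, c1 - k) / denom
        if pk <= p_obs * (1 + 1e-7):
            total += pk
    return min(1.0, total)


def bh_stepup(p_values):
    """BH step-up q-values computed literally from the definition."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        prev = min(prev, p_values[i] * m / rank_from_top)
        q[i] = prev
    return q


def ols_slope(x, y):
    """Closed-form simple-regression slope."""
    xbar = sum(x) / len(x)
    ybar = sum(y) / len(y)
    num = sum((xi - xbar) * (yi - ybar) for xi, yi in zip(x, y))
    den = sum((xi - xbar) ** 2 for xi in x)
    return num / den


def paired_t_p_df2(diffs):
    """Two-sided paired-t p for exactly 3 differences (df = 2, closed form)."""
    n = len(diffs)
    assert n == 3
    mean = sum(diffs) / n
    sd = math.sqrt(sum((d - mean) ** 2 for d in diffs) / (n - 1))
    t = abs(mean) / (sd / math.sqrt(n))
    return 1.0 - t / math.sqrt(2.0 + t * t)


def chi2_sf_df1(x):
    """Survival function of chi-squared with 1 df via erfc."""
    return math.erfc(math.sqrt(x / 2.0))
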