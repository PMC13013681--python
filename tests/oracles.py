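"""Independent brute-force oracles used by the unit and acceptance tests.

These are deliberately naive (pure-Python loops, full enumeration) and share
no code with the package implementation they check.
"""

import itertools
import math


def apen_bruteforce(x, m, r):
    """Approximate entropy by direct template counting, self-matches included."""
    n = len(x)

    def phi(mm):
        n_templates = n - mm + 1
        logs = []
        for i in range(n_templates):
            count = 0
            for j in range(n_templates):
                if max(abs(x[i + k] - x[j + k]) for k in range(mm)) <= r:
                    count += 1
            logs.append(math.log(count / n_templates))
        return sum(logs) / n_templates

    return phi(m) - phi(m + 1)


def sampen_bruteforce(x, m, r):
    """Sample entropy by direct ordered-pair counting, self-matches excluded.

    Returns NaN when either count is zero.
    """
    n = len(x)
    b = a = 0
    for i in range(n - m):
        for j in range(n - m):
            if i == j:
                continue
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
            if max(abs(x[i + k] - x[j + k]) for k in range(m + 1)) <= r:
                a += 1
    if a == 0 or b == 0:
        return math.nan
    return -math.log(a / b)


def wilcoxon_exact_bruteforce(differences):
    """Two-sided exact signed-rank p by enumerating all 2^n sign patterns.

    Assumes no zero differences and no tied absolute values; ranks are
    therefore the integers 1..n.  The p-value is twice the smaller tail of
    the observed W+ (capped at 1).
    """
    d = list(differences)
    n = len(d)
    order = sorted(range(n), key=lambda i: abs(d[i]))
    ranks = [0] * n
    for rank0, i in enumerate(order):
        ranks[i] = rank0 + 1
    w_obs = sum(rank for rank, di in zip(ranks, d) if di > 0)

    all_w = []
    for signs in itertools.product((0, 1), repeat=n):
        all_w.append(sum(rank for rank, s in zip(range(1, n + 1), signs) if s))
    total = len(all_w)
    lower = sum(w <= w_obs for w in all_w) / total
    upper = sum(w >= w_obs for w in all_w) / total
    return min(1.0, 2.0 * min(lower, upper))
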