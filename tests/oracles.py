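"""Independent brute-force oracles used by the test suite.

Each function recomputes a statistic from first principles (pair
enumeration, hypergeometric summation, rank-then-Pearson) so the package
implementations are checked against a route that shares no code with them.
"""

import math

import numpy as np


def concordance_u(x, y) -> float:
    """Mann-Whitney U of x vs y by O(n^2) pair counting (ties count 1/2)."""
    u = 0.0
    for xi in x:
        for yi in y:
            if xi > yi:
                u += 1.0
            elif xi == yi:
                u += 0.5
    return u


def auc_pair_fraction(scores, labels) -> float:
    """AUC as the concordant-pair fraction with the tie-1/2 convention."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    return concordance_u(pos, neg) / (len(pos) * len(neg))


def fisher_p_enumeration(table) -> float:
    """Two-sided Fisher p by full enumeration over the fixed margins."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(k):
        return (
            math.comb(r1, k) * math.comb(r2, c1 - k) / math.comb(n, c1)
        )

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = prob(a)
    return sum(prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs * (1 + 1e-9))


def spearman_via_pearson_ranks(x, y) -> float:
    """Spearman rho as Pearson correlation of average ranks."""
    from scipy.stats import rankdata

    rx = rankdata(x, method="average")
    ry = rankdata(y, method="average")
    return float(np.corrcoef(rx, ry)[0, 1])
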