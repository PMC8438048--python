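"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations that share no code path with the
package: integer-arithmetic hypergeometric enumeration for the exact test,
a conditional-likelihood root bracket for the MLE odds ratio, sort/cummin
Benjamini-Hochberg, and O(n^3) complete-linkage clustering.
"""

from __future__ import annotations

import math
from math import comb

import numpy as np

TIE_NUM = 10**7 + 1
TIE_DEN = 10**7


def fisher_p_enum(table) -> float:
    """Two-sided Fisher p by exact integer enumeration of the support.

    Includes every table whose (integer) hypergeometric weight is at most
    the observed one times the customary 1 + 1e-7 tie guard, evaluated in
    exact arithmetic.
    """
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = [comb(r1, k) * comb(r2, c1 - k) for k in range(lo, hi + 1)]
    obs = weights[a - lo]
    num = sum(w for w in weights if w * TIE_DEN <= obs * TIE_NUM)
    return num / comb(n, c1)


def cmle_or_enum(table) -> float:
    """Conditional-MLE odds ratio via the noncentral hypergeometric mean.

    Solves E_psi[A] = a by bisection on log(psi); boundary tables return
    0 or infinity.
    """
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    if a == lo == hi:
        return float("nan")
    if a == hi:
        return float("inf")
    if a == lo:
        return 0.0
    ks = np.arange(lo, hi + 1)
    logw = np.array([math.log(comb(r1, k)) + math.log(comb(r2, c1 - k))
                     for k in ks])

    def cond_mean(logpsi: float) -> float:
        lp = logw + ks * logpsi
        lp -= lp.max()
        w = np.exp(lp)
        return float((ks * w).sum() / w.sum())

    low, high = -50.0, 50.0
    for _ in range(200):
        mid = 0.5 * (low + high)
        if cond_mean(mid) < a:
            low = mid
        else:
            high = mid
    return math.exp(0.5 * (low + high))


def bh_enum(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted values by explicit sort and cummin."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    for i in range(m - 2, -1, -1):
        adj[i] = min(adj[i], adj[i + 1])
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def complete_linkage_enum(points: np.ndarray) -> list[float]:
    """Merge heights of complete-linkage clustering, O(n^3), Euclidean."""
    clusters = [[i] for i in range(len(points))]
    heights = []
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    while len(clusters) > 1:
        best = (float("inf"), None)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dist = max(d[a, b] for a in clusters[i] for b in clusters[j])
                if dist < best[0]:
                    best = (dist, (i, j))
        h, (i, j) = best
        heights.append(h)
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return heights


def all_tables(max_total: int):
    """Every 2x2 non-negative integer table with positive margins and grand
    total at most ``max_total``."""
    for n in range(1, max_total + 1):
        for a in range(n + 1):
            for b in range(n + 1 - a):
                for c in range(n + 1 - a - b):
                    d = n - a - b - c
                    t = ((a, b), (c, d))
                    if a + b and c + d and a + c and b + d:
                        yield t
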