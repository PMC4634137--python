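"""Independent brute-force oracles used only by the test suite."""
from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import scipy.stats


def hypergeom_tail_enum(N: int, K: int, n: int, k: int) -> Fraction:
    """Exact upper-tail hypergeometric probability by direct summation of
    binomial-coefficient ratios (integer arithmetic)."""
    total = comb(N, n)
    acc = 0
    for j in range(k, min(K, n) + 1):
        if n - j > N - K:
            continue
        acc += comb(K, j) * comb(N - K, n - j)
    return Fraction(acc, total)


def ranksum_exact_p_greater(x, y) -> Fraction:
    """Exact one-sided p that the x group is shifted right: the fraction of
    equally likely rank assignments whose x rank-sum is >= the observed one.

    Counts subsets by rank-sum with a dynamic program over the pooled ranks
    (identical to full enumeration; inputs must be tie-free).
    """
    x = list(x)
    y = list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires no ties"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n1, n = len(x), len(pooled)
    w_obs = sum(ranks[v] for v in x)
    max_sum = n * (n + 1) // 2
    # ways[j][s] = number of j-subsets of {1..n} with rank-sum s
    ways = np.zeros((n1 + 1, max_sum + 1), dtype=object)
    ways[0][0] = 1
    for r in range(1, n + 1):
        for j in range(min(n1, r), 0, -1):
            ways[j][r:] = ways[j][r:] + ways[j - 1][:-r if r else None]
    counts = ways[n1]
    favourable = sum(counts[w_obs:])
    return Fraction(int(favourable), comb(n, n1))


def anova2_projection(y: np.ndarray, organ_idx: np.ndarray,
                      ct_idx: np.ndarray) -> dict:
    """Two-way ANOVA with interaction via least-squares projections.

    Type-II F statistics: each main-effect SS is the RSS drop from adding
    that factor to the other main effect; the interaction SS is the RSS
    drop from additive to the full cell-means model.
    """
    def dummies(idx):
        levels = np.unique(idx)
        return (idx[:, None] == levels[None, :]).astype(float)

    ones = np.ones((y.size, 1))
    a_dum = dummies(organ_idx)[:, 1:]
    b_dum = dummies(ct_idx)[:, 1:]
    cell = organ_idx * (ct_idx.max() + 1) + ct_idx
    full = dummies(cell)

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    rss_a = rss(np.hstack([ones, a_dum]))
    rss_b = rss(np.hstack([ones, b_dum]))
    rss_ab = rss(np.hstack([ones, a_dum, b_dum]))
    rss_full = rss(full)

    a_levels = int(organ_idx.max()) + 1
    b_levels = int(ct_idx.max()) + 1
    df = {"organ": a_levels - 1, "cell_type": b_levels - 1,
          "interaction": (a_levels - 1) * (b_levels - 1)}
    df_err = y.size - a_levels * b_levels
    ss = {"organ": rss_b - rss_ab, "cell_type": rss_a - rss_ab,
          "interaction": rss_ab - rss_full}
    out = {}
    for effect in df:
        f = (ss[effect] / df[effect]) / (rss_full / df_err)
        out[f"F_{effect}"] = f
        out[f"p_{effect}"] = float(scipy.stats.f.sf(f, df[effect], df_err))
    return out
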