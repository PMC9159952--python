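"""Shared statistical utilities: BH adjustment and the exact one-sided
Wilcoxon rank-sum test used for cluster-abundance comparisons."""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_adjust", "wilcoxon_onesided"]


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped at 1).

    Order-preserving: adjusted values keep the input order. NaNs are
    propagated and excluded from the number of tests m.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be 1-D")
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full_like(p, np.nan)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def _rank_sum_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """P(rank-sum of y >= observed) by enumeration over distinct assignments.

    Midranks handle ties, so the enumeration is over all C(n, n_y)
    position subsets of the pooled sorted sample; exact even with ties.
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks
    n, ny = len(pooled), len(y)
    obs = ranks[len(x):].sum()
    hits = 0
    total = comb(n, ny)
    for idx in combinations(range(n), ny):
        if ranks[list(idx)].sum() >= obs - 1e-9:
            hits += 1
    return hits / total


def wilcoxon_onesided(
    x, y, alternative: str = "y_greater", exact_max_n: int = 20
) -> tuple[float, float]:
    """One-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Tests whether group ``y`` is stochastically greater than ``x``
    (``alternative='y_greater'``) or smaller (``'y_less'``). Exact
    enumeration over rank assignments (midranks for ties) when
    n_x + n_y <= ``exact_max_n``; otherwise the normal approximation
    with tie correction. Returns (W, p) where W is the Mann-Whitney U
    statistic of ``y`` versus ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    if alternative == "y_less":
        return wilcoxon_onesided(-x, -y, "y_greater", exact_max_n)
    if alternative != "y_greater":
        raise ValueError("alternative must be 'y_greater' or 'y_less'")

    ranks = stats.rankdata(np.concatenate([x, y]))
    u = ranks[len(x):].sum() - len(y) * (len(y) + 1) / 2.0
    if len(x) + len(y) <= exact_max_n:
        p = _rank_sum_exact_p(x, y)
    else:
        p = stats.mannwhitneyu(y, x, alternative="greater").pvalue
    return float(u), float(p)
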