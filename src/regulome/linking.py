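"""Peak-gene linking and regulatory-potential association testing.

Links are Pearson correlations between gene expression and peak
accessibility over cells (or pseudo-replicate means), restricted to a
distance window around the TSS, with Fisher-z p-values BH-adjusted
within each gene. Regulatory potential is a distance-decayed sum of
peak weights near the TSS, exp(-0.5 - 4*Delta) with Delta = distance /
half-window, and peak sets are tested for association with regulated
genes by a one-sided two-sample Kolmogorov-Smirnov test on RP values.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import PeakSet
from .stats import bh_adjust

__all__ = ["link_peaks", "regulatory_potential", "association_test"]


def _pearson_fisher_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from the Fisher z-transform of Pearson r."""
    r = np.clip(r, -1 + 1e-12, 1 - 1e-12)
    z = np.arctanh(r) * np.sqrt(max(n - 3, 1))
    return 2.0 * stats.norm.sf(np.abs(z))


def link_peaks(
    expr: pd.DataFrame,
    acc: pd.DataFrame,
    tss: pd.Series,
    peak_centers: pd.Series,
    min_distance: float = 2_000,
    max_distance: float = 1_000_000,
    min_cells_frac: float = 0.02,
) -> pd.DataFrame:
    """Correlate gene expression with peak accessibility within a
    distance window.

    expr : cells x genes values (e.g. log-normalised expression)
    acc  : cells x peaks values (same cell universe)
    tss  : gene -> TSS position (bp); genes without a TSS are skipped
    peak_centers : peak -> center position (bp)

    Candidate pairs satisfy min_distance <= |center - TSS| <=
    max_distance; peaks must be non-zero in >= ``min_cells_frac`` of
    cells; constant vectors are excluded. Signed distance (center - TSS)
    is reported. p-values (Fisher z) are BH-adjusted within each gene.
    """
    if not expr.index.equals(acc.index):
        raise ValueError("expr and acc must share the same cell universe")
    n = len(expr)
    frac_open = (acc > 0).mean(axis=0)
    usable_peaks = frac_open[frac_open >= min_cells_frac].index

    rows = []
    centers = peak_centers.loc[[p for p in usable_peaks if p in peak_centers.index]]
    for gene in expr.columns:
        if gene not in tss.index:
            warnings.warn(f"gene {gene!r} has no TSS; skipped")
            continue
        d = centers - tss[gene]
        cand = centers.index[(d.abs() >= min_distance) & (d.abs() <= max_distance)]
        if not len(cand):
            continue
        x = expr[gene].to_numpy(dtype=float)
        if np.std(x) == 0:
            continue
        gene_rows = []
        for peak in cand:
            y = acc[peak].to_numpy(dtype=float)
            if np.std(y) == 0:
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            gene_rows.append({
                "peak": peak, "gene": gene,
                "distance": float(d[peak]), "r": r,
                "p": float(_pearson_fisher_p(np.array([r]), n)[0]),
            })
        if gene_rows:
            sub = pd.DataFrame(gene_rows)
            sub["p_adj"] = bh_adjust(sub["p"].to_numpy())
            rows.append(sub)
    if not rows:
        return pd.DataFrame(columns=["peak", "gene", "distance", "r", "p", "p_adj"])
    return pd.concat(rows, ignore_index=True)


def regulatory_potential(
    peaks: PeakSet,
    tss: pd.Series,
    d: float = 500_000,
    weights: tuple[float, float] = (0.5, 4.0),
) -> pd.DataFrame:
    """Regulatory-potential score per gene.

    RP(gene) = sum over peaks with |center - TSS| <= d of
    exp(-w0 - w1 * Delta), Delta = |center - TSS| / d. Genes with no
    peak in the window score 0.
    """
    if d <= 0:
        raise ValueError("d must be positive")
    w0, w1 = weights
    if "summit" in peaks.df.columns and peaks.df["summit"].notna().all():
        centers = peaks.df["summit"].to_numpy(dtype=float)
    else:
        centers = (peaks.df["start"] + peaks.df["end"]).to_numpy(dtype=float) / 2.0
    rows = []
    for gene, pos in tss.items():
        delta = np.abs(centers - pos) / d
        inside = delta <= 1.0
        rp = float(np.exp(-w0 - w1 * delta[inside]).sum())
        rows.append({"gene": gene, "rp": rp, "n_peaks": int(inside.sum())})
    return pd.DataFrame(rows).set_index("gene")


def association_test(
    rp: pd.DataFrame,
    regulated_genes: list[str],
    background_genes: list[str],
) -> dict:
    """One-sided KS test: do regulated genes have higher RP than background?

    The two gene sets must be disjoint and non-empty. Returns the KS
    statistic and one-sided p for the alternative "regulated RP is
    stochastically greater".
    """
    reg, bg = set(regulated_genes), set(background_genes)
    if not reg or not bg:
        raise ValueError("both gene sets must be non-empty")
    if reg & bg:
        raise ValueError("regulated and background gene sets overlap")
    x = rp.loc[sorted(reg), "rp"].to_numpy()
    y = rp.loc[sorted(bg), "rp"].to_numpy()
    # alternative='less': CDF of x lies below CDF of y, i.e. x is larger
    res = stats.ks_2samp(x, y, alternative="less")
    return {"statistic": float(res.statistic), "p": float(res.pvalue),
            "n_regulated": len(x), "n_background": len(y)}
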