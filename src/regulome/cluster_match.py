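"""Cross-dataset cluster replicability by neighbor-voting AUROC.

Cells from two datasets are placed in one rank-standardised Spearman
correlation network restricted to cross-dataset edges; a query cell's
vote for a reference cluster is its mean (row-normalised) connectivity
to that cluster's cells, and the AUROC asks how well those votes
separate each query cluster from the rest.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import stats

__all__ = ["cross_dataset_variable_genes", "neighbor_vote_auroc", "auroc"]


def _dense(adata: AnnData) -> np.ndarray:
    X = adata.X
    return np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X)


def _log_normalize(X: np.ndarray, scale: float = 1e4) -> np.ndarray:
    depth = np.maximum(X.sum(axis=1, keepdims=True), 1.0)
    return np.log1p(X / depth * scale)


def _binned_dispersion_rank(X: np.ndarray, n_bins: int = 20):
    """Dispersion of log-normalised counts standardised within
    mean-expression bins.

    Returns (rank_quantile, z): the within-bin rank quantile (for the
    top-fraction gate) and the within-bin z-score of dispersion (for
    ordering across bins).
    """
    logn = _log_normalize(X)
    mean = logn.mean(axis=0)
    var = logn.var(axis=0)
    disp = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)
    order = np.argsort(mean)
    ranks = np.zeros(len(mean))
    z = np.zeros(len(mean))
    n_bins = min(n_bins, max(1, len(mean) // 10))
    for b in np.array_split(order, n_bins):
        if len(b):
            ranks[b] = stats.rankdata(disp[b]) / (len(b) + 1)
            sd = disp[b].std()
            z[b] = (disp[b] - disp[b].mean()) / sd if sd > 0 else 0.0
    return ranks, z


def cross_dataset_variable_genes(
    a: AnnData, b: AnnData, n_genes: int = 500, top_quantile: float = 0.5
) -> list[str]:
    """Highly variable genes shared across two datasets.

    Genes are ranked per dataset by binned dispersion; genes in the top
    ``top_quantile`` of both datasets are kept, ordered by the summed
    rank, truncated to ``n_genes``. Constant genes never qualify.
    """
    shared = [g for g in a.var_names if g in set(b.var_names)]
    if not shared:
        raise ValueError("no shared genes between datasets")
    Xa = _dense(a[:, shared])
    Xb = _dense(b[:, shared])
    ra, za = _binned_dispersion_rank(Xa)
    rb, zb = _binned_dispersion_rank(Xb)
    nonconst = (Xa.var(axis=0) > 0) & (Xb.var(axis=0) > 0)
    qual = (ra >= top_quantile) & (rb >= top_quantile) & nonconst
    if not qual.any():
        raise ValueError("no gene passes the variable-gene intersection")
    score = np.where(qual, za + zb, -np.inf)
    order = np.argsort(-score, kind="stable")
    picked = [shared[i] for i in order[: min(n_genes, int(qual.sum()))]]
    return picked


def auroc(votes: np.ndarray, positive: np.ndarray) -> float:
    """AUROC via the Mann-Whitney identity U / (n+ * n-), with midranks."""
    pos = positive.astype(bool)
    n1, n0 = pos.sum(), (~pos).sum()
    if n1 == 0 or n0 == 0:
        return np.nan
    ranks = stats.rankdata(votes)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def neighbor_vote_auroc(
    a: AnnData,
    b: AnnData,
    genes: list[str],
    cluster_key: str = "cluster",
    min_cluster_size: int = 10,
) -> pd.DataFrame:
    """AUROC matrix of reference (rows, dataset ``a``) against query
    clusters (columns, dataset ``b``).

    Expression is log-normalised and rank-transformed per cell over the
    supplied genes (Spearman network); the cross-dataset correlation
    matrix is row-normalised to non-negative voting weights. Clusters
    below ``min_cluster_size`` are dropped with a warning.
    """
    def prep(adata):
        keep_clusters = adata.obs[cluster_key].value_counts()
        small = keep_clusters[keep_clusters < min_cluster_size].index
        if len(small):
            warnings.warn(f"dropping small clusters: {list(small)}")
        mask = ~adata.obs[cluster_key].isin(small)
        sub = adata[mask]
        X = _log_normalize(_dense(sub[:, genes]))
        R = np.apply_along_axis(stats.rankdata, 1, X)
        R = (R - R.mean(axis=1, keepdims=True))
        R = R / np.maximum(np.linalg.norm(R, axis=1, keepdims=True), 1e-12)
        return R, sub.obs[cluster_key].astype(str).to_numpy()

    Ra, ca = prep(a)
    Rb, cb = prep(b)
    if len(np.unique(ca)) < 2 or len(np.unique(cb)) < 2:
        raise ValueError("need >= 2 clusters per dataset")
    net = Rb @ Ra.T                       # query x reference Spearman corr
    net = net - net.min()                 # non-negative weights
    net = net / np.maximum(net.sum(axis=1, keepdims=True), 1e-12)

    ref_clusters = sorted(np.unique(ca))
    qry_clusters = sorted(np.unique(cb))
    votes = np.column_stack([net[:, ca == rc].mean(axis=1) for rc in ref_clusters])
    out = pd.DataFrame(index=ref_clusters, columns=qry_clusters, dtype=float)
    for i, rc in enumerate(ref_clusters):
        for qc in qry_clusters:
            out.loc[rc, qc] = auroc(votes[:, i], cb == qc)
    return out
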