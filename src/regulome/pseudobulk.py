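"""Per-cluster differential expression.

Implements the pseudo-bulk workflow: gene filtering, per-(cluster,
replicate) aggregation with small-replicate exclusion, median-of-ratios
size factors, an NB Wald test on the group coefficient (with optional
categorical covariates), a one-sided threshold test for cluster markers,
a single-cell two-part hurdle test, marker-based cluster merging and
marker-positive cluster classification.

Dispersion is per-gene method of moments with a floor and no shrinkage;
the aim is calibrated decisions (type-I error, planted-effect recovery),
not coefficient-level equality with any particular reference package.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import stats
from scipy.cluster.hierarchy import linkage, to_tree

from ._glm import estimate_dispersion, fit_nb_glm, lr_test, wald_test
from .stats import bh_adjust

__all__ = [
    "filter_genes", "aggregate", "size_factors", "nb_wald", "marker_lfc_test",
    "hurdle_test", "merge_clusters", "classify_marker_clusters",
    "PseudobulkMatrix",
]

LN2 = np.log(2.0)
# NCBI-predicted style gene ids (the pattern itself is configurable)
PREDICTED_GENE_PATTERNS = (r"^Gm\d+$", r"Rik$")


def _X(adata: AnnData) -> np.ndarray:
    X = adata.X
    return np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X)


def filter_genes(
    cells: AnnData,
    min_count: int = 2,
    min_cells: int = 5,
    predicted_patterns: tuple[str, ...] = PREDICTED_GENE_PATTERNS,
) -> AnnData:
    """Keep genes with > 1 count (i.e. >= ``min_count``) in >= ``min_cells``
    cells, and drop ids matching the predicted-gene patterns."""
    X = _X(cells)
    expressed = (X >= min_count).sum(axis=0) >= min_cells
    regexes = [re.compile(p) for p in predicted_patterns]
    not_predicted = np.array(
        [not any(r.search(g) for r in regexes) for g in cells.var_names]
    )
    return cells[:, expressed & not_predicted].copy()


@dataclass
class PseudobulkMatrix:
    """Gene x replicate count sums for one cluster, plus column metadata."""

    counts: pd.DataFrame           # genes x replicates
    meta: pd.DataFrame             # per-column: sex/condition, n_cells
    excluded: list[str] = field(default_factory=list)

    @property
    def n_columns(self) -> int:
        return self.counts.shape[1]


def aggregate(
    cells: AnnData,
    cluster: str,
    min_cells: int = 20,
    cluster_key: str = "cluster",
    replicate_key: str = "replicate",
    group_keys: tuple[str, ...] = ("sex",),
) -> PseudobulkMatrix:
    """Sum gene counts per biological replicate within one cluster.

    Replicates with <= ``min_cells`` cells in the cluster are excluded
    and reported. Raises if the cluster label is unknown.
    """
    if cluster not in set(cells.obs[cluster_key]):
        raise KeyError(f"unknown cluster {cluster!r}")
    sub = cells[cells.obs[cluster_key] == cluster]
    X = _X(sub)
    cols, meta_rows, excluded = {}, [], []
    for rep, idx in sub.obs.groupby(replicate_key, observed=True).indices.items():
        n = len(idx)
        if n <= min_cells:
            excluded.append(str(rep))
            continue
        cols[str(rep)] = X[idx].sum(axis=0)
        row = {"replicate": str(rep), "n_cells": n}
        for k in group_keys:
            vals = sub.obs[k].iloc[idx].unique()
            if len(vals) != 1:
                raise ValueError(f"replicate {rep} has mixed {k!r} labels")
            row[k] = vals[0]
        meta_rows.append(row)
    counts = pd.DataFrame(cols, index=sub.var_names).round().astype(int)
    meta = pd.DataFrame(meta_rows).set_index("replicate") if meta_rows else (
        pd.DataFrame(columns=["n_cells", *group_keys])
    )
    return PseudobulkMatrix(counts=counts, meta=meta, excluded=excluded)


def size_factors(counts: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors, renormalised to geometric mean 1.

    factor_j = median over genes nonzero in every column of
    count_gj / geometric_mean_g(count_g.).
    """
    mat = np.asarray(counts, dtype=float)
    allpos = (mat > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no gene with nonzero counts in every column; consider a "
            "pseudo-reference fallback (not implemented by default)"
        )
    logs = np.log(mat[allpos])
    logratio = logs - logs.mean(axis=1, keepdims=True)
    f = np.exp(np.median(logratio, axis=0))
    return f / np.exp(np.mean(np.log(f)))


def _design_matrix(meta: pd.DataFrame, group_key: str, covariates: tuple[str, ...]):
    """Intercept + treatment-coded group (last column) + covariate dummies."""
    pieces = [np.ones((len(meta), 1))]
    names = ["intercept"]
    for cov in covariates:
        dummies = pd.get_dummies(meta[cov], drop_first=True, prefix=cov)
        pieces.append(dummies.to_numpy(dtype=float))
        names += list(dummies.columns)
    levels = sorted(pd.unique(meta[group_key]))
    if len(levels) != 2:
        raise ValueError(f"group {group_key!r} must have exactly 2 levels")
    g = (meta[group_key] == levels[1]).to_numpy(dtype=float)[:, None]
    X = np.hstack(pieces + [g])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("confounded design: group is collinear with covariates")
    names.append(f"{group_key}[{levels[1]} vs {levels[0]}]")
    return X, names, levels


def nb_wald(
    pb: PseudobulkMatrix,
    group_key: str = "sex",
    covariates: tuple[str, ...] = (),
) -> pd.DataFrame:
    """NB Wald test of the group coefficient per gene.

    log2FC is group level-2 over level-1 (levels sorted). All-zero genes
    get NA. Requires >= 2 columns per group.
    """
    meta = pb.meta
    X, names, levels = _design_matrix(meta, group_key, covariates)
    if (meta[group_key] == levels[0]).sum() < 2 or (meta[group_key] == levels[1]).sum() < 2:
        raise ValueError("need >= 2 replicates per group")
    counts = pb.counts.to_numpy(dtype=float)
    sf = size_factors(pb.counts)
    offset = np.log(sf)

    nonzero = counts.sum(axis=1) > 0
    res = pd.DataFrame(
        index=pb.counts.index,
        columns=["baseMean", "log2FC", "stat", "p", "p_adj"],
        dtype=float,
    )
    if nonzero.any():
        sub = counts[nonzero]
        alpha = estimate_dispersion(sub, X, offset)
        fit = fit_nb_glm(sub, X, offset, alpha=alpha)
        beta, se, p = wald_test(fit, coef=X.shape[1] - 1,
                                df_resid=max(X.shape[0] - X.shape[1], 1))
        res.loc[nonzero, "baseMean"] = (sub / sf).mean(axis=1)
        res.loc[nonzero, "log2FC"] = beta / LN2
        res.loc[nonzero, "stat"] = beta / se
        res.loc[nonzero, "p"] = p
        res.loc[nonzero, "p_adj"] = bh_adjust(p)
    return res


def marker_lfc_test(
    pb: PseudobulkMatrix,
    focal_cluster: str,
    cluster_key: str = "cluster_id",
    lfc_threshold: float = 2.0,
) -> pd.DataFrame:
    """One-sided NB Wald test of H1: log2FC(focal vs rest) > ``lfc_threshold``.

    Used to call markers enriched in a focal cluster against the rest
    at a fold-change bar (null: log2FC <= threshold).
    """
    meta = pb.meta.copy()
    meta["_focal"] = np.where(meta[cluster_key] == focal_cluster, "z_focal", "a_rest")
    X, _, _ = _design_matrix(meta, "_focal", ())
    counts = pb.counts.to_numpy(dtype=float)
    sf = size_factors(pb.counts)
    offset = np.log(sf)
    nonzero = counts.sum(axis=1) > 0
    res = pd.DataFrame(
        index=pb.counts.index, columns=["log2FC", "stat", "p", "p_adj"], dtype=float
    )
    if nonzero.any():
        sub = counts[nonzero]
        alpha = estimate_dispersion(sub, X, offset)
        fit = fit_nb_glm(sub, X, offset, alpha=alpha)
        j = X.shape[1] - 1
        beta = fit["beta"][:, j]
        se = np.sqrt(np.maximum(fit["cov"][:, j, j], 1e-300))
        z = (beta - lfc_threshold * LN2) / se
        res.loc[nonzero, "log2FC"] = beta / LN2
        res.loc[nonzero, "stat"] = z
        res.loc[nonzero, "p"] = stats.t.sf(z, max(X.shape[0] - X.shape[1], 1))
        res.loc[nonzero, "p_adj"] = bh_adjust(res.loc[nonzero, "p"].to_numpy())
    return res


# ---------------------------------------------------------------------------
# single-cell hurdle test


def _logistic_deviance(X: np.ndarray, y: np.ndarray, max_iter: int = 50) -> float:
    """Deviance of a logistic fit by IRLS (small designs only)."""
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = np.maximum(mu * (1 - mu), 1e-10)
        z = eta + (y - mu) / W
        new = np.linalg.lstsq(X * np.sqrt(W)[:, None], z * np.sqrt(W), rcond=None)[0]
        if np.max(np.abs(new - beta)) < 1e-8:
            beta = new
            break
        beta = new
    eta = np.clip(X @ beta, -30, 30)
    mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
    return float(-2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


def _normalize_log(X: np.ndarray, scale: float = 1e4) -> np.ndarray:
    depth = np.maximum(X.sum(axis=1, keepdims=True), 1.0)
    return np.log1p(X / depth * scale)


def hurdle_test(
    cells: AnnData,
    group_key: str = "sex",
    min_pct: float = 0.05,
    logfc_threshold: float = 0.2,
    covariates: tuple[str, ...] = ("n_genes", "total_counts"),
) -> pd.DataFrame:
    """Two-part hurdle test per gene between two cell groups.

    Detection (count > 0) is modelled by logistic regression and the
    positive-part log-normalised expression by a linear model, both with
    the group term plus continuous covariates; the two likelihood-ratio
    statistics are summed and referred to chi-square with summed df.
    Genes detected in < ``min_pct`` of both groups, or whose
    |log2FC| of mean log1p-normalised expression is below
    ``logfc_threshold``, are not tested. Untested genes carry NaN p.
    """
    groups = sorted(pd.unique(cells.obs[group_key]))
    if len(groups) != 2:
        raise ValueError("hurdle_test requires exactly two groups")
    g = (cells.obs[group_key] == groups[1]).to_numpy(dtype=float)
    if g.sum() < 3 or (1 - g).sum() < 3:
        raise ValueError("need >= 3 cells per group")
    X = _X(cells)
    logn = _normalize_log(X)

    covs = []
    for c in covariates:
        v = cells.obs[c].to_numpy(dtype=float)
        if np.std(v) == 0:
            warnings.warn(f"dropping constant covariate {c!r}")
            continue
        covs.append((v - v.mean()) / v.std())
    C = np.column_stack(covs) if covs else np.empty((len(g), 0))
    D0 = np.column_stack([np.ones_like(g), C])          # null design
    D1 = np.column_stack([np.ones_like(g), C, g])       # with group

    a, b = g == 0, g == 1
    det = X > 0
    pct_a, pct_b = det[a].mean(axis=0), det[b].mean(axis=0)
    lfc = (logn[b].mean(axis=0) - logn[a].mean(axis=0)) / LN2
    testable = ((pct_a >= min_pct) | (pct_b >= min_pct)) & (np.abs(lfc) >= logfc_threshold)

    res = pd.DataFrame(
        index=cells.var_names,
        columns=["pct_1", "pct_2", "log2FC", "stat", "df", "p", "p_adj"],
        dtype=float,
    )
    res["pct_1"], res["pct_2"], res["log2FC"] = pct_a, pct_b, lfc
    stat = np.full(X.shape[1], np.nan)
    dfs = np.full(X.shape[1], np.nan)
    for j in np.flatnonzero(testable):
        y_det = det[:, j].astype(float)
        lr, df = 0.0, 0
        if 0 < y_det.sum() < len(y_det):
            lr += _logistic_deviance(D0, y_det) - _logistic_deviance(D1, y_det)
            df += 1
        pos = det[:, j]
        if pos.sum() >= D1.shape[1] + 1 and len(np.unique(g[pos])) == 2:
            yv = logn[pos, j]
            r0 = yv - D0[pos] @ np.linalg.lstsq(D0[pos], yv, rcond=None)[0]
            r1 = yv - D1[pos] @ np.linalg.lstsq(D1[pos], yv, rcond=None)[0]
            n_pos = pos.sum()
            lr += n_pos * (np.log(np.sum(r0**2)) - np.log(np.maximum(np.sum(r1**2), 1e-300)))
            df += 1
        if df:
            stat[j], dfs[j] = max(lr, 0.0), df
    res["stat"], res["df"] = stat, dfs
    ok = ~np.isnan(stat)
    res.loc[ok, "p"] = stats.chi2.sf(stat[ok], dfs[ok])
    res.loc[ok, "p_adj"] = bh_adjust(res.loc[ok, "p"].to_numpy())
    return res


# ---------------------------------------------------------------------------
# cluster merging and marker classification


def _qualifying_degs(
    cells: AnnData,
    labels: pd.Series,
    c1: str,
    c2: str,
    p_adj_threshold: float = 0.05,
    min_lfc: float = 0.5,
    max_pct_negative: float = 0.10,
    min_pct_positive: float = 0.25,
) -> int:
    """Count genes distinguishing two clusters under the marker gates:
    |avg log2FC| > 0.5, < 10% detection in the negative cluster and
    > 25% detection in the positive cluster, at adjusted p below cutoff."""
    mask = labels.isin([c1, c2]).to_numpy()
    sub = cells[mask].copy()
    sub.obs["_pair"] = labels[mask].to_numpy()
    for col, default in (("n_genes", None), ("total_counts", None)):
        if col not in sub.obs.columns:
            X = _X(sub)
            sub.obs["n_genes"] = (X > 0).sum(axis=1)
            sub.obs["total_counts"] = X.sum(axis=1)
            break
    res = hurdle_test(
        sub, group_key="_pair", min_pct=0.0, logfc_threshold=0.0
    )
    sig = res["p_adj"] < p_adj_threshold
    up = (  # marker of group 2 (positive = higher detection side)
        (res["log2FC"] > min_lfc)
        & (res["pct_1"] < max_pct_negative)
        & (res["pct_2"] > min_pct_positive)
    )
    down = (
        (res["log2FC"] < -min_lfc)
        & (res["pct_2"] < max_pct_negative)
        & (res["pct_1"] > min_pct_positive)
    )
    return int((sig & (up | down)).sum())


def _terminal_pairs(means: pd.DataFrame) -> list[tuple[str, str]]:
    """Sibling leaf pairs of an average-linkage dendrogram over cluster
    mean profiles (correlation distance)."""
    if means.shape[0] < 2:
        return []
    Z = linkage(means.to_numpy(), method="average", metric="euclidean")
    tree = to_tree(Z)
    labels = list(means.index)
    pairs = []

    def walk(node):
        if node.is_leaf():
            return
        l, r = node.get_left(), node.get_right()
        if l.is_leaf() and r.is_leaf():
            pairs.append((labels[l.id], labels[r.id]))
        else:
            walk(l)
            walk(r)

    walk(tree)
    return pairs


def merge_clusters(
    cells: AnnData,
    cluster_key: str = "cluster",
    min_degs: int = 10,
    max_rounds: int = 20,
    **deg_kwargs,
) -> pd.Series:
    """Iteratively merge terminal sibling clusters with < ``min_degs``
    qualifying marker genes between them; repeat until a fixed point.

    The dendrogram is rebuilt each round from cluster mean log-normalised
    profiles. Returns the merged label per cell (merged clusters take the
    name "a+b", sorted).
    """
    labels = cells.obs[cluster_key].astype(str).copy()
    logn = _normalize_log(_X(cells))
    for _ in range(max_rounds):
        uniq = sorted(labels.unique())
        if len(uniq) < 2:
            break
        means = pd.DataFrame(
            {c: logn[(labels == c).to_numpy()].mean(axis=0) for c in uniq}
        ).T
        merged_any = False
        for c1, c2 in _terminal_pairs(means):
            n = _qualifying_degs(cells, labels, c1, c2, **deg_kwargs)
            if n < min_degs:
                new = "+".join(sorted(set(c1.split("+")) | set(c2.split("+"))))
                labels[labels.isin([c1, c2])] = new
                merged_any = True
        if not merged_any:
            break
    return labels


def classify_marker_clusters(
    cells: AnnData,
    marker: str,
    threshold_pct: float = 0.25,
    cluster_key: str = "cluster",
) -> pd.Series:
    """Label each cluster positive iff >= ``threshold_pct`` of its cells
    have >= 1 count of ``marker`` (e.g. Esr1+ classification)."""
    if marker not in cells.var_names:
        raise KeyError(f"marker {marker!r} not in matrix")
    j = list(cells.var_names).index(marker)
    x = _X(cells)[:, j]
    out = {}
    for c, idx in cells.obs.groupby(cluster_key, observed=True).indices.items():
        out[c] = (x[idx] >= 1).mean() >= threshold_pct
    return pd.Series(out, name=f"{marker}_positive")
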