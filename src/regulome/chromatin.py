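"""Multi-condition differential accessibility and chromatin-state calling.

Covers CPM normalisation, the NB GLM likelihood-ratio test over one or
several coefficients (pairwise contrast, multi-group ANOVA-like test and
sex x treatment interaction), k-means archetype clustering with
centroid-correlation pruning, hierarchical clustering with NE-open /
NE-close labelling on the neonatal three-group design, per-cluster
sex-difference CPM profiling, and the maintenance-overlap statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans

from ._glm import estimate_dispersion, fit_nb_glm, lr_test
from .intervals import PeakSet, intersect
from .stats import bh_adjust

__all__ = [
    "cpm", "multi_condition_test", "kmeans_states", "hierarchical_ne_states",
    "sex_difference_profile", "maintenance_overlap", "StateClustering",
]

LN2 = np.log(2.0)


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million per column: count * 1e6 / library size."""
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise ValueError("zero library size")
    return counts * 1e6 / lib


def _group_design(design: pd.DataFrame, factors: tuple[str, ...], interaction: bool):
    """Intercept + treatment-coded factor dummies (+ interaction columns).

    Returns (X, coef_names). Coefficient 0 is the intercept.
    """
    X = [np.ones(len(design))]
    names = ["intercept"]
    dummy_cols: dict[str, list[np.ndarray]] = {}
    for f in factors:
        d = pd.get_dummies(design[f], drop_first=True, prefix=f)
        dummy_cols[f] = [d[c].to_numpy(dtype=float) for c in d.columns]
        X += dummy_cols[f]
        names += list(d.columns)
    if interaction:
        if len(factors) != 2:
            raise ValueError("interaction requires exactly two factors")
        f1, f2 = factors
        for i, a in enumerate(dummy_cols[f1]):
            for j, b in enumerate(dummy_cols[f2]):
                X.append(a * b)
                names.append(f"{f1}x{f2}_{i}_{j}")
    M = np.column_stack(X)
    if np.linalg.matrix_rank(M) < M.shape[1]:
        raise ValueError("singular design")
    return M, names


def multi_condition_test(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    factors: tuple[str, ...] = ("sex", "treatment"),
    contrast: str = "anova",
    coefficients: list[int] | None = None,
) -> pd.DataFrame:
    """NB GLM likelihood-ratio test over one or several coefficients.

    counts : peak x sample integer counts
    design : per-sample factor table
    contrast:
      'anova'       — drop all non-intercept main-effect coefficients
                      (or the subset in ``coefficients``)
      'interaction' — fit main effects + interaction, test the
                      interaction coefficients
      a factor name — test that factor's coefficients only (pairwise
                      contrast when the factor has two levels)

    Offsets are log library sizes. Returns per-peak LR statistic, df, p,
    BH-adjusted p and per-tested-coefficient log2FCs.
    """
    for f in factors:
        if design.groupby(f, observed=True).size().min() < 2:
            raise ValueError("need >= 2 replicates per group")
    interaction = contrast == "interaction"
    X, names = _group_design(design, factors, interaction=interaction)
    if interaction:
        test_idx = [i for i, n in enumerate(names) if "x" in n and n != "intercept"]
    elif contrast == "anova":
        test_idx = coefficients if coefficients is not None else list(range(1, X.shape[1]))
    elif contrast in factors:
        test_idx = [i for i, n in enumerate(names) if n.startswith(f"{contrast}_")]
    else:
        raise ValueError(f"unknown contrast {contrast!r}")
    if not test_idx:
        raise ValueError("no coefficients to test")

    Y = counts.to_numpy(dtype=float)
    offset = np.log(Y.sum(axis=0).astype(float))
    keep = [i for i in range(X.shape[1]) if i not in test_idx]
    X0 = X[:, keep]

    nonzero = Y.sum(axis=1) > 0
    res = pd.DataFrame(index=counts.index, columns=["stat", "df", "p", "p_adj"], dtype=float)
    lfc_cols = {f"log2FC_{names[i]}": np.full(len(counts), np.nan) for i in test_idx}
    if nonzero.any():
        sub = Y[nonzero]
        alpha = estimate_dispersion(sub, X, offset)
        full = fit_nb_glm(sub, X, offset, alpha=alpha)
        red = fit_nb_glm(sub, X0, offset, alpha=alpha)
        stat, p = lr_test(full["loglik"], red["loglik"], df=len(test_idx),
                          df_resid=max(X.shape[0] - X.shape[1], 1))
        res.loc[nonzero, "stat"] = stat
        res.loc[nonzero, "df"] = len(test_idx)
        res.loc[nonzero, "p"] = p
        res.loc[nonzero, "p_adj"] = bh_adjust(p)
        for i in test_idx:
            lfc_cols[f"log2FC_{names[i]}"][np.flatnonzero(nonzero)] = full["beta"][:, i] / LN2
    for k, v in lfc_cols.items():
        res[k] = v
    return res


@dataclass
class StateClustering:
    """Peak-to-state assignment with post-pruning centroids."""

    labels: pd.Series           # peak -> cluster id; -1 = pruned
    centroids: pd.DataFrame     # cluster x condition (post-pruning means)
    correlation: pd.Series      # per-peak Pearson r with assigned centroid


def zscale_rows(mat: pd.DataFrame, drop_zero_variance: bool = True) -> pd.DataFrame:
    """Row z-score across columns; zero-variance rows dropped (or NaN)."""
    mu = mat.mean(axis=1)
    sd = mat.std(axis=1, ddof=0)
    z = mat.sub(mu, axis=0).div(sd.replace(0, np.nan), axis=0)
    return z.dropna() if drop_zero_variance else z


def _row_centroid_corr(Z: np.ndarray, centroids: np.ndarray, labels: np.ndarray) -> np.ndarray:
    out = np.full(len(Z), np.nan)
    for i in range(len(Z)):
        c = centroids[labels[i]]
        if np.std(Z[i]) == 0 or np.std(c) == 0:
            out[i] = 0.0
        else:
            out[i] = np.corrcoef(Z[i], c)[0, 1]
    return out


def kmeans_states(
    normalized: pd.DataFrame,
    k: int = 4,
    max_iter: int = 50,
    prune_r: float = 0.8,
    n_restarts: int = 25,
    seed: int = 0,
) -> StateClustering:
    """K-means over row-standardised condition profiles, then one pruning
    pass removing peaks with Pearson r < ``prune_r`` to their centroid.

    Centroids are recomputed from retained members after pruning. Pruned
    peaks get label -1.
    """
    Z = zscale_rows(normalized)
    if k > len(Z):
        raise ValueError("k exceeds number of peaks")
    km = KMeans(n_clusters=k, n_init=n_restarts, max_iter=max_iter, random_state=seed)
    lab = km.fit_predict(Z.to_numpy())
    corr = _row_centroid_corr(Z.to_numpy(), km.cluster_centers_, lab)
    pruned = corr < prune_r
    final = np.where(pruned, -1, lab)
    cent = {}
    for c in range(k):
        members = Z.to_numpy()[final == c]
        cent[c] = members.mean(axis=0) if len(members) else km.cluster_centers_[c]
    labels = pd.Series(final, index=Z.index, name="state")
    labels = labels.reindex(normalized.index, fill_value=-1)
    return StateClustering(
        labels=labels,
        centroids=pd.DataFrame(cent, index=Z.columns).T,
        correlation=pd.Series(corr, index=Z.index).reindex(normalized.index),
    )


def hierarchical_ne_states(
    normalized: pd.DataFrame,
    k_cut: int = 6,
    groups: tuple[str, str, str] = ("NV-F", "NV-M", "NE-F"),
    method: str = "complete",
    metric: str = "euclidean",
) -> pd.DataFrame:
    """Hierarchical clustering of neonatal three-group profiles and
    NE-open / NE-close labelling.

    Rows (peaks, pre-filtered to differential) are z-scaled, clustered
    (Euclidean, complete linkage by default) and the dendrogram cut into
    ``k_cut`` groups. Among the two largest clusters, one is labelled
    NE-open if its centroid has higher accessibility in NV males and NE
    females than NV females, NE-close for the mirrored pattern; clusters
    matching neither rule stay unlabelled.
    """
    if k_cut > len(normalized):
        raise ValueError("k_cut exceeds number of peaks")
    nv_f, nv_m, ne_f = groups
    Z = zscale_rows(normalized[list(groups)])
    link = linkage(Z.to_numpy(), method=method, metric=metric)
    lab = fcluster(link, t=k_cut, criterion="maxclust")
    out = pd.DataFrame({"cluster": lab}, index=Z.index)
    sizes = out["cluster"].value_counts()
    largest = sizes.index.sort_values()[
        np.argsort(-sizes.reindex(sizes.index.sort_values()).to_numpy(), kind="stable")
    ][:2]
    out["ne_state"] = ""
    for c in largest:
        cent = Z[out["cluster"] == c].mean(axis=0)
        if cent[nv_m] > cent[nv_f] and cent[ne_f] > cent[nv_f]:
            out.loc[out["cluster"] == c, "ne_state"] = "NE-open"
        elif cent[nv_m] < cent[nv_f] and cent[ne_f] < cent[nv_f]:
            out.loc[out["cluster"] == c, "ne_state"] = "NE-close"
    return out.reindex(normalized.index)


def sex_difference_profile(
    atac,
    loci: list[str],
    k: int = 12,
    min_cells_per_cluster: int = 400,
    cluster_key: str = "cluster",
    sex_key: str = "sex",
    max_iter: int = 50,
    seed: int = 0,
    n_restarts: int = 25,
) -> StateClustering:
    """Cluster per-locus male-minus-female CPM differences across cell
    clusters.

    Low-abundance clusters (< ``min_cells_per_cluster`` cells) are
    removed first; clusters missing one sex are excluded with a warning.
    The locus x cluster difference matrix is row z-scaled then k-means
    grouped (no pruning pass).
    """
    X = atac.X
    X = np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X)
    names = list(atac.var_names)
    li = [names.index(p) for p in loci]
    depth = np.maximum(X.sum(axis=1, keepdims=True), 1.0)
    cpm_cells = X / depth * 1e6

    diffs = {}
    for c, idx in atac.obs.groupby(cluster_key, observed=True).indices.items():
        if len(idx) < min_cells_per_cluster:
            continue
        sex = atac.obs[sex_key].iloc[idx]
        m, f = idx[(sex == "M").to_numpy()], idx[(sex == "F").to_numpy()]
        if len(m) == 0 or len(f) == 0:
            warnings.warn(f"cluster {c!r} missing a sex; excluded")
            continue
        diffs[c] = cpm_cells[m][:, li].mean(axis=0) - cpm_cells[f][:, li].mean(axis=0)
    mat = pd.DataFrame(diffs, index=loci)
    if mat.shape[1] == 0:
        empty = pd.Series(-1, index=pd.Index(loci), name="profile")
        return StateClustering(labels=empty, centroids=pd.DataFrame(),
                               correlation=pd.Series(np.nan, index=loci))
    Z = zscale_rows(mat)
    km = KMeans(n_clusters=min(k, len(Z)), n_init=n_restarts, max_iter=max_iter,
                random_state=seed)
    lab = km.fit_predict(Z.to_numpy())
    corr = _row_centroid_corr(Z.to_numpy(), km.cluster_centers_, lab)
    return StateClustering(
        labels=pd.Series(lab, index=Z.index, name="profile").reindex(mat.index, fill_value=-1),
        centroids=pd.DataFrame(km.cluster_centers_, columns=Z.columns),
        correlation=pd.Series(corr, index=Z.index).reindex(mat.index),
    )


def maintenance_overlap(early: PeakSet, adult_biased: PeakSet) -> tuple[float, np.ndarray]:
    """Fraction of early (e.g. neonatally regulated) peaks that overlap
    adult sex-biased peaks by >= 1 bp, plus the per-peak flags."""
    from .intervals import overlaps_mask

    flags = overlaps_mask(early, adult_biased)
    frac = float(flags.mean()) if len(early) else 0.0
    return frac, flags
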