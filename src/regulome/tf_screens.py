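"""Transcription-factor screens.

Two procedures: (1) ranking TFs by the R^2 of a linear regression of
per-cluster sex-DEG counts on per-cluster TF detection rates, and
(2) an identity-regulator screen combining the correlation of TF RNA
expression with its motif deviation score and the TF's maximum
inter-cluster expression fold change.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import stats

__all__ = ["percent_expressing", "tf_r2_ranking", "identity_regulator_screen"]


def percent_expressing(cells: AnnData, genes: list[str], cluster_key: str = "cluster") -> pd.DataFrame:
    """Percent of cells with >= 1 count, per gene per cluster."""
    X = cells.X
    X = np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X)
    idx = [list(cells.var_names).index(g) for g in genes]
    det = X[:, idx] >= 1
    out = {}
    for c, rows in cells.obs.groupby(cluster_key, observed=True).indices.items():
        out[c] = det[rows].mean(axis=0) * 100.0
    return pd.DataFrame(out, index=genes)


def tf_r2_ranking(
    cells: AnnData,
    sex_deg_counts: pd.Series,
    tf_list: list[str],
    cluster_key: str = "cluster",
) -> pd.DataFrame:
    """Rank TFs by R^2 of DEG count per cluster on TF detection rate.

    Ordinary least squares with the per-cluster percent of expressing
    cells as the predictor and the sex-DEG count as the response; R^2 is
    the squared Pearson correlation. Constant-predictor TFs get R^2 = 0
    and a flag. Descending R^2, ties broken by TF id.
    """
    clusters = list(sex_deg_counts.index)
    if len(clusters) < 3:
        raise ValueError("need >= 3 clusters")
    tfs = [t for t in tf_list if t in set(cells.var_names)]
    pct = percent_expressing(cells, tfs, cluster_key=cluster_key)[clusters]
    y = sex_deg_counts.to_numpy(dtype=float)
    rows = []
    for tf in tfs:
        x = pct.loc[tf].to_numpy(dtype=float)
        if np.std(x) == 0:
            rows.append({"tf": tf, "r2": 0.0, "slope": 0.0, "constant_predictor": True})
            continue
        fit = stats.linregress(x, y)
        rows.append({
            "tf": tf, "r2": fit.rvalue**2, "slope": fit.slope,
            "constant_predictor": False,
        })
    res = pd.DataFrame(rows).sort_values(
        ["r2", "tf"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    res["rank"] = np.arange(1, len(res) + 1)
    return res


def identity_regulator_screen(
    tf_expression: pd.DataFrame,
    deviations: pd.DataFrame,
    tf_motif_pairs: dict[str, str],
    clusters: pd.Series,
    r_threshold: float = 0.5,
    lfc_quantile: float = 0.5,
    use_cluster_means: bool = False,
) -> pd.DataFrame:
    """Classify TFs as identity regulators.

    tf_expression : cells x TFs log-normalised expression
    deviations    : cells x motifs deviation z-scores
    tf_motif_pairs: TF id -> motif id
    clusters      : per-cell cluster label

    A TF is called iff the Pearson correlation between its expression
    and its motif deviation exceeds ``r_threshold`` AND its maximum
    inter-cluster expression log2FC is in the top (1 - lfc_quantile)
    fraction across screened TFs. Zero-variance TFs are excluded; TFs
    without a paired motif are skipped with a warning.
    """
    rows = []
    eps = 1e-9
    cl = clusters.astype(str)
    for tf in tf_expression.columns:
        motif = tf_motif_pairs.get(tf)
        if motif is None or motif not in deviations.columns:
            warnings.warn(f"TF {tf!r} has no paired motif; skipped")
            continue
        x = tf_expression[tf].to_numpy(dtype=float)
        z = deviations[motif].to_numpy(dtype=float)
        if np.std(x) == 0:
            continue
        if use_cluster_means:
            xm = pd.Series(x).groupby(cl.values).mean()
            zm = pd.Series(z).groupby(cl.values).mean()
            r = float(np.corrcoef(xm, zm)[0, 1])
        else:
            r = float(np.corrcoef(x, z)[0, 1])
        means = pd.Series(np.expm1(x) if (x >= 0).all() else x).groupby(cl.values).mean()
        lo, hi = means.min(), means.max()
        max_lfc = float(np.log2((hi + eps) / (lo + eps)))
        rows.append({"tf": tf, "motif": motif, "r": r, "max_log2fc": max_lfc})
    res = pd.DataFrame(rows)
    if res.empty:
        return res.assign(regulator=pd.Series(dtype=bool))
    cutoff = res["max_log2fc"].quantile(lfc_quantile)
    res["regulator"] = (res["r"] > r_threshold) & (res["max_log2fc"] >= cutoff)
    return res.sort_values("r", ascending=False).reset_index(drop=True)
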