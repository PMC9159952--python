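"""Differential cell-type abundance between sexes.

Per-replicate cluster proportions, outlier-replicate exclusion on a
required-detection rule, and a one-sided exact Wilcoxon rank-sum test
per cluster with BH adjustment across the cluster family.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from anndata import AnnData

from .stats import bh_adjust, wilcoxon_onesided

__all__ = ["proportions", "flag_outlier_replicates", "abundance_test"]


def proportions(
    cells: AnnData,
    clusters: list[str] | None = None,
    cluster_key: str = "cluster",
    replicate_key: str = "replicate",
    sex_key: str = "sex",
) -> pd.DataFrame:
    """Replicate x cluster proportion table over a cluster subset.

    Each row sums to 1 over the included clusters; a replicate with no
    cells in the subset gets a zero row and is flagged. Columns also
    carry the replicate's sex and total subset cell count.
    """
    obs = cells.obs
    if clusters is None:
        clusters = sorted(obs[cluster_key].astype(str).unique())
    counts = (
        obs.assign(_c=obs[cluster_key].astype(str))
        .groupby([replicate_key, "_c"], observed=False)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=clusters, fill_value=0)
    )
    totals = counts.sum(axis=1)
    props = counts.div(totals.replace(0, np.nan), axis=0).fillna(0.0)
    sex = obs.groupby(replicate_key, observed=True)[sex_key].first()
    props.insert(0, "sex", sex.reindex(props.index))
    props["total_cells"] = totals
    props["empty_flag"] = totals == 0
    return props


def flag_outlier_replicates(
    pt: pd.DataFrame, required_clusters: list[str]
) -> pd.Series:
    """Flag replicates with zero cells in any required cluster.

    ``pt`` is the proportions table (must still include every required
    cluster column). A replicate is flagged iff any required cluster has
    proportion 0 (no detection).
    """
    for c in required_clusters:
        if c not in pt.columns:
            raise KeyError(f"required cluster {c!r} unknown")
    return (pt[required_clusters] == 0).any(axis=1).rename("outlier")


def abundance_test(
    pt: pd.DataFrame,
    alternative: str = "male_greater",
    sex_levels: tuple[str, str] = ("F", "M"),
    exclude: pd.Series | None = None,
) -> pd.DataFrame:
    """One-sided exact Wilcoxon rank-sum per cluster, BH across clusters.

    ``alternative='male_greater'`` tests that the second sex level has
    higher proportions. Replicates flagged True in ``exclude`` are
    dropped first.
    """
    tab = pt if exclude is None else pt.loc[~exclude.reindex(pt.index, fill_value=False)]
    clusters = [c for c in tab.columns if c not in ("sex", "total_cells", "empty_flag")]
    f = tab[tab["sex"] == sex_levels[0]]
    m = tab[tab["sex"] == sex_levels[1]]
    alt = "y_greater" if alternative == "male_greater" else "y_less"
    rows = []
    for c in clusters:
        w, p = wilcoxon_onesided(f[c].to_numpy(), m[c].to_numpy(), alternative=alt)
        rows.append({"cluster": c, "W": w, "p": p})
    res = pd.DataFrame(rows).set_index("cluster")
    res["p_adj"] = bh_adjust(res["p"].to_numpy())
    return res
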