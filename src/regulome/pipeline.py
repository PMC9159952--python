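"""End-to-end orchestration on synthetic data.

``run`` executes the full chain — simulate, QC, per-cluster pseudo-bulk
differential expression, cluster abundance, multi-condition chromatin
states (adult four-group and neonatal three-group), motif enrichment
with matched background, per-cell motif deviations and the identity-
regulator screen, peak-gene linking, split-half cluster matching and
the maintenance-overlap statistic — and emits a manifest with every
stage's parameters, per-stage runtime, and a truth-recovery report.

Each stage draws its seed deterministically from the master seed, so a
rerun with the same config is bit-identical (manifest timestamps aside).
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import abundance as ab
from . import chromatin, cluster_match, linking, motifs, pseudobulk, simulate
from .io import QCBounds, qc_filter
from .simulate import SimulationConfig
from .tf_screens import identity_regulator_screen

__all__ = ["PipelineConfig", "run"]


@dataclass
class PipelineConfig:
    """Stage toggles and the defaults used throughout the pipeline."""

    seed: int = 0
    outdir: str | None = None
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    # stage parameters (defaults follow the published analysis settings)
    de_alpha: float = 0.1            # pseudo-bulk DE adjusted-p cutoff
    min_cells_per_replicate: int = 20
    esr1_threshold_pct: float = 0.25
    state_k: int = 4
    state_prune_r: float = 0.8
    state_p_adj: float = 0.01
    ne_k_cut: int = 6
    ne_p_adj: float = 0.05
    link_min_distance: float = 2_000
    link_max_distance: float = 1_000_000
    link_min_cells_frac: float = 0.02
    link_p_adj: float = 0.05
    regulator_r_threshold: float = 0.5
    regulator_lfc_quantile: float = 0.5
    deviation_background_sets: int = 50
    maintenance_fraction: float = 0.10
    motif_planting_rate: float = 0.8
    stages: tuple[str, ...] = (
        "simulate", "qc", "de", "abundance", "states", "ne_states",
        "motifs", "regulators", "links", "match", "maintenance",
    )


def _seed_for(cfg: PipelineConfig, stage: str) -> int:
    return (cfg.seed * 1009 + sum(map(ord, stage))) % (2**31 - 1)


def run(cfg: PipelineConfig | None = None) -> dict:
    """Run the pipeline; returns the manifest (also written to outdir)."""
    cfg = cfg or PipelineConfig()
    manifest: dict = {"seed": cfg.seed, "stages": {}, "metrics": {}}
    out = Path(cfg.outdir) if cfg.outdir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    def stage(name):
        return name in cfg.stages

    t0 = time.time()

    # --- simulate ----------------------------------------------------------
    sim_cfg = SimulationConfig(**{**asdict(cfg.sim), "seed": _seed_for(cfg, "simulate")})
    rna, atac, peaks, truth = simulate.generate_multiome(sim_cfg)
    manifest["stages"]["simulate"] = {
        "seconds": round(time.time() - t0, 2),
        "n_cells": int(rna.n_obs), "n_genes": int(rna.n_vars),
        "n_peaks": int(atac.n_vars),
    }

    # --- qc ----------------------------------------------------------------
    if stage("qc"):
        t = time.time()
        rna, qc_report = qc_filter(rna, QCBounds())
        atac = atac[rna.obs_names].copy()
        manifest["stages"]["qc"] = {"seconds": round(time.time() - t, 2),
                                    **qc_report}

    # --- pseudo-bulk sex DE per cluster -------------------------------------
    if stage("de"):
        t = time.time()
        filtered = pseudobulk.filter_genes(rna)
        calls, tables, skipped = set(), [], []
        for cluster in sorted(rna.obs["cluster"].unique()):
            pb = pseudobulk.aggregate(
                filtered, cluster, min_cells=cfg.min_cells_per_replicate)
            sexes = pb.meta.get("sex", pd.Series(dtype=object))
            if (sexes.nunique() < 2
                    or sexes.value_counts().min() < 2):
                # no eligible replicates in one group: untestable cluster
                skipped.append(cluster)
                continue
            res = pseudobulk.nb_wald(pb, group_key="sex")
            res["cluster"] = cluster
            tables.append(res)
            hits = res.index[res["p_adj"] < cfg.de_alpha]
            calls |= {(cluster, g) for g in hits}
        truth_pairs = {
            (r.cluster, r.gene) for r in truth.sex_degs.itertuples()
            if r.gene in set(filtered.var_names)
            and r.cluster not in set(skipped)
        }
        tp = len(calls & truth_pairs)
        sens = tp / len(truth_pairs) if truth_pairs else np.nan
        fdr = (len(calls) - tp) / len(calls) if calls else 0.0
        manifest["metrics"]["sex_deg_sensitivity"] = round(sens, 4)
        manifest["metrics"]["sex_deg_fdr"] = round(fdr, 4)
        manifest["metrics"]["sex_deg_calls"] = len(calls)
        manifest["stages"]["de"] = {"seconds": round(time.time() - t, 2),
                                    "skipped_clusters": skipped}
        if out:
            pd.concat(tables).to_csv(out / "sex_degs.tsv", sep="\t")
        deg_counts = pd.Series(
            [c for c, _ in calls], dtype=object).value_counts()

    # --- abundance (no effect planted; expected null) ------------------------
    if stage("abundance"):
        t = time.time()
        pt = ab.proportions(rna)
        res = ab.abundance_test(pt)
        manifest["metrics"]["abundance_min_p_adj"] = round(float(res["p_adj"].min()), 4)
        manifest["stages"]["abundance"] = {"seconds": round(time.time() - t, 2)}
        if out:
            res.to_csv(out / "abundance.tsv", sep="\t")

    # --- adult four-condition chromatin states -------------------------------
    if stage("states"):
        t = time.time()
        counts, design, bulk_peaks, bulk_truth = simulate.generate_condition_atac(
            SimulationConfig(**{**asdict(cfg.sim), "seed": _seed_for(cfg, "states")}))
        res = chromatin.multi_condition_test(counts, design,
                                             factors=("group",), contrast="anova")
        diff = res.index[res["p_adj"] < cfg.state_p_adj]
        cpm_means = (
            chromatin.cpm(counts).T.groupby(design["group"]).mean().T
        )
        states = chromatin.kmeans_states(
            cpm_means.loc[diff], k=cfg.state_k, prune_r=cfg.state_prune_r,
            seed=_seed_for(cfg, "kmeans"))
        lab = bulk_truth.peak_archetypes
        planted = lab.index[(lab != "null")]
        both = [p for p in planted if p in diff and states.labels[p] != -1]
        ari = adjusted_rand_score(lab[both], states.labels[both]) if both else np.nan
        manifest["metrics"]["archetype_ari"] = round(float(ari), 4)
        manifest["metrics"]["archetype_n_differential"] = int(len(diff))
        manifest["stages"]["states"] = {"seconds": round(time.time() - t, 2)}

    # --- neonatal three-group NE states --------------------------------------
    if stage("ne_states"):
        t = time.time()
        counts, design, ne_peaks, ne_truth = simulate.generate_condition_atac(
            SimulationConfig(**{**asdict(cfg.sim), "seed": _seed_for(cfg, "ne")}),
            groups=simulate.neonatal_three_group_groups(),
            archetypes=simulate.NEONATAL_ARCHETYPES,
            peaks_per_archetype=simulate.NEONATAL_ARCHETYPE_SIZES,
        )
        res = chromatin.multi_condition_test(counts, design,
                                             factors=("group",), contrast="anova")
        diff = res.index[res["p_adj"] < cfg.ne_p_adj]
        cpm_means = chromatin.cpm(counts).T.groupby(design["group"]).mean().T
        ne = chromatin.hierarchical_ne_states(cpm_means.loc[diff], k_cut=cfg.ne_k_cut)
        lab = ne_truth.peak_archetypes
        for state in ("NE-open", "NE-close"):
            called = set(ne.index[ne["ne_state"] == state])
            true = set(lab.index[lab == state]) & set(diff)
            key = state.lower().replace("-", "_")
            manifest["metrics"][f"{key}_precision"] = round(
                len(called & true) / len(called), 4) if called else np.nan
            manifest["metrics"][f"{key}_recall"] = round(
                len(called & true) / len(true), 4) if true else np.nan
        ne_open_peak_names = sorted(set(lab.index[lab == "NE-open"]))
        manifest["stages"]["ne_states"] = {"seconds": round(time.time() - t, 2)}

    # --- motif enrichment with matched background ----------------------------
    if stage("motifs"):
        if not stage("ne_states"):
            raise ValueError(
                "stage 'motifs' consumes NE-open peaks; enable stage "
                "'ne_states' (its producer) or drop 'motifs'")
        t = time.time()
        motif_set = simulate.default_motifs()
        fg_names = ne_open_peak_names
        plan = {"ERE": (fg_names, cfg.motif_planting_rate)}
        seq_peaks, planted = simulate.generate_motif_sequences(
            ne_peaks, motif_set, plan, seed=_seed_for(cfg, "motifseq"))
        fg = seq_peaks.subset(seq_peaks.df["name"].isin(fg_names).to_numpy())
        pool = seq_peaks.subset(~seq_peaks.df["name"].isin(fg_names).to_numpy())
        bg = motifs.matched_background(fg, pool, n_per_peak=2,
                                       seed=_seed_for(cfg, "bg"))
        fg_hits, bg_hits = [], []
        for m in motif_set:
            fg_hits.append(motifs.scan(fg, m).assign(motif=m.id))
            bg_hits.append(motifs.scan(bg, m).assign(motif=m.id))
        enr = motifs.enrich(pd.concat(fg_hits), pd.concat(bg_hits),
                            n_foreground=len(fg), n_background=len(bg))
        manifest["metrics"]["top_enriched_motif"] = str(enr.iloc[0]["motif"])
        manifest["metrics"]["ere_frac_foreground"] = round(
            float(enr.set_index("motif").loc["ERE", "frac_foreground"]), 4)
        manifest["stages"]["motifs"] = {"seconds": round(time.time() - t, 2)}
        if out:
            enr.to_csv(out / "motif_enrichment.tsv", sep="\t", index=False)

    # --- deviations + identity-regulator screen ------------------------------
    if stage("regulators"):
        t = time.time()
        dev = motifs.deviations(
            atac, truth.tf_motif_peaks, peaks,
            n_background_sets=cfg.deviation_background_sets,
            seed=_seed_for(cfg, "dev"))
        X = np.asarray(rna.X)
        depth = np.maximum(X.sum(axis=1, keepdims=True), 1.0)
        logn = np.log1p(X / depth * 1e4)
        tf_expr = pd.DataFrame(
            logn[:, [list(rna.var_names).index(tf) for tf in truth.tf_list]],
            index=rna.obs_names, columns=truth.tf_list)
        pairs = {tf: f"MOTIF_{tf}" for tf in truth.tf_list}
        screen = identity_regulator_screen(
            tf_expr, dev, pairs, rna.obs["cluster"],
            r_threshold=cfg.regulator_r_threshold,
            lfc_quantile=cfg.regulator_lfc_quantile)
        called = set(screen[screen["regulator"]]["tf"])
        true_regs = set(truth.regulators["tf"])
        prec = len(called & true_regs) / len(called) if called else np.nan
        rec = len(called & true_regs) / len(true_regs) if true_regs else np.nan
        manifest["metrics"]["regulator_precision"] = round(float(prec), 4)
        manifest["metrics"]["regulator_recall"] = round(float(rec), 4)
        manifest["stages"]["regulators"] = {"seconds": round(time.time() - t, 2)}
        if out:
            screen.to_csv(out / "identity_regulators.tsv", sep="\t", index=False)

    # --- peak-gene links ------------------------------------------------------
    if stage("links"):
        t = time.time()
        X = np.asarray(rna.X)
        depth = np.maximum(X.sum(axis=1, keepdims=True), 1.0)
        logn_rna = np.log1p(X / depth * 1e4)
        A = np.asarray(atac.X)
        depth_a = np.maximum(A.sum(axis=1, keepdims=True), 1.0)
        logn_atac = np.log1p(A / depth_a * 1e4)
        link_genes = list(truth.links["gene"])
        gi = [list(rna.var_names).index(g) for g in link_genes]
        expr = pd.DataFrame(logn_rna[:, gi], index=rna.obs_names,
                            columns=link_genes)
        acc_df = pd.DataFrame(logn_atac, index=atac.obs_names,
                              columns=atac.var_names)
        tss = pd.Series(rna.var["tss"].to_numpy(), index=rna.var_names)
        centers = pd.Series(
            ((peaks.df["start"] + peaks.df["end"]) / 2).to_numpy(),
            index=peaks.df["name"])
        links = linking.link_peaks(
            expr, acc_df, tss, centers,
            min_distance=cfg.link_min_distance,
            max_distance=cfg.link_max_distance,
            min_cells_frac=cfg.link_min_cells_frac)
        called = set(map(tuple, links.loc[links["p_adj"] < cfg.link_p_adj,
                                          ["gene", "peak"]].to_numpy()))
        true_links = set(map(tuple, truth.links[["gene", "peak"]].to_numpy()))
        sens = len(called & true_links) / len(true_links) if true_links else np.nan
        manifest["metrics"]["link_sensitivity"] = round(float(sens), 4)
        manifest["stages"]["links"] = {"seconds": round(time.time() - t, 2)}
        if out:
            links.to_csv(out / "links.tsv", sep="\t", index=False)

    # --- split-half cluster matching -----------------------------------------
    if stage("match"):
        t = time.time()
        rng = np.random.default_rng(_seed_for(cfg, "match"))
        half = rng.random(rna.n_obs) < 0.5
        a, b = rna[half].copy(), rna[~half].copy()
        genes = cluster_match.cross_dataset_variable_genes(a, b, n_genes=500)
        auc = cluster_match.neighbor_vote_auroc(a, b, genes)
        diag = np.array([auc.loc[c, c] for c in auc.index if c in auc.columns])
        manifest["metrics"]["match_median_self_auroc"] = round(
            float(np.median(diag)), 4)
        manifest["stages"]["match"] = {"seconds": round(time.time() - t, 2)}
        if out:
            auc.to_csv(out / "cluster_match_auroc.tsv", sep="\t")

    # --- maintenance overlap --------------------------------------------------
    if stage("maintenance"):
        t = time.time()
        early, adult, planted_frac = simulate.generate_maintenance_instance(
            overlap_fraction=cfg.maintenance_fraction,
            seed=_seed_for(cfg, "maintenance"))
        frac, _ = chromatin.maintenance_overlap(early, adult)
        manifest["metrics"]["maintenance_fraction"] = round(float(frac), 4)
        manifest["metrics"]["maintenance_planted"] = round(float(planted_frac), 4)
        manifest["stages"]["maintenance"] = {"seconds": round(time.time() - t, 2)}

    manifest["total_seconds"] = round(time.time() - t0, 2)
    if out:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
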