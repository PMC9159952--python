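"""Synthetic multiome generator with planted ground truth.

Emulates the statistical structure of the datasets the pipeline is
designed for — negative-binomial counts with biological-replicate
structure, cluster identity programs, sex-biased genes planted per
cluster, hormone-condition peak archetypes, motif-bearing peak
sequences and coupled TF-expression/accessibility — on a toy
single-chromosome genome, so that every downstream stage has a known
answer. Only statistical structure is emulated, never real content.

All randomness flows through one seeded generator; a fixed seed gives
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData

from .intervals import PeakSet
from .motifs import MotifModel

__all__ = [
    "SimulationConfig", "TruthTable", "generate_multiome",
    "generate_condition_atac", "generate_motif_sequences",
    "generate_maintenance_instance", "default_motifs",
    "adult_four_condition_groups", "neonatal_three_group_groups",
]


def adult_four_condition_groups() -> dict[str, tuple[str, str]]:
    """Adult gonadally-intact vs gonadectomised design: group -> (sex, treatment)."""
    return {
        "intact-F": ("F", "intact"), "intact-M": ("M", "intact"),
        "GDX-F": ("F", "GDX"), "GDX-M": ("M", "GDX"),
    }


def neonatal_three_group_groups() -> dict[str, tuple[str, str]]:
    """Neonatal design: vehicle females/males and oestradiol-treated females."""
    return {"NV-F": ("F", "vehicle"), "NV-M": ("M", "vehicle"),
            "NE-F": ("F", "E2")}


# archetype -> per-group mean multiplier (adult four-condition order)
ADULT_ARCHETYPES = {
    "male-intact-open": {"intact-F": 1, "intact-M": 4, "GDX-F": 1, "GDX-M": 1},
    "female-intact-open": {"intact-F": 4, "intact-M": 1, "GDX-F": 1, "GDX-M": 1},
    "close-on-GDX": {"intact-F": 4, "intact-M": 4, "GDX-F": 1, "GDX-M": 1},
    "open-on-GDX": {"intact-F": 1, "intact-M": 1, "GDX-F": 4, "GDX-M": 4},
}

NEONATAL_ARCHETYPES = {
    "NE-open": {"NV-F": 1, "NV-M": 4, "NE-F": 4},
    "NE-close": {"NV-F": 4, "NV-M": 1, "NE-F": 1},
    "F-only-open": {"NV-F": 1, "NV-M": 1, "NE-F": 4},
    "M-only-open": {"NV-F": 1, "NV-M": 4, "NE-F": 1},
}

# scaled-down class sizes mirroring the neonatal study, where regions
# opened by the oestradiol surge far outnumber closed ones and minor
# patterns are rare (full-scale counts are in the thousands/hundreds)
NEONATAL_ARCHETYPE_SIZES = {
    "NE-open": 200, "NE-close": 100, "F-only-open": 40, "M-only-open": 40,
}


@dataclass
class SimulationConfig:
    """Study-condition defaults for the synthetic multiome.

    The multiome emulates seven hormone-receptive inhibitory-neuron
    clusters profiled across 5 biological replicates per sex (~3,000
    nuclei total), 2,000 genes and 3,000 peaks on a 6-Mb toy chromosome.
    """

    seed: int = 0
    n_clusters: int = 7
    cells_per_cluster_per_replicate: int = 42
    replicates_per_sex: int = 3 + 2       # 5; scaled down from 7-8 per sex
    n_genes: int = 2000
    n_peaks: int = 3000
    # negative-binomial structure
    gene_mean_log_mu: float = np.log(0.5)
    gene_mean_log_sigma: float = 1.0
    dispersion_log_mu: float = np.log(0.05)
    dispersion_log_sigma: float = 0.5
    replicate_log_sigma: float = 0.15
    library_log_sigma: float = 0.3
    # identity programs
    markers_per_cluster: int = 20
    marker_log2fc: float = 2.5
    # planted sex effects
    n_sex_degs: int = 200
    sex_deg_log2fc: float = 1.5
    max_clusters_per_deg: int = 3
    # ATAC
    peak_mean_log_mu: float = np.log(0.4)
    peak_mean_log_sigma: float = 0.8
    peaks_per_regulator: int = 60
    n_regulators: int = 5
    n_tfs: int = 100
    regulator_coupling: float = 0.8
    n_sex_biased_peaks: int = 100
    sex_peak_log2fc: float = 1.5
    # peak-gene links
    n_links: int = 50
    link_coupling: float = 0.6
    # bulk condition design
    bulk_replicates_per_group: int = 3
    bulk_peak_mean_log_mu: float = np.log(50.0)
    bulk_peak_mean_log_sigma: float = 0.7
    bulk_dispersion_log_mu: float = np.log(0.05)
    bulk_dispersion_log_sigma: float = 0.4
    peaks_per_archetype: dict = field(default_factory=lambda: {})
    # toy genome
    peak_width: int = 501
    peak_spacing: int = 2000
    background_gc: float = 0.45

    def validate(self) -> None:
        if self.n_sex_degs > self.n_genes:
            raise ValueError("more planted sex DEGs than genes")
        if self.n_regulators * self.peaks_per_regulator > self.n_peaks:
            raise ValueError("regulator peak sets exceed the peak universe")
        if min(self.n_clusters, self.n_genes, self.n_peaks,
               self.replicates_per_sex,
               self.cells_per_cluster_per_replicate) < 1:
            raise ValueError("all counts must be positive")


@dataclass
class TruthTable:
    """Ground truth for every planted effect."""

    sex_degs: pd.DataFrame          # cluster, gene, log2fc (M over F)
    cluster_markers: pd.DataFrame   # cluster, gene
    tf_list: list[str]
    regulators: pd.DataFrame        # tf, motif, cluster
    regulator_peaks: dict           # motif -> [peak names] (coupled)
    tf_motif_peaks: dict            # motif -> [peak names], every TF
    sex_biased_peaks: pd.DataFrame  # peak, clusters, log2fc
    links: pd.DataFrame             # gene, peak
    peak_archetypes: pd.Series      # peak -> archetype or 'null'
    planted_motifs: pd.DataFrame    # motif, peak, offset, strand


def default_motifs() -> list[MotifModel]:
    """A small built-in motif set: an oestrogen-response-element-like
    palindromic PWM, an androgen-response-element-like PWM, a GC-rich
    motif (to exercise GC confounding) and two neutral controls."""
    def sharp(consensus: str, p: float = 0.9) -> np.ndarray:
        mat = np.full((len(consensus), 4), (1 - p) / 3)
        for i, b in enumerate(consensus):
            mat[i, "ACGT".index(b)] = p
        return mat

    return [
        MotifModel("ERE", sharp("GGTCACAGTGACC")),
        MotifModel("ARE", sharp("GGAACATACTGTTCC")),
        MotifModel("GCBOX", sharp("GGGCGGGGCG")),
        MotifModel("CTRL1", sharp("ATTACGTAAT")),
        MotifModel("CTRL2", sharp("CATTGCAATG")),
    ]


def _toy_peaks(cfg: SimulationConfig) -> PeakSet:
    starts = np.arange(cfg.n_peaks) * cfg.peak_spacing + 500
    df = pd.DataFrame({
        "chrom": "chr1",
        "start": starts,
        "end": starts + cfg.peak_width,
        "name": [f"peak_{i:05d}" for i in range(cfg.n_peaks)],
        "summit": starts + cfg.peak_width // 2,
    })
    return PeakSet(df)


def _gene_tss(cfg: SimulationConfig) -> pd.Series:
    genome_length = cfg.n_peaks * cfg.peak_spacing + 1000
    pos = np.linspace(0, genome_length - 1, cfg.n_genes).astype(int)
    return pd.Series(pos, index=[f"gene_{i:04d}" for i in range(cfg.n_genes)])


def _nb_counts(rng, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Gamma-Poisson draw with Var = mu + alpha mu^2 (alpha may be ~0)."""
    shape = 1.0 / np.maximum(alpha, 1e-8)
    lam = rng.gamma(shape, 1.0 / shape, size=mean.shape) * mean
    return rng.poisson(lam)


def generate_multiome(cfg: SimulationConfig | None = None):
    """Generate (rna, atac, peaks, truth).

    rna, atac : AnnData, same nuclei (cells x genes / cells x peaks),
    obs columns cluster, sex, replicate, condition, timepoint plus QC
    metrics; peaks : PeakSet with summits on the toy genome; truth :
    TruthTable listing every planted effect.
    """
    cfg = cfg or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    genes = [f"gene_{i:04d}" for i in range(cfg.n_genes)]
    peaks = _toy_peaks(cfg)
    peak_names = list(peaks.df["name"])
    tss = _gene_tss(cfg)

    # --- cell metadata -----------------------------------------------------
    sexes = ["F", "M"]
    rows = []
    for sex in sexes:
        for rep in range(cfg.replicates_per_sex):
            rep_id = f"{sex}{rep + 1}"
            for c in range(cfg.n_clusters):
                for _ in range(cfg.cells_per_cluster_per_replicate):
                    rows.append((f"c{c}", sex, rep_id))
    obs = pd.DataFrame(rows, columns=["cluster", "sex", "replicate"])
    obs["condition"] = "intact"
    obs["timepoint"] = "P4"
    obs.index = [f"cell_{i:05d}" for i in range(len(obs))]
    n_cells = len(obs)
    cluster_idx = obs["cluster"].str[1:].astype(int).to_numpy()
    is_male = (obs["sex"] == "M").to_numpy()

    # --- RNA truth ---------------------------------------------------------
    base_mean = rng.lognormal(cfg.gene_mean_log_mu, cfg.gene_mean_log_sigma,
                              cfg.n_genes)
    dispersion = rng.lognormal(cfg.dispersion_log_mu, cfg.dispersion_log_sigma,
                               cfg.n_genes)

    tf_list = [genes[i] for i in rng.choice(cfg.n_genes, cfg.n_tfs, replace=False)]
    marker_rows = []
    marker_boost = np.ones((cfg.n_clusters, cfg.n_genes))
    free = [g for g in range(cfg.n_genes)]
    # planted regulators double as markers of distinct clusters; identity
    # TFs are robustly expressed, so draw them from the better-expressed
    # half of the TF catalogue
    tf_means = np.array([base_mean[genes.index(t)] for t in tf_list])
    well_expressed = [t for t, m in zip(tf_list, tf_means)
                      if m >= np.median(tf_means)]
    reg_tfs = list(rng.choice(well_expressed, cfg.n_regulators, replace=False))
    reg_clusters = list(rng.choice(cfg.n_clusters, cfg.n_regulators, replace=False)) \
        if cfg.n_regulators <= cfg.n_clusters else \
        list(rng.integers(0, cfg.n_clusters, cfg.n_regulators))
    for tf, c in zip(reg_tfs, reg_clusters):
        gi = genes.index(tf)
        marker_boost[c, gi] *= 2.0 ** (cfg.marker_log2fc + 0.5)
        marker_rows.append({"cluster": f"c{c}", "gene": tf})
        if gi in free:
            free.remove(gi)
    for c in range(cfg.n_clusters):
        picked = rng.choice(free, cfg.markers_per_cluster, replace=False)
        for gi in picked:
            marker_boost[c, gi] *= 2.0 ** cfg.marker_log2fc
            marker_rows.append({"cluster": f"c{c}", "gene": genes[gi]})
            free.remove(gi)
    cluster_markers = pd.DataFrame(marker_rows)

    # sex DEGs planted multiplicatively on cluster baselines, preferring
    # genes above median expression so effects are detectable at scale
    eligible = np.flatnonzero(base_mean >= np.median(base_mean))
    eligible = np.array([g for g in eligible if g in set(free)])
    deg_genes = rng.choice(eligible, min(cfg.n_sex_degs, len(eligible)),
                           replace=False)
    sex_mult = np.ones((cfg.n_clusters, cfg.n_genes))
    deg_rows = []
    for gi in deg_genes:
        sign = 1 if rng.random() < 0.5 else -1
        k = int(rng.integers(1, min(cfg.max_clusters_per_deg,
                                    cfg.n_clusters) + 1))
        for c in rng.choice(cfg.n_clusters, k, replace=False):
            sex_mult[c, gi] = 2.0 ** (sign * cfg.sex_deg_log2fc)
            deg_rows.append({
                "cluster": f"c{c}", "gene": genes[gi],
                "log2fc": sign * cfg.sex_deg_log2fc,
            })
    sex_degs = pd.DataFrame(deg_rows)

    # replicate-level biological noise, per gene
    reps = sorted(obs["replicate"].unique())
    rep_idx = obs["replicate"].map({r: i for i, r in enumerate(reps)}).to_numpy()
    rep_noise = rng.lognormal(0.0, cfg.replicate_log_sigma,
                              (len(reps), cfg.n_genes))
    lib = rng.lognormal(0.0, cfg.library_log_sigma, n_cells)

    mean_cg = (base_mean[None, :]
               * marker_boost[cluster_idx]
               * np.where(is_male[:, None], sex_mult[cluster_idx], 1.0)
               * rep_noise[rep_idx]
               * lib[:, None])

    # latent per-cell factor coupling planted gene-peak link pairs
    u = rng.normal(0.0, 1.0, n_cells)
    link_gene_idx = rng.choice(
        [g for g in eligible if g not in set(deg_genes)],
        cfg.n_links, replace=False)
    link_rows = []
    for gi in link_gene_idx:
        mean_cg[:, gi] = mean_cg[:, gi] * np.exp(cfg.link_coupling * u
                                                 - cfg.link_coupling**2 / 2)

    # --- ATAC --------------------------------------------------------------
    peak_base = rng.lognormal(cfg.peak_mean_log_mu, cfg.peak_mean_log_sigma,
                              cfg.n_peaks)
    peak_disp = rng.lognormal(cfg.dispersion_log_mu, cfg.dispersion_log_sigma,
                              cfg.n_peaks)
    atac_lib = rng.lognormal(0.0, cfg.library_log_sigma, n_cells)
    mean_cp = np.tile(peak_base, (n_cells, 1))

    # regulator-coupled peaks: accessibility follows the TF's underlying
    # (noise-free) expression rate on the log scale
    free_peaks = list(range(cfg.n_peaks))
    regulator_peaks: dict[str, list[str]] = {}
    reg_rows = []
    for tf, c in zip(reg_tfs, reg_clusters):
        gi = genes.index(tf)
        motif = f"MOTIF_{tf}"
        chosen = rng.choice(free_peaks, cfg.peaks_per_regulator, replace=False)
        for p in chosen:
            free_peaks.remove(int(p))
        regulator_peaks[motif] = [peak_names[p] for p in chosen]
        rate = np.log(base_mean[gi] * marker_boost[cluster_idx, gi])
        z = (rate - rate.mean()) / max(rate.std(), 1e-9)
        mult = np.exp(cfg.regulator_coupling * z)
        mean_cp[:, chosen] *= mult[:, None]
        reg_rows.append({"tf": tf, "motif": motif, "cluster": f"c{c}"})
    regulators = pd.DataFrame(reg_rows)

    # every other TF gets an uncoupled motif annotation (random peaks,
    # overlaps allowed) so the identity screen can scan the full catalogue
    tf_motif_peaks = dict(regulator_peaks)
    uncoupled_pool = np.array(free_peaks)
    for tf in tf_list:
        if tf in reg_tfs:
            continue
        chosen = rng.choice(uncoupled_pool,
                            min(cfg.peaks_per_regulator, len(uncoupled_pool)),
                            replace=False)
        tf_motif_peaks[f"MOTIF_{tf}"] = [peak_names[p] for p in chosen]

    # sex-biased peaks restricted to a subset of clusters (male-open)
    sexpeak_idx = rng.choice(free_peaks, cfg.n_sex_biased_peaks, replace=False)
    for p in sexpeak_idx:
        free_peaks.remove(int(p))
    # cluster-restricted male-open loci: a strict subset of clusters, so
    # the (M - F) profile varies across clusters after row scaling
    n_target = min(3, max(1, cfg.n_clusters - 1))
    sex_peak_clusters = sorted(rng.choice(cfg.n_clusters, n_target,
                                          replace=False))
    in_target = np.isin(cluster_idx, sex_peak_clusters)
    boost = np.where(is_male & in_target, 2.0 ** cfg.sex_peak_log2fc, 1.0)
    mean_cp[:, sexpeak_idx] *= boost[:, None]
    sex_biased_peaks = pd.DataFrame({
        "peak": [peak_names[p] for p in sexpeak_idx],
        "clusters": [",".join(f"c{c}" for c in sex_peak_clusters)] * len(sexpeak_idx),
        "log2fc": cfg.sex_peak_log2fc,
    })

    # planted peak-gene links: peak within the 2 kb - 1 Mb window of the
    # gene TSS, accessibility driven by the same latent factor
    for gi in link_gene_idx:
        pos = tss.iloc[gi]
        centers = (peaks.df["start"] + peaks.df["end"]) / 2
        d = (centers - pos).abs()
        window = [p for p in free_peaks
                  if 2000 <= d.iloc[p] <= 1_000_000]
        p = int(rng.choice(window))
        free_peaks.remove(p)
        mean_cp[:, p] = mean_cp[:, p] * np.exp(cfg.link_coupling * u
                                               - cfg.link_coupling**2 / 2)
        link_rows.append({"gene": genes[gi], "peak": peak_names[p]})
    links = pd.DataFrame(link_rows)

    # counts are drawn only after every truth-table draw, so the truth is
    # invariant to nuisance parameters (library size) under a fixed seed
    mean_cp *= atac_lib[:, None]
    rna_X = _nb_counts(rng, mean_cg, np.broadcast_to(dispersion, mean_cg.shape))
    atac_X = _nb_counts(rng, mean_cp, np.broadcast_to(peak_disp, mean_cp.shape))

    # --- QC metadata (inside default bounds) -------------------------------
    # the simulated genes/peaks are a panel, not the full transcriptome or
    # peak atlas, so real-scale QC totals include a panel-external floor
    obs = obs.copy()
    obs["total_counts"] = rna_X.sum(axis=1) + 2000
    obs["n_genes"] = (rna_X > 0).sum(axis=1) + 800
    obs["atac_fragments"] = atac_X.sum(axis=1) + 2000
    obs["nucleosome_signal"] = rng.uniform(0.5, 2.0, n_cells)
    obs["tss_enrichment"] = rng.uniform(4.0, 12.0, n_cells)

    rna = AnnData(X=rna_X.astype(np.int32), obs=obs.copy(),
                  var=pd.DataFrame(index=genes))
    rna.var["tss"] = tss.values
    atac = AnnData(X=atac_X.astype(np.int32), obs=obs.copy(),
                   var=pd.DataFrame(index=peak_names))

    peaks = peaks.copy()
    peaks.df["mean_accessibility"] = atac_X.mean(axis=0)
    # nominal GC (no sequence attached yet); generate_motif_sequences
    # recomputes it from the actual sequence
    peaks.df["gc_fraction"] = rng.uniform(0.35, 0.6, cfg.n_peaks)

    truth = TruthTable(
        sex_degs=sex_degs,
        cluster_markers=cluster_markers,
        tf_list=tf_list,
        regulators=regulators,
        regulator_peaks=regulator_peaks,
        tf_motif_peaks=tf_motif_peaks,
        sex_biased_peaks=sex_biased_peaks,
        links=links,
        peak_archetypes=pd.Series("null", index=peak_names, name="archetype"),
        planted_motifs=pd.DataFrame(columns=["motif", "peak", "offset", "strand"]),
    )
    return rna, atac, peaks, truth


def generate_condition_atac(
    cfg: SimulationConfig | None = None,
    groups: dict[str, tuple[str, str]] | None = None,
    archetypes: dict[str, dict[str, float]] | None = None,
    peaks_per_archetype: int | dict[str, int] = 200,
):
    """Bulk peak x sample counts across hormone conditions.

    groups maps group name -> (sex, treatment); archetype definitions
    give the per-group mean multiplier of each planted peak class,
    remaining peaks are null. Returns (counts, design, peaks, truth).
    """
    cfg = cfg or SimulationConfig()
    cfg.validate()
    if cfg.bulk_replicates_per_group < 2:
        raise ValueError("need >= 2 replicates per group (dispersion not estimable)")
    groups = groups or adult_four_condition_groups()
    archetypes = archetypes if archetypes is not None else ADULT_ARCHETYPES
    for name, mult in archetypes.items():
        if set(mult) != set(groups):
            raise ValueError(f"archetype {name!r} does not cover all groups")
    total_planted = sum(
        (peaks_per_archetype if isinstance(peaks_per_archetype, int)
         else peaks_per_archetype[a]) for a in archetypes)
    if total_planted > cfg.n_peaks:
        raise ValueError("planted archetype peaks exceed the peak universe")
    rng = np.random.default_rng(cfg.seed + 1)

    peaks = _toy_peaks(cfg)
    peak_names = list(peaks.df["name"])
    base = rng.lognormal(cfg.bulk_peak_mean_log_mu, cfg.bulk_peak_mean_log_sigma,
                         cfg.n_peaks)
    disp = rng.lognormal(cfg.bulk_dispersion_log_mu, cfg.bulk_dispersion_log_sigma,
                         cfg.n_peaks)

    labels = pd.Series("null", index=peak_names, name="archetype")
    free = list(range(cfg.n_peaks))
    mult_matrix = np.ones((cfg.n_peaks, len(groups)))
    group_names = list(groups)
    for name, mult in archetypes.items():
        n_planted = (peaks_per_archetype if isinstance(peaks_per_archetype, int)
                     else peaks_per_archetype[name])
        chosen = rng.choice(free, n_planted, replace=False)
        for p in chosen:
            free.remove(int(p))
        labels.iloc[chosen] = name
        for j, g in enumerate(group_names):
            mult_matrix[chosen, j] = mult[g]

    design_rows, cols = [], {}
    for g in group_names:
        sex, treatment = groups[g]
        for r in range(cfg.bulk_replicates_per_group):
            sample = f"{g}_r{r + 1}"
            libfac = rng.lognormal(0.0, 0.2)
            j = group_names.index(g)
            mean = base * mult_matrix[:, j] * libfac
            cols[sample] = _nb_counts(rng, mean, disp)
            design_rows.append({"sample": sample, "group": g,
                                "sex": sex, "treatment": treatment})
    counts = pd.DataFrame(cols, index=peak_names)
    design = pd.DataFrame(design_rows).set_index("sample")

    peaks = peaks.copy()
    peaks.df["mean_accessibility"] = counts.mean(axis=1).to_numpy()
    truth = TruthTable(
        sex_degs=pd.DataFrame(columns=["cluster", "gene", "log2fc"]),
        cluster_markers=pd.DataFrame(columns=["cluster", "gene"]),
        tf_list=[], regulators=pd.DataFrame(columns=["tf", "motif", "cluster"]),
        regulator_peaks={}, tf_motif_peaks={},
        sex_biased_peaks=pd.DataFrame(columns=["peak", "clusters", "log2fc"]),
        links=pd.DataFrame(columns=["gene", "peak"]),
        peak_archetypes=labels,
        planted_motifs=pd.DataFrame(columns=["motif", "peak", "offset", "strand"]),
    )
    return counts, design, peaks, truth


def generate_motif_sequences(
    peaks: PeakSet,
    motifs: list[MotifModel],
    planting_plan: dict[str, tuple[list[str], float]],
    background_gc: float | np.ndarray = 0.45,
    seed: int = 0,
    exact_consensus: bool = False,
) -> tuple[PeakSet, pd.DataFrame]:
    """Attach i.i.d.-background sequences to peaks and plant motif
    instances.

    planting_plan maps motif id -> (peak names, planting rate); each
    designated peak receives one sampled-PWM (or exact-consensus)
    instance at a random offset with probability `rate`. GC fraction is
    recomputed from the final sequence. Returns the annotated PeakSet
    and the planted-instance table (motif, peak, offset, strand).
    """
    rng = np.random.default_rng(seed)
    by_id = {m.id: m for m in motifs}
    widths = (peaks.df["end"] - peaks.df["start"]).to_numpy()
    for mid, (names, _) in planting_plan.items():
        if by_id[mid].width > widths.min():
            raise ValueError(f"motif {mid!r} wider than the narrowest peak")

    gc_per_peak = np.broadcast_to(np.asarray(background_gc, dtype=float),
                                  (len(peaks),))
    seqs = {}
    for name, w, gc in zip(peaks.df["name"], widths, gc_per_peak):
        probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        seqs[name] = list("ACGT"[i] for i in rng.choice(4, int(w), p=probs))

    planted = []
    for mid, (names, rate) in planting_plan.items():
        motif = by_id[mid]
        for name in names:
            if rng.random() > rate:
                continue
            inst = motif.consensus if exact_consensus else motif.sample(rng)
            L = len(seqs[name])
            off = int(rng.integers(0, L - motif.width + 1))
            seqs[name][off : off + motif.width] = list(inst)
            planted.append({"motif": mid, "peak": name, "offset": off,
                            "strand": "+"})

    out = peaks.copy()
    joined = ["".join(seqs[n]) for n in out.df["name"]]
    out.df["sequence"] = joined
    out.df["gc_fraction"] = [
        (s.count("G") + s.count("C")) / len(s) for s in joined
    ]
    return out, pd.DataFrame(planted, columns=["motif", "peak", "offset", "strand"])


def generate_maintenance_instance(
    n_early: int = 300,
    n_adult: int = 600,
    overlap_fraction: float = 0.10,
    peak_width: int = 501,
    spacing: int = 3000,
    seed: int = 0,
) -> tuple[PeakSet, PeakSet, float]:
    """Early-life regulated peaks of which a planted fraction overlaps
    adult sex-biased peaks; returns (early, adult, planted_fraction)."""
    rng = np.random.default_rng(seed)
    n_overlap = int(round(n_early * overlap_fraction))
    starts = np.arange(n_early + n_adult) * spacing + 100
    rng.shuffle(starts)
    early_starts = starts[:n_early]
    adult_starts = list(starts[n_early:n_early + n_adult - n_overlap])
    shared = rng.choice(n_early, n_overlap, replace=False)
    for i in shared:  # overlap by a partial shift, still >= 1 bp shared
        adult_starts.append(early_starts[i] + rng.integers(0, peak_width // 2))
    early = PeakSet(pd.DataFrame({
        "chrom": "chr1", "start": np.sort(early_starts),
        "end": np.sort(early_starts) + peak_width,
    }))
    adult_starts = np.sort(np.array(adult_starts))
    adult = PeakSet(pd.DataFrame({
        "chrom": "chr1", "start": adult_starts, "end": adult_starts + peak_width,
    }))
    return early, adult, n_overlap / n_early
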