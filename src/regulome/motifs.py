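"""PWM motif scanning, matched-background sampling, enrichment and
per-cell deviation z-scores.

Scanning scores log2-odds of a position probability matrix against a
zero-order background and converts scores to exact p-values through a
dynamic-programming null score distribution (scores discretised to
1e-3 bits, which bounds the p-value error). Enrichment is a Fisher
exact test on peak-level motif presence against a background peak set
matched on GC content and mean accessibility. Deviations are
chromVAR-style: observed minus expected motif-peak counts per cell,
z-scored against matched background peak sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neighbors import NearestNeighbors

from .intervals import PeakSet
from .stats import bh_adjust

__all__ = [
    "MotifModel", "scan", "matched_background", "enrich", "deviations",
    "read_jaspar", "read_meme",
]

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
SCORE_GRID_BITS = 1e-3  # DP score discretisation


@dataclass
class MotifModel:
    """A position probability matrix with background base frequencies."""

    id: str
    ppm: np.ndarray                     # (width, 4), rows sum to 1
    pseudocount: float = 1e-3
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.ppm.ndim != 2 or self.ppm.shape[1] != 4:
            raise ValueError("ppm must be (width, 4)")
        if (self.ppm < 0).any() or np.abs(self.ppm.sum(axis=1) - 1).max() > 1e-6:
            raise ValueError("ppm rows must be probabilities summing to 1")

    @property
    def width(self) -> int:
        return self.ppm.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.ppm.argmax(axis=1))

    def log_odds(self) -> np.ndarray:
        """(width, 4) log2 odds with pseudocount regularisation."""
        p = self.ppm + self.pseudocount
        p = p / p.sum(axis=1, keepdims=True)
        return np.log2(p / self.background)

    def max_score(self) -> float:
        return float(self.log_odds().max(axis=1).sum())

    def reverse_complement(self) -> "MotifModel":
        return MotifModel(self.id + "_rc", self.ppm[::-1, ::-1],
                          self.pseudocount, self.background[::-1])

    def sample(self, rng: np.random.Generator) -> str:
        return "".join(
            BASES[rng.choice(4, p=row / row.sum())] for row in self.ppm
        )


def read_jaspar(path) -> list[MotifModel]:
    """Read JASPAR PFM text (4 count rows per motif, 'A [ ... ]' style)."""
    motifs, name, rows = [], None, []
    with open(path) as fh:
        lines = [l.strip() for l in fh if l.strip()]
    for line in lines:
        if line.startswith(">"):
            if name and rows:
                motifs.append(_pfm_to_model(name, rows))
            name, rows = line[1:].split()[0], []
        else:
            payload = line.split("[")[-1].rstrip("]").replace("]", "")
            payload = payload.lstrip("ACGT").strip()
            rows.append([float(x) for x in payload.split()])
    if name and rows:
        motifs.append(_pfm_to_model(name, rows))
    return motifs


def _pfm_to_model(name: str, rows: list[list[float]]) -> MotifModel:
    counts = np.asarray(rows, dtype=float).T  # (width, 4)
    counts += 0.5
    return MotifModel(name, counts / counts.sum(axis=1, keepdims=True))


def read_meme(path) -> list[MotifModel]:
    """Minimal MEME-format reader (letter-probability matrix blocks)."""
    motifs, name, rows, bg = [], None, [], np.full(4, 0.25)
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            vals = lines[i + 1].split()
            bg = np.array([float(vals[j]) for j in (1, 3, 5, 7)])
            i += 2
            continue
        if line.startswith("MOTIF"):
            name = line.split()[1]
            rows = []
        elif line.startswith("letter-probability matrix"):
            i += 1
            while i < len(lines) and lines[i].strip() and not lines[i].startswith("MOTIF"):
                parts = lines[i].split()
                if len(parts) == 4:
                    rows.append([float(x) for x in parts])
                    i += 1
                else:
                    break
            motifs.append(MotifModel(name, np.asarray(rows), background=bg))
            continue
        i += 1
    return motifs


# ---------------------------------------------------------------------------
# scanning


def _score_distribution(lom: np.ndarray, background: np.ndarray, grid: float):
    """Exact null distribution of the discretised PWM score by DP.

    Returns (offset, probs) where score_of_bin[i] = (offset + i) * grid.
    """
    q = np.round(lom / grid).astype(int)          # (width, 4) integer scores
    lo = q.min(axis=1).cumsum()
    hi = q.max(axis=1).cumsum()
    # dense DP over the reachable integer-score range, one convolution
    # (4 shifted adds) per motif position
    cur = np.zeros(int(hi[0] - lo[0]) + 1)
    for b in range(4):
        cur[q[0, b] - lo[0]] += background[b]
    for j in range(1, q.shape[0]):
        nxt = np.zeros(int(hi[j] - lo[j]) + 1)
        for b in range(4):
            shift = q[j, b] + lo[j - 1] - lo[j]
            nxt[shift : shift + len(cur)] += cur * background[b]
        cur = nxt
    keys = np.arange(lo[-1], hi[-1] + 1)
    return keys, cur


def score_pvalue_table(motif: MotifModel, grid: float = SCORE_GRID_BITS):
    """(scores_in_bits, P(score >= s)) for every achievable discretised score."""
    lom = motif.log_odds()
    keys, probs = _score_distribution(lom, motif.background, grid)
    tail = np.cumsum(probs[::-1])[::-1]
    return keys * grid, tail


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE.get(c, 4) for c in seq.upper()], dtype=np.int8)


def _window_scores(codes: np.ndarray, lom: np.ndarray) -> np.ndarray:
    """Scores of all windows; N bases contribute 0 log-odds."""
    w = lom.shape[0]
    L = len(codes)
    if L < w:
        return np.empty(0)
    lom5 = np.hstack([lom, np.zeros((w, 1))])  # column for N
    out = np.zeros(L - w + 1)
    for j in range(w):
        out += lom5[j, codes[j : L - w + 1 + j]]
    return out


def scan(
    peaks: PeakSet,
    motif: MotifModel,
    p_threshold: float = 1e-4,
    both_strands: bool = True,
) -> pd.DataFrame:
    """Scan peak sequences for motif hits with exact null p-values.

    Every position (and strand) whose log2-odds score has null
    probability P(score >= s) <= ``p_threshold`` is reported. Sequences
    shorter than the motif yield no hits. Returns a DataFrame with
    columns (peak, offset, strand, score, p).
    """
    if "sequence" not in peaks.df.columns:
        raise ValueError("peaks carry no sequences")
    scores_grid, tail = score_pvalue_table(motif)
    lom = motif.log_odds()
    lom_rc = lom[::-1, ::-1]

    def pval(s: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(scores_grid, s - SCORE_GRID_BITS / 2, side="left")
        idx = np.minimum(idx, len(tail) - 1)
        return tail[idx]

    rows = []
    for name, seq in zip(peaks.df["name"], peaks.df["sequence"]):
        codes = _encode(seq)
        for strand, mat in (("+", lom), ("-", lom_rc)):
            if not both_strands and strand == "-":
                continue
            sc = _window_scores(codes, mat)
            if not len(sc):
                continue
            p = pval(sc)
            for off in np.flatnonzero(p <= p_threshold):
                rows.append((name, int(off), strand, float(sc[off]), float(p[off])))
    return pd.DataFrame(rows, columns=["peak", "offset", "strand", "score", "p"])


# ---------------------------------------------------------------------------
# matched background and enrichment


def _matching_space(ps: PeakSet) -> np.ndarray:
    df = ps.df
    for col in ("gc_fraction", "mean_accessibility"):
        if col not in df.columns:
            raise ValueError(f"peaks need annotation {col!r}")
    return np.column_stack([
        df["gc_fraction"].to_numpy(dtype=float),
        np.log1p(df["mean_accessibility"].to_numpy(dtype=float)),
    ])


def matched_background(
    foreground: PeakSet,
    pool: PeakSet,
    n_per_peak: int = 1,
    seed: int = 0,
) -> PeakSet:
    """Background peaks matched on GC content and accessibility.

    For each foreground peak, its ``n_per_peak`` nearest pool peaks in
    standardised (GC, log mean accessibility) space are taken (sampled
    without replacement within each peak); foreground members are
    excluded from the pool. If the pool is smaller than a request it is
    sampled with replacement with a warning.
    """
    fg_keys = set(map(tuple, foreground.df[["chrom", "start", "end"]].to_numpy()))
    pool_mask = [
        tuple(r) not in fg_keys
        for r in pool.df[["chrom", "start", "end"]].to_numpy()
    ]
    avail = pool.subset(pool_mask)
    if len(avail) == 0:
        raise ValueError("background pool is empty after excluding foreground")
    Xf, Xp = _matching_space(foreground), _matching_space(avail)
    mu, sd = Xp.mean(axis=0), np.maximum(Xp.std(axis=0), 1e-9)
    Xf, Xp = (Xf - mu) / sd, (Xp - mu) / sd
    k = min(n_per_peak, len(avail))
    if k < n_per_peak:
        warnings.warn("pool smaller than request; sampling with replacement")
    nn = NearestNeighbors(n_neighbors=k).fit(Xp)
    _, idx = nn.kneighbors(Xf)
    rng = np.random.default_rng(seed)
    chosen = []
    for row in idx:
        take = list(row)
        while len(take) < n_per_peak:
            take.append(int(rng.choice(row)))
        chosen.extend(take[:n_per_peak])
    out = avail.df.iloc[chosen].drop_duplicates(subset=["chrom", "start", "end"])
    return PeakSet(out.reset_index(drop=True))


def enrich(
    foreground_hits: pd.DataFrame,
    background_hits: pd.DataFrame,
    n_foreground: int,
    n_background: int,
    motifs: list[str] | None = None,
) -> pd.DataFrame:
    """Fisher exact motif enrichment on peak-level presence/absence.

    ``*_hits`` are scan outputs with a ``motif`` column (concatenate
    per-motif scans with ``assign(motif=...)``). One-sided
    (greater) hypergeometric p per motif, BH across motifs, plus the
    fraction of peaks containing >= 1 hit in each set.
    """
    if n_foreground == 0:
        raise ValueError("empty foreground")
    if motifs is None:
        motifs = sorted(
            set(foreground_hits.get("motif", pd.Series(dtype=str)))
            | set(background_hits.get("motif", pd.Series(dtype=str)))
        )
    rows = []
    for m in motifs:
        fg = foreground_hits[foreground_hits["motif"] == m]["peak"].nunique()
        bg = background_hits[background_hits["motif"] == m]["peak"].nunique()
        table = [[fg, n_foreground - fg], [bg, n_background - bg]]
        odds, p = stats.fisher_exact(table, alternative="greater")
        rows.append({
            "motif": m, "odds_ratio": odds, "p": p,
            "frac_foreground": fg / n_foreground,
            "frac_background": bg / n_background if n_background else np.nan,
        })
    res = pd.DataFrame(rows)
    res["p_adj"] = bh_adjust(res["p"].to_numpy())
    return res.sort_values("p").reset_index(drop=True)


# ---------------------------------------------------------------------------
# per-cell deviation z-scores


def deviations(
    atac,
    peak_annotations: dict[str, list[str]],
    peaks: PeakSet,
    n_background_sets: int = 50,
    seed: int = 0,
    n_neighbors: int = 50,
) -> pd.DataFrame:
    """chromVAR-style motif deviation z-scores per cell.

    For motif m with peak set P_m, the expected count for cell c is
    depth_c * sum_{p in P_m} f_p where f_p is peak p's share of total
    counts; raw deviation = (obs - exp) / exp. The z-score standardises
    the raw deviation against ``n_background_sets`` sets of GC- and
    accessibility-matched peaks (one matched peak sampled per motif
    peak per set). Requires >= 20 background sets. Deterministic under
    ``seed``.
    """
    if n_background_sets < 20:
        raise ValueError("need >= 20 background sets")
    X = atac.X
    X = np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X)
    names = list(atac.var_names)
    name_to_idx = {n: i for i, n in enumerate(names)}
    total = X.sum()
    f = X.sum(axis=0) / total                 # per-peak share
    depth = X.sum(axis=1)

    space = _matching_space(peaks)
    mu, sd = space.mean(axis=0), np.maximum(space.std(axis=0), 1e-9)
    space = (space - mu) / sd
    order = {n: i for i, n in enumerate(peaks.df["name"])}
    k = min(n_neighbors, len(peaks))
    nn = NearestNeighbors(n_neighbors=k).fit(space)
    _, knn = nn.kneighbors(space)
    rng = np.random.default_rng(seed)

    def raw_dev(idx: np.ndarray) -> np.ndarray:
        exp = depth * f[idx].sum()
        obs = X[:, idx].sum(axis=1)
        return (obs - exp) / np.maximum(exp, 1e-12)

    out = {}
    for motif, peak_names in peak_annotations.items():
        idx = np.array([name_to_idx[p] for p in peak_names if p in name_to_idx])
        if len(idx) == 0:
            warnings.warn(f"motif {motif!r} has no annotated peaks; skipped")
            continue
        obs_dev = raw_dev(idx)
        rows = np.array([order[names[i]] for i in idx])
        bg_devs = np.empty((n_background_sets, len(depth)))
        for b in range(n_background_sets):
            picks = knn[rows, rng.integers(0, k, size=len(rows))]
            bg_idx = np.array([name_to_idx[peaks.df["name"].iat[p]] for p in picks])
            bg_devs[b] = raw_dev(bg_idx)
        m, s = bg_devs.mean(axis=0), bg_devs.std(axis=0, ddof=1)
        out[motif] = (obs_dev - m) / np.maximum(s, 1e-12)
    return pd.DataFrame(out, index=atac.obs_names)
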