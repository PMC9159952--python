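"""Readers/writers for BED, FASTA and count matrices, and per-cell QC filtering.

Count matrices travel as AnnData (cells x features, metadata in ``.obs``)
or plain DataFrames; on disk they are dense TSV or MatrixMarket sparse
triplets with feature/barcode sidecar files.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData

from .intervals import PeakSet

__all__ = [
    "read_bed", "write_bed", "read_fasta", "write_fasta",
    "read_counts_tsv", "write_counts_tsv", "read_counts_mtx",
    "write_counts_mtx", "QCBounds", "qc_filter",
]

_BED_CORE = ["chrom", "start", "end", "name", "score", "strand"]


class BedParseError(ValueError):
    pass


def read_bed(path) -> PeakSet:
    """Read a 3+ column tab-separated BED file into a PeakSet.

    Coordinates are taken as 0-based half-open. Columns beyond the six
    standard BED fields are preserved as ``extra_<i>`` annotations; a
    column named by convention ``summit`` is not part of BED, so summits
    must be supplied via a 7th column when needed (``extra_0``) or set
    programmatically.
    """
    rows = []
    ncols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BedParseError(f"{path}: line {lineno}: fewer than 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as e:
                raise BedParseError(f"{path}: line {lineno}: {e}") from None
            if start >= end or start < 0:
                raise BedParseError(
                    f"{path}: line {lineno}: invalid interval {start}-{end}"
                )
            if ncols is None:
                ncols = len(parts)
            rows.append(parts)
    if not rows:
        return PeakSet(pd.DataFrame(columns=["chrom", "start", "end"]))
    width = max(len(r) for r in rows)
    cols = _BED_CORE[:min(width, 6)] + [f"extra_{i}" for i in range(max(0, width - 6))]
    df = pd.DataFrame([r + [None] * (width - len(r)) for r in rows], columns=cols)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if "score" in df.columns:
        df["score"] = pd.to_numeric(df["score"], errors="coerce")
    return PeakSet(df)


def write_bed(peaks: PeakSet, path) -> None:
    df = peaks.df
    cols = [c for c in _BED_CORE if c in df.columns]
    cols += [c for c in df.columns if c.startswith("extra_")]
    out = df[cols].copy()
    if "score" in out.columns:
        out["score"] = out["score"].fillna(0)
    out.to_csv(path, sep="\t", header=False, index=False)


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into an ordered {id: sequence} dict; bases upper-cased."""
    from Bio import SeqIO

    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(seqs: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _check_unique(index: pd.Index, what: str) -> None:
    if index.duplicated().any():
        dup = index[index.duplicated()][0]
        raise ValueError(f"duplicate {what} id {dup!r}")


def read_counts_tsv(path) -> pd.DataFrame:
    """Dense feature x sample TSV with a header row and feature-id column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    _check_unique(df.index, "feature")
    _check_unique(df.columns, "sample")
    return df


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    _check_unique(counts.index, "feature")
    counts.to_csv(path, sep="\t")


def write_counts_mtx(counts, features, barcodes, prefix) -> None:
    """Sparse triplet (MatrixMarket) + features/barcodes sidecar files."""
    prefix = Path(prefix)
    mat = sp.csr_matrix(counts)
    scipy.io.mmwrite(str(prefix) + ".mtx", mat)
    pd.Series(list(features)).to_csv(
        str(prefix) + ".features.tsv", sep="\t", header=False, index=False
    )
    pd.Series(list(barcodes)).to_csv(
        str(prefix) + ".barcodes.tsv", sep="\t", header=False, index=False
    )


def read_counts_mtx(prefix) -> tuple[sp.csr_matrix, list[str], list[str]]:
    prefix = Path(prefix)
    mat = sp.csr_matrix(scipy.io.mmread(str(prefix) + ".mtx"))
    features = pd.read_csv(
        str(prefix) + ".features.tsv", sep="\t", header=None
    )[0].astype(str).tolist()
    barcodes = pd.read_csv(
        str(prefix) + ".barcodes.tsv", sep="\t", header=None
    )[0].astype(str).tolist()
    _check_unique(pd.Index(features), "feature")
    return mat, features, barcodes


@dataclass
class QCBounds:
    """Per-cell QC thresholds; all strict inequalities, boundary cells survive.

    Defaults are the lower/upper bounds used for nucleus filtering in
    joint RNA+ATAC (multiome) data: remove nuclei with <1,000 ATAC
    fragments, <500 RNA counts, nucleosomal signal >3 or TSS enrichment
    <2, and nuclei with >60,000 ATAC fragments, >20,000 RNA counts or
    >6,000 genes detected. Set a field to None to disable the rule.
    """

    min_atac_fragments: Optional[float] = 1000
    min_counts: Optional[float] = 500
    max_nucleosome_signal: Optional[float] = 3
    min_tss_enrichment: Optional[float] = 2
    max_atac_fragments: Optional[float] = 60000
    max_counts: Optional[float] = 20000
    max_genes: Optional[float] = 6000

    def rules(self) -> list[tuple[str, str, str, float]]:
        spec = [
            ("min_atac_fragments", "atac_fragments", "lt"),
            ("min_counts", "total_counts", "lt"),
            ("max_nucleosome_signal", "nucleosome_signal", "gt"),
            ("min_tss_enrichment", "tss_enrichment", "lt"),
            ("max_atac_fragments", "atac_fragments", "gt"),
            ("max_counts", "total_counts", "gt"),
            ("max_genes", "n_genes", "gt"),
        ]
        out = []
        for name, col, op in spec:
            thr = getattr(self, name)
            if thr is not None:
                out.append((name, col, op, float(thr)))
        return out


def qc_filter(cells: AnnData, bounds: QCBounds | None = None) -> tuple[AnnData, dict]:
    """Remove cells failing any active QC bound.

    Returns the filtered AnnData plus a report with the number of cells
    each rule removed (cells failing several rules count in each).
    """
    if bounds is None:
        bounds = QCBounds()
    fail = np.zeros(cells.n_obs, dtype=bool)
    report: dict[str, int] = {}
    for name, col, op, thr in bounds.rules():
        if col not in cells.obs.columns:
            raise KeyError(f"QC bound {name} needs obs column {col!r}")
        vals = cells.obs[col].to_numpy(dtype=float)
        bad = vals < thr if op == "lt" else vals > thr
        report[name] = int(bad.sum())
        fail |= bad
    report["total_removed"] = int(fail.sum())
    report["total_kept"] = int((~fail).sum())
    return cells[~fail].copy(), report
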