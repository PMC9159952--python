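"""Genomic intervals and peak sets.

All coordinates are 0-based half-open ([start, end)) everywhere in the
package; any 1-based input dialect must be converted at the reader, never
downstream. Overlap means >= 1 shared base pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = ["GenomicInterval", "PeakSet", "recenter_peaks", "intersect"]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with optional summit/strand."""

    chrom: str
    start: int
    end: int
    summit: Optional[int] = None
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.summit is not None and not (self.start <= self.summit < self.end):
            raise ValueError(
                f"summit {self.summit} outside [{self.start}, {self.end})"
            )
        if self.strand is not None and self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


class PeakSet:
    """An ordered collection of peaks with per-peak annotations.

    Backed by a pandas DataFrame with at least columns
    ``chrom, start, end``; optional columns include ``summit``, ``strand``,
    ``name``, ``gc_fraction``, ``mean_accessibility``, ``sequence``.
    (chrom, start, end) keys must be unique.
    """

    REQUIRED = ("chrom", "start", "end")

    def __init__(self, df: pd.DataFrame):
        df = df.reset_index(drop=True).copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValueError(f"PeakSet requires column {col!r}")
        if len(df):
            bad = ~((df["start"] >= 0) & (df["start"] < df["end"]))
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise ValueError(
                    f"invalid interval at row {i}: "
                    f"{df['chrom'].iat[i]}:{df['start'].iat[i]}-{df['end'].iat[i]}"
                )
            if df.duplicated(subset=["chrom", "start", "end"]).any():
                raise ValueError("duplicate (chrom, start, end) keys in PeakSet")
        if "name" not in df.columns:
            df["name"] = [f"peak_{i}" for i in range(len(df))]
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterable[GenomicInterval]:
        has_summit = "summit" in self.df.columns
        for row in self.df.itertuples(index=False):
            summit = getattr(row, "summit", None) if has_summit else None
            if summit is not None and pd.isna(summit):
                summit = None
            yield GenomicInterval(
                row.chrom, int(row.start), int(row.end),
                None if summit is None else int(summit),
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        a = self.df[list(self.REQUIRED)]
        b = other.df[list(self.REQUIRED)]
        return len(a) == len(b) and bool((a.values == b.values).all())

    @property
    def names(self) -> pd.Series:
        return self.df["name"]

    def subset(self, mask) -> "PeakSet":
        return PeakSet(self.df.loc[np.asarray(mask)].reset_index(drop=True))

    def copy(self) -> "PeakSet":
        return PeakSet(self.df.copy())


def recenter_peaks(peaks: PeakSet, flank: int) -> PeakSet:
    """Recenter each peak to +/- ``flank`` bp around its summit.

    The output interval is [summit - flank, summit + flank + 1) — width
    2*flank + 1 with the summit base included — clipped at position 0.
    Every peak must carry a summit.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    df = peaks.df
    if "summit" not in df.columns or df["summit"].isna().any():
        raise ValueError("recenter_peaks requires a summit for every peak")
    out = df.copy()
    summit = df["summit"].astype(int)
    out["start"] = np.maximum(summit - flank, 0)
    out["end"] = summit + flank + 1
    out["summit"] = summit
    return PeakSet(out)


def _trees(b: PeakSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in b.df.groupby("chrom", sort=False):
        trees[chrom] = IntervalTree.from_tuples(
            zip(grp["start"].astype(int), grp["end"].astype(int))
        )
    return trees


def overlaps_mask(a: PeakSet, b: PeakSet) -> np.ndarray:
    """Boolean mask over ``a``: True where the peak shares >= 1 bp with ``b``."""
    trees = _trees(b)
    mask = np.zeros(len(a), dtype=bool)
    for i, (chrom, start, end) in enumerate(
        zip(a.df["chrom"], a.df["start"], a.df["end"])
    ):
        tree = trees.get(chrom)
        if tree is not None and tree.overlaps(int(start), int(end)):
            mask[i] = True
    return mask


def intersect(a: PeakSet, b: PeakSet, mode: str = "report_a"):
    """Interval intersection between two peak sets.

    mode='report_a'  -> members of ``a`` overlapping >= 1 bp of ``b``
    mode='exclude_a' -> members of ``a`` with no overlap (bedtools -v)
    mode='fraction'  -> |report_a| / |a| (0.0 for empty ``a``)
    """
    mask = overlaps_mask(a, b)
    if mode == "report_a":
        return a.subset(mask)
    if mode == "exclude_a":
        return a.subset(~mask)
    if mode == "fraction":
        return float(mask.mean()) if len(a) else 0.0
    raise ValueError(f"unknown mode {mode!r}")
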