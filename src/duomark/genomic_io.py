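"""Readers/writers for standard genomic text formats and exact interval arithmetic.

All coordinates are 0-based half-open (BED convention); interval length is
always ``end - start``.  Strand is carried but ignored by the arithmetic:
nucleosomal signals are unstranded, and strand is only consulted when
orienting metagene profiles.

Supported formats: BED3/4/6/12 (tab-separated, UCSC-style), bedGraph
(``chrom start end value``), chrom.sizes (``name<TAB>length``) and TSV
expression tables.  Chromosome names are compared as exact strings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("duomark")

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "GeneModel",
    "BedFormatError",
    "read_bed",
    "write_bed",
    "read_genes_bed12",
    "write_genes_bed12",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_bedgraph",
    "write_bedgraph",
    "intersect",
    "merge",
]


class BedFormatError(ValueError):
    """Malformed BED content; the message names the offending line."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval with optional BED6 annotations."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start coordinate: {self!r}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: {self!r}")
        if self.strand not in (None, "+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


_PEAK_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


class PeakSet:
    """Sorted collection of genomic intervals (peaks, regions, sites).

    Backed by a pandas DataFrame with columns chrom/start/end/name/score/strand,
    sorted by (chrom, start, end).  Within-set overlaps are permitted; use
    :func:`merge` to flatten them.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] | pd.DataFrame,
                 label: str = "") -> None:
        if isinstance(intervals, pd.DataFrame):
            df = intervals.copy()
            for col in _PEAK_COLUMNS:
                if col not in df.columns:
                    df[col] = None
            df = df[_PEAK_COLUMNS]
        else:
            rows = [(iv.chrom, iv.start, iv.end, iv.name, iv.score, iv.strand)
                    for iv in intervals]
            df = pd.DataFrame(rows, columns=_PEAK_COLUMNS)
        if len(df):
            df["start"] = df["start"].astype(np.int64)
            df["end"] = df["end"].astype(np.int64)
            if (df["start"] < 0).any():
                raise ValueError("negative start coordinate in interval set")
            if (df["end"] <= df["start"]).any():
                raise ValueError("interval with end <= start")
        else:
            df = df.astype({"start": np.int64, "end": np.int64}, errors="ignore")
        self.df = df.sort_values(["chrom", "start", "end"], kind="mergesort",
                                 ignore_index=True)
        self.label = label

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[GenomicInterval]:
        for row in self.df.itertuples(index=False):
            yield GenomicInterval(
                row.chrom, int(row.start), int(row.end),
                None if row.name is None or (isinstance(row.name, float) and np.isnan(row.name)) else row.name,
                None if row.score is None or (isinstance(row.score, float) and np.isnan(row.score)) else float(row.score),
                None if row.strand is None or (isinstance(row.strand, float)) else row.strand,
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        a = self.df[["chrom", "start", "end"]]
        b = other.df[["chrom", "start", "end"]]
        return a.equals(b)

    def total_bases(self) -> int:
        """Sum of interval lengths (overlaps counted multiply)."""
        return int((self.df["end"] - self.df["start"]).sum())

    def chroms(self) -> list[str]:
        return sorted(self.df["chrom"].unique().tolist())

    def subset(self, chrom: str) -> pd.DataFrame:
        return self.df[self.df["chrom"] == chrom]

    def validate_against(self, chrom_sizes: dict[str, int]) -> None:
        for chrom, grp in self.df.groupby("chrom", sort=False):
            if chrom not in chrom_sizes:
                raise ValueError(f"unknown chromosome {chrom!r}")
            if int(grp["end"].max()) > chrom_sizes[chrom]:
                raise ValueError(
                    f"interval exceeds length of chromosome {chrom!r}")


@dataclass
class GeneModel:
    """A gene/transcript model with optional exon blocks (BED12 blocks)."""

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    exons: list[tuple[int, int]] = field(default_factory=list)  # absolute coords

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start >= end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be +/-")
        if not self.exons:
            self.exons = [(self.start, self.end)]

    @property
    def tss(self) -> int:
        """Transcription start: 5' end respecting strand."""
        return self.start if self.strand == "+" else self.end

    def __len__(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# BED / bedGraph / chrom.sizes I/O
# ---------------------------------------------------------------------------

_DIALECT_COLS = {"BED3": 3, "BED4": 4, "BED6": 6, "BED12": 12}


def _parse_coord(raw: str, lineno: int, path: str) -> int:
    try:
        value = int(raw)
    except ValueError:
        raise BedFormatError(
            f"{path} line {lineno}: non-integer coordinate {raw!r}") from None
    if value < 0:
        raise BedFormatError(f"{path} line {lineno}: negative coordinate {value}")
    return value


def read_bed(path: str | Path, dialect: str = "BED3",
             chrom_sizes: dict[str, int] | None = None) -> PeakSet:
    """Read a BED3/4/6 file into a PeakSet (use read_genes_bed12 for genes).

    Malformed lines raise :class:`BedFormatError` naming the line number.
    When ``chrom_sizes`` is given, chromosome names and bounds are checked.
    """
    if dialect not in ("BED3", "BED4", "BED6"):
        raise ValueError(f"unsupported dialect {dialect!r} for read_bed")
    ncol = _DIALECT_COLS[dialect]
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < ncol:
                raise BedFormatError(
                    f"{path} line {lineno}: expected >= {ncol} columns, "
                    f"got {len(fields)}")
            chrom = fields[0]
            start = _parse_coord(fields[1], lineno, str(path))
            end = _parse_coord(fields[2], lineno, str(path))
            if start >= end:
                raise BedFormatError(
                    f"{path} line {lineno}: start {start} >= end {end}")
            if chrom_sizes is not None:
                if chrom not in chrom_sizes:
                    raise BedFormatError(
                        f"{path} line {lineno}: unknown chromosome {chrom!r}")
                if end > chrom_sizes[chrom]:
                    raise BedFormatError(
                        f"{path} line {lineno}: end {end} beyond chromosome "
                        f"{chrom!r} length {chrom_sizes[chrom]}")
            name = fields[3] if ncol >= 4 else None
            score = float(fields[4]) if ncol >= 6 and fields[4] not in (".", "") else None
            strand = fields[5] if ncol >= 6 else None
            if strand == ".":
                strand = None
            rows.append((chrom, start, end, name, score, strand))
    df = pd.DataFrame(rows, columns=_PEAK_COLUMNS)
    return PeakSet(df, label=path.stem)


def write_bed(peaks: PeakSet, path: str | Path, dialect: str = "BED3") -> None:
    if dialect not in ("BED3", "BED4", "BED6"):
        raise ValueError(f"unsupported dialect {dialect!r} for write_bed")
    ncol = _DIALECT_COLS[dialect]
    with open(path, "w") as fh:
        for row in peaks.df.itertuples(index=False):
            fields = [row.chrom, str(int(row.start)), str(int(row.end))]
            if ncol >= 4:
                fields.append("." if row.name in (None,) or pd.isna(row.name) else str(row.name))
            if ncol >= 6:
                score = row.score
                fields.append("0" if score is None or pd.isna(score) else f"{score:g}")
                fields.append(row.strand if row.strand in ("+", "-") else ".")
            fh.write("\t".join(fields) + "\n")


def read_genes_bed12(path: str | Path) -> list[GeneModel]:
    """Read gene models from a BED12 file, reconstructing absolute exon coords."""
    genes = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise BedFormatError(
                    f"{path} line {lineno}: BED12 needs 12 columns, got {len(fields)}")
            chrom = fields[0]
            start = _parse_coord(fields[1], lineno, str(path))
            end = _parse_coord(fields[2], lineno, str(path))
            if start >= end:
                raise BedFormatError(f"{path} line {lineno}: start >= end")
            name, strand = fields[3], fields[5]
            n_blocks = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",") if x]
            starts = [int(x) for x in fields[11].rstrip(",").split(",") if x]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise BedFormatError(
                    f"{path} line {lineno}: blockCount disagrees with block lists")
            exons = [(start + s, start + s + sz) for s, sz in zip(starts, sizes)]
            genes.append(GeneModel(chrom, start, end, strand, name, exons))
    return genes


def write_genes_bed12(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        ordered = sorted(genes, key=lambda g: (g.chrom, g.start, g.end))
        for g in ordered:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            rel = ",".join(str(s - g.start) for s, _ in g.exons)
            fh.write("\t".join([
                g.chrom, str(g.start), str(g.end), g.gene_id, "0", g.strand,
                str(g.start), str(g.end), "0", str(len(g.exons)), sizes, rel,
            ]) + "\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise BedFormatError(f"{path} line {lineno}: need name<TAB>length")
            length = int(fields[1])
            if length <= 0:
                raise BedFormatError(f"{path} line {lineno}: non-positive length")
            sizes[fields[0]] = length
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"],
                     comment="#")
    if (df["end"] <= df["start"]).any():
        bad = df.index[(df["end"] <= df["start"])][0] + 1
        raise BedFormatError(f"{path} line {bad}: start >= end")
    return df


def write_bedgraph(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False,
              columns=["chrom", "start", "end", "value"],
              float_format="%.6g")


# ---------------------------------------------------------------------------
# Interval arithmetic
# ---------------------------------------------------------------------------

def intersect(a: PeakSet, b: PeakSet, min_overlap: int = 1) -> PeakSet:
    """Clipped pairwise intersections of two sorted interval sets.

    Returns one interval per (a, b) pair sharing at least ``min_overlap``
    bases, clipped to the shared span, sorted.  Strand is ignored.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    out_rows = []
    for chrom in sorted(set(a.df["chrom"]).intersection(b.df["chrom"])):
        da = a.subset(chrom)
        db = b.subset(chrom)
        a_start = da["start"].to_numpy()
        a_end = da["end"].to_numpy()
        b_start = db["start"].to_numpy()
        b_end = db["end"].to_numpy()
        j0 = 0
        for i in range(len(a_start)):
            # b intervals ending at/before this a's start can never overlap
            # this or any later a (a is sorted by start)
            while j0 < len(b_start) and b_end[j0] <= a_start[i]:
                j0 += 1
            j = j0
            while j < len(b_start) and b_start[j] < a_end[i]:
                ov = min(a_end[i], b_end[j]) - max(a_start[i], b_start[j])
                if ov >= min_overlap:
                    out_rows.append((chrom,
                                     max(a_start[i], b_start[j]),
                                     min(a_end[i], b_end[j])))
                j += 1
    df = pd.DataFrame(out_rows, columns=["chrom", "start", "end"])
    return PeakSet(df, label=f"{a.label}&{b.label}")


def merge(a: PeakSet, max_gap: int = 0) -> PeakSet:
    """Flatten intervals: any two within ``max_gap`` bases are joined.

    Bookended intervals ([x,b),[b,c)) merge at max_gap=0, so covered bases
    are conserved.  Idempotent.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    out_rows = []
    for chrom, grp in a.df.groupby("chrom", sort=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        cur_s, cur_e = None, None
        for s, e in zip(starts, ends):
            if cur_s is None:
                cur_s, cur_e = int(s), int(e)
            elif s <= cur_e + max_gap:
                cur_e = max(cur_e, int(e))
            else:
                out_rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = int(s), int(e)
        if cur_s is not None:
            out_rows.append((chrom, cur_s, cur_e))
    df = pd.DataFrame(out_rows, columns=["chrom", "start", "end"])
    return PeakSet(df, label=a.label)
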