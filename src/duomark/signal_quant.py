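"""Genome tiling, read counting, RPM normalization, track correlation and a
minimal broad-domain caller.

Bin quantification follows the standard recipe for broad histone marks: the
genome is tiled at a fixed width (1/3/10 kb presets), reads are counted per
bin (midpoint assignment by default, so every read is counted exactly once)
and scaled to reads per million; tracks can additionally be put on a common
scale by normalizing to the largest library.  Track agreement is measured by
Spearman rank correlation of per-bin values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_io import PeakSet

logger = logging.getLogger("duomark")

__all__ = [
    "BinSet",
    "BinnedSignal",
    "CorrelationMatrix",
    "tile_genome",
    "count_reads",
    "normalize",
    "quantify",
    "enrichment_over_input",
    "merge_tracks",
    "spearman_matrix",
    "call_broad_domains",
]


@dataclass
class BinSet:
    """Fixed-width tiling of a genome; the last bin per chromosome may be
    truncated (flagged, not dropped)."""

    chrom_sizes: dict[str, int]
    width: int
    chroms: np.ndarray = field(repr=False)
    starts: np.ndarray = field(repr=False)
    ends: np.ndarray = field(repr=False)
    truncated: np.ndarray = field(repr=False)
    offsets: dict[str, tuple[int, int]] = field(repr=False)  # chrom -> (first, n)

    @property
    def n_bins(self) -> int:
        return len(self.starts)

    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    def bin_index(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Global bin index of genomic positions on one chromosome (-1 when
        outside the genome)."""
        first, n = self.offsets[chrom]
        idx = positions // self.width
        out = first + idx
        out[(idx < 0) | (idx >= n)] = -1
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chroms, "start": self.starts,
                             "end": self.ends, "truncated": self.truncated})

    def subset_peaks(self, mask: np.ndarray, label: str = "") -> PeakSet:
        df = pd.DataFrame({"chrom": self.chroms[mask],
                           "start": self.starts[mask],
                           "end": self.ends[mask]})
        return PeakSet(df, label=label)


@dataclass
class BinnedSignal:
    """Per-bin raw counts and RPM-normalized values for one track."""

    bins: BinSet
    raw: np.ndarray
    norm: np.ndarray
    library_size: int
    label: str

    def __post_init__(self) -> None:
        if len(self.raw) != self.bins.n_bins or len(self.norm) != self.bins.n_bins:
            raise ValueError("signal length does not match the bin set")
        if np.any(self.norm < 0):
            raise ValueError("normalized signal must be non-negative")

    def to_bedgraph_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.bins.chroms,
                             "start": self.bins.starts,
                             "end": self.bins.ends,
                             "value": self.norm})


@dataclass
class CorrelationMatrix:
    labels: list[str]
    matrix: pd.DataFrame
    bin_width: int


def tile_genome(chrom_sizes: dict[str, int], bin_width: int) -> BinSet:
    """Tile every chromosome with ceil(L / width) fixed-width bins."""
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    chroms, starts, ends, trunc = [], [], [], []
    offsets: dict[str, tuple[int, int]] = {}
    first = 0
    for chrom in sorted(chrom_sizes):
        L = chrom_sizes[chrom]
        n = -(-L // bin_width)  # ceil division
        s = np.arange(n, dtype=np.int64) * bin_width
        e = np.minimum(s + bin_width, L)
        chroms.append(np.full(n, chrom, dtype=object))
        starts.append(s)
        ends.append(e)
        trunc.append(e - s < bin_width)
        offsets[chrom] = (first, n)
        first += n
    return BinSet(dict(chrom_sizes), bin_width,
                  np.concatenate(chroms), np.concatenate(starts),
                  np.concatenate(ends), np.concatenate(trunc), offsets)


def count_reads(reads, bins: BinSet, assignment: str = "midpoint") -> np.ndarray:
    """Per-bin raw read counts.

    ``midpoint``: each read is assigned to the single bin holding its
    midpoint, so the counts sum to the number of (in-genome) reads.
    ``overlap``: fractional assignment proportional to the read's overlap
    with each bin; the total is likewise conserved.
    Reads falling outside every bin are counted nowhere and logged.
    """
    if assignment not in ("midpoint", "overlap"):
        raise ValueError(f"unknown assignment mode {assignment!r}")
    counts = np.zeros(bins.n_bins, dtype=float)
    dropped = 0
    for chrom, grp in reads.df.groupby("chrom", sort=False):
        if chrom not in bins.offsets:
            dropped += len(grp)
            continue
        start = grp["start"].to_numpy()
        end = grp["end"].to_numpy()
        if assignment == "midpoint":
            mid = (start + end) // 2
            idx = bins.bin_index(chrom, mid)
            ok = idx >= 0
            dropped += int((~ok).sum())
            np.add.at(counts, idx[ok], 1.0)
        else:
            first, n = bins.offsets[chrom]
            width = bins.width
            chrom_len = bins.chrom_sizes[chrom]
            length = (np.minimum(end, chrom_len) - start).astype(float)
            lo = start // width
            hi = (np.minimum(end, chrom_len) - 1) // width
            ok = (lo >= 0) & (lo < n)
            dropped += int((~ok).sum())
            start, end, lo, hi, length = (a[ok] for a in (start, end, lo, hi, length))
            for i in range(len(start)):
                for b in range(int(lo[i]), int(min(hi[i], n - 1)) + 1):
                    bs, be = b * width, min((b + 1) * width, chrom_len)
                    ov = min(int(end[i]), be) - max(int(start[i]), bs)
                    counts[first + b] += ov / length[i]
    if dropped:
        logger.warning("count_reads: %d reads outside all bins", dropped)
    return counts


def normalize(counts: np.ndarray, library_size: int, bins: BinSet,
              label: str = "", scale_to: int | None = None) -> BinnedSignal:
    """Reads-per-million normalization; with ``scale_to`` (the largest
    library's size) all tracks are additionally multiplied by the common
    constant scale_to/1e6 so per-million units stay comparable."""
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    norm = counts * 1e6 / library_size
    if scale_to is not None:
        if scale_to <= 0:
            raise ValueError("scale_to must be > 0")
        norm = norm * (scale_to / 1e6)
    return BinnedSignal(bins, np.asarray(counts, dtype=float), norm,
                        library_size, label)


def quantify(reads, bins: BinSet, assignment: str = "midpoint",
             scale_to: int | None = None) -> BinnedSignal:
    """Convenience: count + RPM-normalize one read set."""
    raw = count_reads(reads, bins, assignment)
    return normalize(raw, max(len(reads), 1), bins, label=reads.label,
                     scale_to=scale_to)


def enrichment_over_input(signal: BinnedSignal, input_signal: BinnedSignal,
                          pseudocount_frac: float = 0.01) -> BinnedSignal:
    """Per-bin enrichment of a pull-down over its input.

    value = RPM(signal) / (RPM(input) + pc) with pc a small pseudocount
    (``pseudocount_frac`` times the mean input RPM).  Dividing by input
    cancels regional coverage variation (occupancy / accessibility), which
    otherwise dominates between-bin variance and masks the mark densities
    the downstream state and coexistence statistics measure.  The
    pseudocount only guards against near-empty input bins; it is kept small
    because it otherwise re-introduces a coverage-dependent multiplicative
    distortion (low-coverage regions shrink toward zero).
    """
    if signal.bins.n_bins != input_signal.bins.n_bins:
        raise ValueError("signal and input must share a bin set")
    if pseudocount_frac <= 0:
        raise ValueError("pseudocount_frac must be > 0")
    pc = pseudocount_frac * float(input_signal.norm.mean())
    if pc == 0:
        raise ValueError("input track is empty")
    enr = signal.norm / (input_signal.norm + pc)
    return BinnedSignal(signal.bins, signal.raw, enr, signal.library_size,
                        f"{signal.label}_over_input")


def merge_tracks(tracks: list[BinnedSignal], label: str = "merged") -> BinnedSignal:
    """Merge evidence tracks as the mean of normalized signals (e.g. single
    K9 reader merged with the K36-pocket-dead double reader)."""
    if not tracks:
        raise ValueError("no tracks to merge")
    bins = tracks[0].bins
    for t in tracks[1:]:
        if t.bins.n_bins != bins.n_bins or t.bins.width != bins.width:
            raise ValueError("tracks must share a bin set")
    norm = np.mean([t.norm for t in tracks], axis=0)
    raw = np.mean([t.raw for t in tracks], axis=0)
    lib = int(np.mean([t.library_size for t in tracks]))
    return BinnedSignal(bins, raw, norm, lib, label)


def spearman_matrix(tracks: list[BinnedSignal],
                    use_raw: bool = True) -> CorrelationMatrix:
    """Pairwise Spearman correlation of per-bin values (average ranks for
    ties).  A constant track has undefined rank correlation and is reported
    as missing (NaN), not zero."""
    if len(tracks) < 2:
        raise ValueError("need at least two tracks")
    bins = tracks[0].bins
    for t in tracks[1:]:
        if t.bins.n_bins != bins.n_bins or t.bins.width != bins.width:
            raise ValueError("all tracks must be on the identical bin set")
    labels = [t.label for t in tracks]
    values = [t.raw if use_raw else t.norm for t in tracks]
    n = len(tracks)
    mat = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if np.all(values[i] == values[i][0]) or np.all(values[j] == values[j][0]):
                rho = np.nan
            else:
                rho = stats.spearmanr(values[i], values[j]).statistic
            mat[i, j] = mat[j, i] = rho
    for i in range(n):
        if np.all(values[i] == values[i][0]):
            mat[i, i] = np.nan
    df = pd.DataFrame(mat, index=labels, columns=labels)
    return CorrelationMatrix(labels, df, bins.width)


def call_broad_domains(signal: BinnedSignal, input_signal: BinnedSignal,
                       min_fold: float = 3.0, max_gap_bins: int = 1,
                       min_len_bins: int = 2) -> PeakSet:
    """Deliberately simple broad-domain caller for synthetic pipelines.

    A bin is marked when its normalized signal reaches ``min_fold`` times
    the per-bin floor max(input, genome-median of the signal); marked runs
    separated by gaps of at most ``max_gap_bins`` are joined, and runs of at
    least ``min_len_bins`` bins are emitted as peaks.  Real-data users
    supply externally called peaks as BED instead.
    """
    if signal.bins.n_bins != input_signal.bins.n_bins:
        raise ValueError("signal and input must share a bin set")
    floor = np.maximum(input_signal.norm, np.median(signal.norm))
    marked = signal.norm >= min_fold * floor
    rows = []
    bins = signal.bins
    for chrom in sorted(bins.offsets):
        first, n = bins.offsets[chrom]
        m = marked[first:first + n]
        runs: list[list[int]] = []
        i = 0
        while i < n:
            if m[i]:
                j = i
                while j + 1 < n and m[j + 1]:
                    j += 1
                if runs and i - runs[-1][1] - 1 <= max_gap_bins:
                    runs[-1][1] = j
                else:
                    runs.append([i, j])
                i = j + 1
            else:
                i += 1
        for i0, j0 in runs:
            if j0 - i0 + 1 >= min_len_bins:
                rows.append((chrom, int(bins.starts[first + i0]),
                             int(bins.ends[first + j0])))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return PeakSet(df, label=f"{signal.label}_domains")
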