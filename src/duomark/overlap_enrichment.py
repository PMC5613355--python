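"""Peak overlap counting, randomized-peak enrichment and factor-site overlap.

The null model for enrichment is the simple randomization used for
genome-wide peak-set comparisons: each observed peak is re-placed uniformly
at random on its own chromosome, preserving the number and lengths of peaks
(but not inter-peak spacing or exclusion zones; an optional non-overlap
constraint is available and off by default).  Observed overlap is measured
in bases by default to avoid length bias; a peak-count mode is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomic_io import PeakSet, intersect, merge

logger = logging.getLogger("duomark")

__all__ = [
    "VennCounts",
    "EnrichmentResult",
    "venn_counts",
    "shuffle_peaks",
    "segment_enrichment",
    "fraction_sites_overlaid",
]


@dataclass
class VennCounts:
    """Per-set unique / overlapping peak counts (need not be symmetric)."""

    a_only: int
    b_only: int
    a_overlapping: int
    b_overlapping: int


@dataclass
class EnrichmentResult:
    """Observed overlap vs a shuffle null for one segment label."""

    label: str
    observed: float
    null_mean: float
    null_sd: float
    ratio: float          # observed / null mean (NaN when null mean is 0)
    p_value: float        # empirical, (1 + #null >= obs) / (n_iter + 1)
    n_iter: int
    seed: int

    def to_row(self) -> dict:
        return {"label": self.label, "observed": self.observed,
                "null_mean": self.null_mean, "null_sd": self.null_sd,
                "ratio": self.ratio, "p_value": self.p_value,
                "n_iter": self.n_iter}


def _overlap_flags(a: PeakSet, b: PeakSet) -> np.ndarray:
    """Per-peak flag: does peak i of a intersect >= 1 bp of any peak in b."""
    flags = np.zeros(len(a), dtype=bool)
    merged_b = merge(b)
    for chrom in a.chroms():
        da = a.subset(chrom)
        db = merged_b.subset(chrom)
        if len(db) == 0:
            continue
        b_start = db["start"].to_numpy()
        b_end = db["end"].to_numpy()
        a_start = da["start"].to_numpy()
        a_end = da["end"].to_numpy()
        # merged b is disjoint+sorted: peak overlaps iff the first b interval
        # with end > a_start also starts before a_end
        j = np.searchsorted(b_end, a_start, side="right")
        ok = (j < len(b_start)) & (b_start[np.minimum(j, len(b_start) - 1)]
                                   < a_end)
        flags[da.index.to_numpy()] = ok
    return flags


def venn_counts(a: PeakSet, b: PeakSet) -> VennCounts:
    """Unique and overlapping peak counts of two sets (>= 1 bp overlap)."""
    fa = _overlap_flags(a, b)
    fb = _overlap_flags(b, a)
    return VennCounts(int((~fa).sum()), int((~fb).sum()),
                      int(fa.sum()), int(fb.sum()))


def shuffle_peaks(peaks: PeakSet, chrom_sizes: dict[str, int], seed: int,
                  non_overlapping: bool = False,
                  max_tries: int = 100) -> PeakSet:
    """Re-place every peak uniformly at random on its own chromosome.

    Number, lengths and chromosome assignment are preserved; output peaks
    may overlap each other unless ``non_overlapping`` is set (rejection
    sampling, failing after ``max_tries`` sweeps).
    """
    rng = np.random.default_rng([seed, 701])
    rows = []
    for row in peaks.df.itertuples(index=False):
        length = int(row.end - row.start)
        if row.chrom not in chrom_sizes:
            raise ValueError(f"unknown chromosome {row.chrom!r}")
        L = chrom_sizes[row.chrom]
        if length > L:
            raise ValueError(
                f"peak of length {length} exceeds chromosome {row.chrom!r} "
                f"({L} bp)")
        placed = False
        for _ in range(max_tries if non_overlapping else 1):
            s = int(rng.integers(0, L - length + 1))
            if non_overlapping and any(
                    c == row.chrom and s < e0 and s + length > s0
                    for c, s0, e0 in rows):
                continue
            placed = True
            break
        if not placed:
            raise RuntimeError("could not place non-overlapping shuffled peak")
        rows.append((row.chrom, s, s + length))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return PeakSet(df, label=f"{peaks.label}_shuffled")


def _overlap_bases_by_label(peaks: PeakSet, segments: PeakSet) -> dict[str, float]:
    out: dict[str, float] = {}
    for label, grp in segments.df.groupby("name", sort=True):
        seg = PeakSet(grp[["chrom", "start", "end"]].copy(), label=str(label))
        out[str(label)] = float(intersect(peaks, seg).total_bases())
    return out


def _overlap_counts_by_label(peaks: PeakSet, segments: PeakSet) -> dict[str, float]:
    out: dict[str, float] = {}
    for label, grp in segments.df.groupby("name", sort=True):
        seg = PeakSet(grp[["chrom", "start", "end"]].copy(), label=str(label))
        out[str(label)] = float(_overlap_flags(peaks, seg).sum())
    return out


def segment_enrichment(peaks: PeakSet, segments: PeakSet,
                       chrom_sizes: dict[str, int], n_iter: int = 100,
                       seed: int = 0, unit: str = "bases",
                       labels: list[str] | None = None) -> pd.DataFrame:
    """Enrichment of a peak set in labeled genome segments vs shuffled peaks.

    ``segments`` is a BED4-style labeled PeakSet (e.g. a chromatin-state
    segmentation).  For every label the observed overlap (bases by default,
    peak counts with ``unit='count'``) is compared with ``n_iter`` shuffle
    nulls; with n_iter=0 only observed values are reported.  Labels
    requested but absent from the segments yield NaN rows.
    """
    if unit not in ("bases", "count"):
        raise ValueError(f"unknown overlap unit {unit!r}")
    measure = (_overlap_bases_by_label if unit == "bases"
               else _overlap_counts_by_label)
    observed = measure(peaks, segments)
    present = sorted(observed)
    wanted = labels if labels is not None else present

    null: dict[str, list[float]] = {label: [] for label in present}
    for it in range(n_iter):
        shuffled = shuffle_peaks(peaks, chrom_sizes, seed=seed * 100003 + it)
        for label, value in measure(shuffled, segments).items():
            null[label].append(value)

    rows = []
    for label in wanted:
        if label not in observed:
            rows.append({"label": label, "observed": np.nan,
                         "null_mean": np.nan, "null_sd": np.nan,
                         "ratio": np.nan, "p_value": np.nan, "n_iter": n_iter})
            logger.warning("segment_enrichment: label %r absent from segments",
                           label)
            continue
        obs = observed[label]
        if n_iter == 0:
            rows.append({"label": label, "observed": obs, "null_mean": np.nan,
                         "null_sd": np.nan, "ratio": np.nan,
                         "p_value": np.nan, "n_iter": 0})
            continue
        arr = np.asarray(null[label], dtype=float)
        mean, sd = float(arr.mean()), float(arr.std(ddof=0))
        ratio = obs / mean if mean > 0 else np.nan
        p = (1.0 + float((arr >= obs).sum())) / (n_iter + 1.0)
        rows.append({"label": label, "observed": obs, "null_mean": mean,
                     "null_sd": sd, "ratio": ratio, "p_value": p,
                     "n_iter": n_iter})
    return pd.DataFrame(rows)


def fraction_sites_overlaid(factor_peaks: PeakSet,
                            bivalent_peaks: PeakSet) -> float:
    """Fraction of factor binding sites intersecting >= 1 bp of the bivalent
    peak set (NaN for an empty factor set)."""
    if len(factor_peaks) == 0:
        logger.warning("fraction_sites_overlaid: empty factor set")
        return float("nan")
    flags = _overlap_flags(factor_peaks, bivalent_peaks)
    return float(flags.mean())
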