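"""Expression-stratified metagene profiles, anchor-centered tag-density
matrices, k-means clustering and cluster gene-list export.

Metagene profiles rescale every gene body to a fixed number of positional
bins with fixed-width flanks, orient minus-strand genes 5'->3', and average
RPKM-style densities per expression group.  Tag-density matrices collect
read densities in fixed windows around anchor midpoints (TSS, peak
midpoints); rows are clustered with seeded k-means for heatmap export, and
each anchor can be linked to its nearest sufficiently distal TSS to produce
per-cluster gene lists for external GO tools.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .genomic_io import GeneModel, PeakSet

logger = logging.getLogger("duomark")

__all__ = [
    "ExpressionGroups",
    "ProfileMatrix",
    "ClusterResult",
    "EXPRESSION_GROUP_ORDER",
    "assign_expression_groups",
    "metagene_profile",
    "tag_density_matrix",
    "kmeans_clusters",
    "export_cluster_genes",
]

EXPRESSION_GROUP_ORDER = ("no_expression", "low_1", "low_2", "medium", "high")


@dataclass
class ExpressionGroups:
    """Transcript -> expression-group assignment with RPKM retained.

    Zero-RPKM transcripts are exactly the ``no_expression`` group; the
    remaining transcripts are split into four contiguous RPKM-rank quantile
    groups (low_1, low_2, medium, high), ties broken by transcript id.
    """

    table: pd.DataFrame  # gene_id, rpkm, group

    def ids_in_group(self, group: str) -> list[str]:
        return self.table.loc[self.table["group"] == group, "gene_id"].tolist()

    def group_of(self) -> dict[str, str]:
        return dict(zip(self.table["gene_id"], self.table["group"]))

    def counts(self) -> dict[str, int]:
        vc = self.table["group"].value_counts()
        return {g: int(vc.get(g, 0)) for g in EXPRESSION_GROUP_ORDER}


def assign_expression_groups(expression: pd.DataFrame,
                             id_col: str = "gene_id",
                             rpkm_col: str = "rpkm") -> ExpressionGroups:
    """Rank transcripts by RPKM into the five-group scheme.

    The five labels resolve to zero-RPKM = ``no_expression`` set aside, then
    four rank-quantile groups over the nonzero transcripts — the reading
    consistent with "four groups" carrying five labels.
    """
    if len(expression) == 0:
        raise ValueError("empty expression table")
    if (expression[rpkm_col] < 0).any():
        raise ValueError("negative RPKM")
    df = expression[[id_col, rpkm_col]].rename(
        columns={id_col: "gene_id", rpkm_col: "rpkm"}).copy()
    df["group"] = "no_expression"
    nonzero = df[df["rpkm"] > 0].sort_values(
        ["rpkm", "gene_id"], kind="mergesort")
    n = len(nonzero)
    if n:
        ranks = np.arange(n)
        quartile = np.minimum((ranks * 4) // n, 3)
        labels = np.array(["low_1", "low_2", "medium", "high"])[quartile]
        df.loc[nonzero.index, "group"] = labels
        if df.loc[nonzero.index, "rpkm"].duplicated().any():
            logger.info("expression grouping: RPKM ties broken by gene id order")
    return ExpressionGroups(df.reset_index(drop=True))


@dataclass
class ProfileMatrix:
    """Per-anchor positional read-density rows (one column per position bin)."""

    matrix: np.ndarray            # (n_anchors, n_columns), NaN where padded
    anchor_ids: list[str]
    column_positions: np.ndarray  # bp offset of each column center from anchor
    label: str = ""

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix,
                          columns=[f"{int(p)}" for p in self.column_positions])
        df.insert(0, "anchor", self.anchor_ids)
        return df


@dataclass
class ClusterResult:
    """Seeded k-means partition of profile rows."""

    labels: np.ndarray            # cluster index per row, 1..k
    centers: np.ndarray           # (k, n_columns) mean profiles
    k: int
    seed: int
    inertia: float
    row_order: np.ndarray         # rows sorted by cluster then mean signal

    def rows_in_cluster(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)


def _gene_bin_edges(gene: GeneModel, flank: int, n_body_bins: int,
                    n_flank_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Absolute bin edges (upstream flank, body, downstream flank) in genome
    orientation, plus per-bin widths."""
    up = np.linspace(gene.start - flank, gene.start, n_flank_bins + 1)
    body = np.linspace(gene.start, gene.end, n_body_bins + 1)
    down = np.linspace(gene.end, gene.end + flank, n_flank_bins + 1)
    edges = np.concatenate([up[:-1], body[:-1], down])
    widths = np.diff(edges)
    return edges, widths


def metagene_profile(reads, genes: Sequence[GeneModel],
                     groups: ExpressionGroups, flank: int = 2000,
                     n_body_bins: int = 40, n_flank_bins: int = 10,
                     library_size: int | None = None) -> pd.DataFrame:
    """Per-expression-group mean metagene profile.

    Gene bodies are rescaled to ``n_body_bins`` positional bins regardless of
    length; flanks are fixed-width.  Minus-strand genes are reversed so the
    profile always runs 5'->3'.  Densities are RPKM-style: reads per kb of
    bin width per million library reads, averaged over the genes of each
    group.  Returns a DataFrame indexed by group with one column per
    positional bin (negative = upstream flank, 0..n_body_bins-1 = body,
    then downstream flank).
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    lib = library_size if library_size is not None else max(len(reads), 1)
    group_of = groups.group_of()
    mids = reads.midpoints()
    by_chrom = {chrom: np.sort(grp["pos"].to_numpy())
                for chrom, grp in mids.groupby("chrom", sort=False)}

    n_cols = n_body_bins + 2 * n_flank_bins
    sums: dict[str, np.ndarray] = {g: np.zeros(n_cols)
                                   for g in EXPRESSION_GROUP_ORDER}
    n_genes: dict[str, int] = {g: 0 for g in EXPRESSION_GROUP_ORDER}

    for gene in genes:
        group = group_of.get(gene.gene_id)
        if group is None:
            continue
        if len(gene) < n_body_bins:
            warnings.warn(f"gene {gene.gene_id} shorter than n_body_bins; "
                          "body bins repeat bases")
        edges, widths = _gene_bin_edges(gene, flank, n_body_bins, n_flank_bins)
        pos = by_chrom.get(gene.chrom, np.array([], dtype=np.int64))
        counts = np.diff(np.searchsorted(pos, edges))
        density = counts / np.maximum(widths, 1e-9) * 1e3 * 1e6 / lib
        if gene.strand == "-":
            density = density[::-1]
        sums[group] += density
        n_genes[group] += 1

    rows = {}
    for g in EXPRESSION_GROUP_ORDER:
        rows[g] = sums[g] / n_genes[g] if n_genes[g] else np.full(n_cols, np.nan)
    col_names = ([f"up_{i}" for i in range(n_flank_bins)]
                 + [f"body_{i}" for i in range(n_body_bins)]
                 + [f"down_{i}" for i in range(n_flank_bins)])
    out = pd.DataFrame(rows).T
    out.columns = col_names
    out.index.name = "group"
    return out


def tag_density_matrix(reads, anchors: PeakSet, window: int = 5000,
                       bin_width: int = 100,
                       library_size: int | None = None,
                       label: str = "") -> ProfileMatrix:
    """Read density in positional bins of a fixed window around each anchor
    midpoint.  Columns outside the chromosome are padded with NaN.  Row i,
    column j is the density in the j-th bin around anchor i."""
    if window % bin_width != 0:
        raise ValueError("window must be a multiple of bin_width")
    lib = library_size if library_size is not None else max(len(reads), 1)
    n_cols = 2 * window // bin_width
    offsets = np.arange(-window, window, bin_width) + bin_width / 2

    mids = reads.midpoints()
    by_chrom = {chrom: np.sort(grp["pos"].to_numpy())
                for chrom, grp in mids.groupby("chrom", sort=False)}
    sizes = reads.chrom_sizes or {}

    mat = np.full((len(anchors), n_cols), np.nan)
    ids = []
    for i, iv in enumerate(anchors):
        ids.append(iv.name or f"{iv.chrom}:{iv.start}-{iv.end}")
        center = iv.midpoint
        edges = center - window + np.arange(n_cols + 1) * bin_width
        pos = by_chrom.get(iv.chrom, np.array([], dtype=np.int64))
        counts = np.diff(np.searchsorted(pos, edges)).astype(float)
        chrom_len = sizes.get(iv.chrom)
        valid = np.ones(n_cols, dtype=bool)
        if chrom_len is not None:
            valid = (edges[:-1] >= 0) & (edges[1:] <= chrom_len)
        counts[~valid] = np.nan
        mat[i] = counts * 1e6 / lib
    return ProfileMatrix(mat, ids, offsets, label=label)


def kmeans_clusters(matrices: list[ProfileMatrix], k: int = 10, seed: int = 0,
                    max_iter: int = 300,
                    row_normalize: bool = False) -> ClusterResult:
    """Seeded k-means (k-means++ / Lloyd) over column-wise concatenated
    profile matrices.  Deterministic for a fixed seed.  Rows are additionally
    ordered by cluster, then by descending within-cluster mean signal, for
    heatmap export."""
    if not matrices:
        raise ValueError("no matrices supplied")
    n_rows = matrices[0].shape[0]
    for m in matrices[1:]:
        if m.shape[0] != n_rows:
            raise ValueError("matrices must cover the same anchors")
    data = np.concatenate([m.matrix for m in matrices], axis=1)
    if np.all(np.isnan(data), axis=1).any():
        raise ValueError("row with only missing values")
    data = np.nan_to_num(data, nan=0.0)
    if k > n_rows:
        raise ValueError(f"k={k} exceeds the {n_rows} rows available")
    if row_normalize:
        peak = data.max(axis=1, keepdims=True)
        data = data / np.maximum(peak, 1e-12)
    km = KMeans(n_clusters=k, init="k-means++", n_init=10,
                max_iter=max_iter, random_state=seed)
    labels0 = km.fit_predict(data)
    labels = labels0 + 1
    mean_signal = data.mean(axis=1)
    order = np.lexsort((-mean_signal, labels))
    return ClusterResult(labels, km.cluster_centers_, k, seed,
                         float(km.inertia_), order)


def export_cluster_genes(clusters: ClusterResult, anchors: PeakSet,
                         genes: Sequence[GeneModel],
                         min_distance: int = 10_000,
                         outdir: str | Path | None = None) -> dict[int, list[str]]:
    """Link each anchor to the nearest TSS at distance >= ``min_distance``
    (associating distal elements with putative target genes while excluding
    promoters) and collect unique gene ids per cluster.  Anchors with no
    sufficiently distal TSS on their chromosome stay unlinked (logged)."""
    tss_by_chrom: dict[str, list[tuple[int, str]]] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, []).append((g.tss, g.gene_id))
    for chrom in tss_by_chrom:
        tss_by_chrom[chrom].sort()

    result: dict[int, list[str]] = {c: [] for c in range(1, clusters.k + 1)}
    unlinked = 0
    for i, iv in enumerate(anchors):
        entries = tss_by_chrom.get(iv.chrom, [])
        best: tuple[int, str] | None = None
        for tss, gid in entries:
            dist = abs(tss - iv.midpoint)
            if dist >= min_distance and (best is None or dist < best[0]):
                best = (dist, gid)
        if best is None:
            unlinked += 1
            continue
        cluster = int(clusters.labels[i])
        if best[1] not in result[cluster]:
            result[cluster].append(best[1])
    if unlinked:
        logger.info("export_cluster_genes: %d anchors unlinked "
                    "(no TSS at >= %d bp)", unlinked, min_distance)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for cluster, ids in result.items():
            with open(outdir / f"cluster_{cluster:02d}_genes.txt", "w") as fh:
                fh.write("\n".join(ids) + ("\n" if ids else ""))
    return result
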