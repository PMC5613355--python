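"""Ground-truth genome, nucleosome-population and pull-down simulator.

The generator emulates the statistical structure of a mononucleosomal
CIDOP/ChIP-seq experiment over a genome partitioned into regions of four
chromatin states: unmarked, H3K9me3-only, H3K36me2/3-only and bivalent
(both marks).  Per nucleosome position it tracks how many molecules (cell
population / alleles) carry each per-molecule mark configuration, which is
the ground truth every downstream stage is tested against.

Three generative modes for dual-positive (bivalent) regions encode the
competing biological hypotheses:

``coexistence``
    each molecule carries both marks together (probability = modification
    density) — true per-nucleosome bivalency;
``mixture``
    each molecule carries exactly one of the two marks (allele / cell
    heterogeneity), never both, so each mark's marginal density is halved
    at the default mixing fraction 0.5;
``adjacent``
    alternating nucleosome positions are purely K9- or purely K36-marked.

Affinity reagents are capture-probability tables over the four per-molecule
configurations (:class:`ReaderModel`).  The wild-type double reader is an
AND-logic reagent: its avidity for doubly modified nucleosomes exceeds the
capture of either single mark.  Binding-pocket mutants degenerate the table
to a single-mark readout.  A sequential two-step pull-down composes two
tables multiplicatively on the captured pool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from .genomic_io import GeneModel, PeakSet, write_bed, \
    write_chrom_sizes, write_genes_bed12

logger = logging.getLogger("duomark")

__all__ = [
    "SimConfig",
    "RegionLayout",
    "NucleosomePopulation",
    "ReaderModel",
    "ReadSet",
    "CONFIG_NONE",
    "CONFIG_K9",
    "CONFIG_K36",
    "CONFIG_BOTH",
    "STATE_NAMES",
    "build_layout",
    "populate_molecules",
    "simulate_pulldown",
    "simulate_sequential",
    "simulate_input",
    "wt_and_reader",
    "or_reader",
    "k9_single_reader",
    "k36_single_reader",
    "pwwp_dead_reader",
    "chromo_dead_reader",
]

# per-molecule mark configurations (column order of count matrices)
CONFIG_NONE, CONFIG_K9, CONFIG_K36, CONFIG_BOTH = 0, 1, 2, 3
CONFIG_NAMES = ("none", "k9", "k36", "both")

# regional chromatin states
STATE_NAMES = ("neither", "k9_only", "k36_only", "bivalent")
_STATE_INDEX = {name: i for i, name in enumerate(STATE_NAMES)}

EXPRESSION_GROUPS = ("no_expression", "low_1", "low_2", "medium", "high")

READ_LENGTH = 147  # mononucleosome footprint, bp


@dataclass
class SimConfig:
    """Study conditions of a simulated dual-mark experiment.

    Defaults describe a desk-scale genome with the regional state mix of a
    somatic cell line in which ~15% of the genome is bivalently marked,
    mononucleosomal fragments of 147 bp at 200 bp spacing, and a modification
    density of 0.25 (about a quarter of molecules in a marked region carry
    the region's mark(s)).
    """

    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 4_000_000, "chr2": 4_000_000})
    nucleosome_spacing: int = 200
    molecules_per_position: int = 100
    state_fractions: tuple[float, float, float, float] = (0.55, 0.15, 0.15, 0.15)
    region_length_mean: int = 20_000
    region_length_min: int = 6_000
    mod_density: float = 0.25
    mixture_phi: float = 0.5
    occupancy_sigma: float = 0.5
    k36_gradient_start: float = 0.5
    gene_length_range: tuple[int, int] = (3_000, 6_000)
    gene_flank: int = 1_000
    nonexpressed_gene_prob: float = 0.4
    n_factor_sites: int = 200
    factor_site_length: int = 400
    factor_bivalent_fraction: float = 0.6
    fragment_jitter: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if abs(sum(self.state_fractions) - 1.0) > 1e-9:
            raise ValueError("state_fractions must sum to 1")
        if any(f < 0 for f in self.state_fractions):
            raise ValueError("state_fractions must be non-negative")
        for name in ("nucleosome_spacing", "molecules_per_position",
                     "region_length_mean", "region_length_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if any(L <= 0 for L in self.chrom_sizes.values()):
            raise ValueError("chromosome lengths must be > 0")
        if not 0.0 <= self.mod_density <= 1.0:
            raise ValueError("mod_density must be in [0, 1]")
        if not 0.0 < self.mixture_phi <= 0.5:
            raise ValueError("mixture_phi must be in (0, 0.5]")
        if not 0.0 <= self.k36_gradient_start <= 1.0:
            raise ValueError("k36_gradient_start must be in [0, 1]")
        if (len(self.gene_length_range) != 2
                or self.gene_length_range[0] <= 0
                or self.gene_length_range[0] > self.gene_length_range[1]):
            raise ValueError("gene_length_range must be (lo, hi) with 0 < lo <= hi")
        if self.occupancy_sigma < 0:
            raise ValueError("occupancy_sigma must be >= 0")
        if not 0.0 <= self.factor_bivalent_fraction <= 1.0:
            raise ValueError("factor_bivalent_fraction must be in [0, 1]")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "state_fractions" in data:
            data["state_fractions"] = tuple(data["state_fractions"])
        if "gene_length_range" in data:
            data["gene_length_range"] = tuple(data["gene_length_range"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            **self.__dict__,
            "state_fractions": list(self.state_fractions),
            "gene_length_range": list(self.gene_length_range),
            "chrom_sizes": dict(self.chrom_sizes),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class RegionLayout:
    """Ground-truth regional annotation of a simulated genome.

    Regions tile each chromosome without gaps or overlap; every base has
    exactly one state.  Genes sit inside regions (with a small flank) and
    carry an expression group; factor binding sites co-localize with
    bivalent regions at the configured fraction.
    """

    chrom_sizes: dict[str, int]
    regions: pd.DataFrame          # chrom, start, end, state, occupancy
    genes: list[GeneModel]
    gene_table: pd.DataFrame       # gene_id, group, rpkm
    factor_sites: PeakSet
    config: SimConfig

    def state_base_fractions(self) -> dict[str, float]:
        lengths = self.regions["end"] - self.regions["start"]
        total = float(lengths.sum())
        out = {}
        for state in STATE_NAMES:
            mask = self.regions["state"] == state
            out[state] = float(lengths[mask].sum()) / total
        return out

    def regions_with_state(self, state: str) -> pd.DataFrame:
        return self.regions[self.regions["state"] == state]

    def state_peaks(self, state: str) -> PeakSet:
        sub = self.regions_with_state(state)
        return PeakSet(sub[["chrom", "start", "end"]].copy(), label=state)

    def write(self, outdir: str | Path) -> None:
        """Write layout as plain-text truth files (BED4/BED12/TSV/chrom.sizes)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_chrom_sizes(self.chrom_sizes, outdir / "genome.chrom.sizes")
        truth = self.regions.copy()
        truth = truth.rename(columns={"state": "name"})
        write_bed(PeakSet(truth[["chrom", "start", "end", "name"]]),
                  outdir / "truth_regions.bed", dialect="BED4")
        write_genes_bed12(self.genes, outdir / "genes.bed12")
        self.gene_table.to_csv(outdir / "expression.tsv", sep="\t", index=False,
                               float_format="%.6g")
        write_bed(self.factor_sites, outdir / "factor_sites.bed", dialect="BED3")


@dataclass
class NucleosomePopulation:
    """Per-position molecule counts over the four mark configurations.

    ``counts[i, c]`` is the number of molecules at nucleosome position ``i``
    in configuration ``c`` (none / K9-only / K36-only / both); rows sum to
    the (occupancy-scaled) molecules at that position.
    """

    chroms: np.ndarray            # per-position chromosome name (object)
    starts: np.ndarray            # per-position footprint start (int64)
    counts: np.ndarray            # (n_positions, 4) int64
    region_state: np.ndarray      # per-position regional state index (int8)
    chrom_sizes: dict[str, int]
    mode: str

    @property
    def n_positions(self) -> int:
        return len(self.starts)

    def molecules_per_position(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def total_by_config(self) -> dict[str, int]:
        sums = self.counts.sum(axis=0)
        return {name: int(sums[i]) for i, name in enumerate(CONFIG_NAMES)}

    def marginal_mark_counts(self) -> tuple[int, int]:
        """Total molecules carrying K9 and carrying K36 (both-configured count
        in each)."""
        totals = self.counts.sum(axis=0)
        k9 = int(totals[CONFIG_K9] + totals[CONFIG_BOTH])
        k36 = int(totals[CONFIG_K36] + totals[CONFIG_BOTH])
        return k9, k36

    def summary_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "chrom": self.chroms,
            "start": self.starts,
            "state": [STATE_NAMES[s] for s in self.region_state],
        })
        for i, name in enumerate(CONFIG_NAMES):
            df[f"n_{name}"] = self.counts[:, i]
        return df


@dataclass(frozen=True)
class ReaderModel:
    """Capture-probability table of an affinity reagent.

    One probability per per-molecule mark configuration; ``p_none`` is the
    non-specific background capture of unmarked molecules.
    """

    name: str
    p_none: float
    p_k9: float
    p_k36: float
    p_both: float

    def __post_init__(self) -> None:
        for attr in ("p_none", "p_k9", "p_k36", "p_both"):
            p = getattr(self, attr)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{self.name}: {attr}={p} outside [0, 1]")

    @property
    def probabilities(self) -> np.ndarray:
        return np.array([self.p_none, self.p_k9, self.p_k36, self.p_both])

    def check_and_logic(self) -> None:
        """Assert the AND-logic ordering p(both) > p(K9) >= p(K36) >= bg."""
        if not (self.p_both > self.p_k9 >= self.p_k36 >= self.p_none):
            raise ValueError(
                f"{self.name}: capture table violates AND-logic ordering "
                f"p(both) > p(K9) >= p(K36) >= background")


def wt_and_reader(p_both: float = 0.8, p_k9: float = 0.3,
                  p_k36: float = 0.01, background: float = 0.005) -> ReaderModel:
    """Wild-type double reader: AND-logic avidity for doubly marked nucleosomes.

    The default asymmetry (K9 arm functional alone, K36 arm essentially not)
    reflects a chromodomain with ~100 nM affinity fused to a PWWP domain
    with ~100 uM affinity under stringent washing.
    """
    reader = ReaderModel("wt_double", background, p_k9, p_k36, p_both)
    reader.check_and_logic()
    return reader


def or_reader(p: float = 0.3, background: float = 0.005) -> ReaderModel:
    """Hypothetical OR-logic reagent: captures if either mark is present."""
    return ReaderModel("or_double", background, p, p, p)


def k9_single_reader(p: float = 0.3, background: float = 0.005) -> ReaderModel:
    """Single K9me3 reader (chromodomain): capture depends only on K9."""
    return ReaderModel("k9_single", background, p, background, p)


def k36_single_reader(p: float = 0.3, background: float = 0.005) -> ReaderModel:
    """Single K36me2/3 reader (PWWP under permissive washing)."""
    return ReaderModel("k36_single", background, background, p, p)


def pwwp_dead_reader(p: float = 0.3, background: float = 0.005) -> ReaderModel:
    """Double reader with inactivated K36 pocket: a de facto K9 reader."""
    return ReaderModel("pwwp_dead", background, p, background, p)


def chromo_dead_reader(p: float = 0.01, background: float = 0.005) -> ReaderModel:
    """Double reader with inactivated K9 pocket: weak K36-only readout."""
    return ReaderModel("chromo_dead", background, background, p, p)


@dataclass
class ReadSet:
    """Sequenced-read intervals from one library, with an optional truth channel.

    ``configs[i]`` records the per-molecule mark configuration of the molecule
    read ``i`` was sampled from (-1 when unknown, e.g. after file round-trip).
    """

    df: pd.DataFrame              # chrom, start, end, config
    label: str
    chrom_sizes: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if len(self.df):
            if (self.df["end"] <= self.df["start"]).any():
                raise ValueError("read with end <= start")
            if (self.df["start"] < 0).any():
                raise ValueError("read with negative start")
            if self.chrom_sizes is not None:
                for chrom, grp in self.df.groupby("chrom", sort=False):
                    if int(grp["end"].max()) > self.chrom_sizes[chrom]:
                        raise ValueError(
                            f"read beyond end of chromosome {chrom!r}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def configs(self) -> np.ndarray:
        return self.df["config"].to_numpy()

    def midpoints(self) -> pd.DataFrame:
        mid = (self.df["start"] + self.df["end"]) // 2
        return pd.DataFrame({"chrom": self.df["chrom"], "pos": mid})

    def write_bed(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", header=False, index=False,
                       columns=["chrom", "start", "end"])

    @classmethod
    def empty(cls, label: str) -> "ReadSet":
        df = pd.DataFrame({"chrom": pd.Series(dtype=object),
                           "start": pd.Series(dtype=np.int64),
                           "end": pd.Series(dtype=np.int64),
                           "config": pd.Series(dtype=np.int8)})
        return cls(df, label)


# ---------------------------------------------------------------------------
# Layout construction
# ---------------------------------------------------------------------------

def _draw_region_lengths(rng: np.random.Generator, chrom_len: int,
                         chrom: str, config: SimConfig) -> np.ndarray:
    """Exponential-ish region lengths >= region_length_min filling the chromosome."""
    if config.region_length_min > chrom_len:
        raise ValueError(
            f"chromosome {chrom!r} (length {chrom_len}) is shorter than the "
            f"minimum region length {config.region_length_min}")
    mean_extra = max(config.region_length_mean - config.region_length_min, 1)
    lengths = []
    remaining = chrom_len
    while remaining > 0:
        length = config.region_length_min + int(rng.exponential(mean_extra))
        if length >= remaining:
            length = remaining
        lengths.append(length)
        remaining -= length
    return np.asarray(lengths, dtype=np.int64)


def _assign_states(rng: np.random.Generator, lengths: np.ndarray,
                   fractions: tuple[float, ...]) -> np.ndarray:
    """Assign regional states so realized base fractions track the targets.

    Regions are visited in random order and each is assigned the state with
    the largest remaining base quota (random tie-break), which keeps realized
    fractions within about one region length of the targets while the random
    visiting order decorrelates state and genomic position.
    """
    total = float(lengths.sum())
    deficits = np.array(fractions) * total
    order = rng.permutation(len(lengths))
    states = np.empty(len(lengths), dtype=np.int8)
    for idx in order:
        jitter = rng.random(4) * 1e-9
        state = int(np.argmax(deficits + jitter))
        states[idx] = state
        deficits[state] -= lengths[idx]
    return states


def build_layout(config: SimConfig) -> RegionLayout:
    """Generate the ground-truth regional layout, genes and factor sites.

    Deterministic for a fixed ``config.seed``.  Realized state base fractions
    match ``config.state_fractions`` within about one region length.  Gene
    expression is tied to the regional state: bivalent regions host
    lowly-expressed genes, K36 regions host medium/highly expressed genes
    (whose bodies carry the 3'-skewed K36 gradient), K9-only and unmarked
    regions host non-expressed genes.  Factor sites land inside bivalent
    regions with probability ``factor_bivalent_fraction``.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 101])

    rows = []
    for chrom in sorted(config.chrom_sizes):
        chrom_len = config.chrom_sizes[chrom]
        lengths = _draw_region_lengths(rng, chrom_len, chrom, config)
        states = _assign_states(rng, lengths, config.state_fractions)
        occ = (np.exp(rng.normal(0.0, config.occupancy_sigma, len(lengths)))
               if config.occupancy_sigma > 0 else np.ones(len(lengths)))
        start = 0
        for length, state, mult in zip(lengths, states, occ):
            rows.append((chrom, start, start + length,
                         STATE_NAMES[state], float(mult)))
            start += length
    regions = pd.DataFrame(rows, columns=["chrom", "start", "end", "state",
                                          "occupancy"])

    genes, gene_rows = [], []
    gid = 0
    for row in regions.itertuples(index=False):
        # one short gene per eligible region, placed inside the interior so
        # quantification bins average over the whole body gradient
        flank = config.gene_flank
        g_len = int(rng.integers(config.gene_length_range[0],
                                 config.gene_length_range[1] + 1))
        if row.end - row.start < g_len + 2 * flank:
            continue
        g_start = int(rng.integers(row.start + flank,
                                   row.end - flank - g_len + 1))
        g_end = g_start + g_len
        strand = "+" if rng.random() < 0.5 else "-"
        if row.state == "bivalent":
            group = "low_1" if rng.random() < 0.5 else "low_2"
        elif row.state == "k36_only":
            group = "medium" if rng.random() < 0.5 else "high"
        else:
            if rng.random() >= config.nonexpressed_gene_prob:
                continue
            group = "no_expression"
        rpkm = {
            "no_expression": 0.0,
            "low_1": float(rng.uniform(0.1, 1.0)),
            "low_2": float(rng.uniform(1.0, 4.0)),
            "medium": float(rng.uniform(4.0, 20.0)),
            "high": float(rng.uniform(20.0, 100.0)),
        }[group]
        gid += 1
        gene_id = f"gene_{gid:04d}"
        genes.append(GeneModel(row.chrom, g_start, g_end, strand, gene_id))
        gene_rows.append((gene_id, group, rpkm))
    gene_table = pd.DataFrame(gene_rows, columns=["gene_id", "group", "rpkm"])

    biv = regions[regions["state"] == "bivalent"].reset_index(drop=True)
    non_biv = regions[regions["state"] != "bivalent"].reset_index(drop=True)
    site_rows = []
    for _ in range(config.n_factor_sites):
        in_biv = rng.random() < config.factor_bivalent_fraction
        pool = biv if in_biv else non_biv
        if len(pool) == 0:
            raise ValueError(
                "layout has no region available for factor-site placement "
                f"({'bivalent' if in_biv else 'non-bivalent'} pool empty)")
        lens = (pool["end"] - pool["start"]).to_numpy().astype(float)
        usable = np.clip(lens - config.factor_site_length, 0, None)
        if usable.sum() <= 0:
            raise ValueError("all candidate regions shorter than a factor site")
        ridx = int(rng.choice(len(pool), p=usable / usable.sum()))
        region = pool.iloc[ridx]
        s = int(rng.integers(region["start"],
                             region["end"] - config.factor_site_length + 1))
        site_rows.append((region["chrom"], s, s + config.factor_site_length))
    sites = PeakSet(pd.DataFrame(site_rows, columns=["chrom", "start", "end"]),
                    label="factor_sites")

    layout = RegionLayout(dict(config.chrom_sizes), regions, genes,
                          gene_table, sites, config)
    fracs = layout.state_base_fractions()
    logger.info("layout: %d regions, %d genes, %d factor sites; "
                "bivalent fraction %.3f",
                len(regions), len(genes), len(sites), fracs["bivalent"])
    return layout


# ---------------------------------------------------------------------------
# Molecule population
# ---------------------------------------------------------------------------

def _nucleosome_positions(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    chroms, starts = [], []
    for chrom in sorted(config.chrom_sizes):
        chrom_len = config.chrom_sizes[chrom]
        pos = np.arange(0, chrom_len - READ_LENGTH + 1,
                        config.nucleosome_spacing, dtype=np.int64)
        starts.append(pos)
        chroms.append(np.full(len(pos), chrom, dtype=object))
    return np.concatenate(chroms), np.concatenate(starts)


def _per_position_annotation(layout: RegionLayout, chroms: np.ndarray,
                             starts: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Regional state index, occupancy multiplier and K36-gradient factor per
    nucleosome position (by footprint midpoint)."""
    n = len(starts)
    state = np.zeros(n, dtype=np.int8)
    occupancy = np.ones(n, dtype=float)
    gradient = np.ones(n, dtype=float)
    mid = starts + READ_LENGTH // 2

    config = layout.config
    gene_groups = dict(zip(layout.gene_table["gene_id"],
                           layout.gene_table["group"]))
    for chrom in sorted(layout.chrom_sizes):
        sel = np.flatnonzero(chroms == chrom)
        if len(sel) == 0:
            continue
        sub = layout.regions[layout.regions["chrom"] == chrom]
        edges = sub["end"].to_numpy()
        ridx = np.searchsorted(edges, mid[sel], side="right")
        ridx = np.clip(ridx, 0, len(sub) - 1)
        state[sel] = np.array([_STATE_INDEX[s] for s in sub["state"]])[ridx]
        occupancy[sel] = sub["occupancy"].to_numpy()[ridx]
        # 5'->3' gradient of K36 density over expressed gene bodies
        for gene in layout.genes:
            if gene.chrom != chrom:
                continue
            if gene_groups.get(gene.gene_id) in ("no_expression", None):
                continue
            inside = sel[(mid[sel] >= gene.start) & (mid[sel] < gene.end)]
            if len(inside) == 0:
                continue
            frac = (mid[inside] - gene.start) / len(gene)
            if gene.strand == "-":
                frac = 1.0 - frac
            # linear 5'->3' ramp from g0 to 2-g0: mean 1 over the body, so
            # the regional mean K36 density remains mod_density
            g0 = config.k36_gradient_start
            gradient[inside] = g0 + 2.0 * (1.0 - g0) * frac
    return state, occupancy, gradient


def populate_molecules(layout: RegionLayout, mode: str,
                       config: SimConfig | None = None,
                       seed: int | None = None) -> NucleosomePopulation:
    """Draw per-molecule mark configurations at every nucleosome position.

    ``mode`` selects the generative hypothesis for bivalent regions
    (``coexistence`` / ``mixture`` / ``adjacent``, see module docstring);
    single-mark and unmarked regions are populated identically across modes.
    """
    if mode not in ("coexistence", "mixture", "adjacent"):
        raise ValueError(
            f"unknown mode {mode!r}: expected coexistence, mixture or adjacent")
    config = config or layout.config
    base_seed = config.seed if seed is None else seed
    # single-mark regions are drawn from a mode-independent stream so the
    # three modes differ only inside bivalent regions
    rng = np.random.default_rng([base_seed, 211])
    rng_biv = np.random.default_rng(
        [base_seed, 211, ("coexistence", "mixture", "adjacent").index(mode)])

    chroms, starts = _nucleosome_positions(config)
    state, occupancy, gradient = _per_position_annotation(layout, chroms, starts)
    n = len(starts)
    molecules = np.maximum(
        np.rint(config.molecules_per_position * occupancy), 1).astype(np.int64)
    counts = np.zeros((n, 4), dtype=np.int64)
    d = config.mod_density

    is_k9 = state == _STATE_INDEX["k9_only"]
    is_k36 = state == _STATE_INDEX["k36_only"]
    is_biv = state == _STATE_INDEX["bivalent"]

    counts[is_k9, CONFIG_K9] = rng.binomial(molecules[is_k9], d)
    counts[is_k36, CONFIG_K36] = rng.binomial(
        molecules[is_k36], np.clip(d * gradient[is_k36], 0.0, 1.0))

    if mode == "coexistence":
        counts[is_biv, CONFIG_BOTH] = rng_biv.binomial(molecules[is_biv], d)
    elif mode == "mixture":
        phi = config.mixture_phi
        nb = int(is_biv.sum())
        if nb:
            p = np.array([1.0 - 2 * phi * d, phi * d, phi * d])
            multi = np.array([rng_biv.multinomial(m, p)
                              for m in molecules[is_biv]])
            counts[is_biv, CONFIG_K9] = multi[:, 1]
            counts[is_biv, CONFIG_K36] = multi[:, 2]
    else:  # adjacent
        idx_biv = np.flatnonzero(is_biv)
        even = idx_biv[(starts[idx_biv] // config.nucleosome_spacing) % 2 == 0]
        odd = idx_biv[(starts[idx_biv] // config.nucleosome_spacing) % 2 == 1]
        counts[even, CONFIG_K9] = rng_biv.binomial(molecules[even], d)
        counts[odd, CONFIG_K36] = rng_biv.binomial(molecules[odd], d)

    marked = counts[:, CONFIG_K9] + counts[:, CONFIG_K36] + counts[:, CONFIG_BOTH]
    counts[:, CONFIG_NONE] = molecules - marked

    pop = NucleosomePopulation(chroms, starts, counts, state,
                               dict(layout.chrom_sizes), mode)
    if mode == "mixture" and int(pop.counts[is_biv, CONFIG_BOTH].sum()) != 0:
        raise AssertionError("mixture mode produced doubly marked molecules")
    return pop


# ---------------------------------------------------------------------------
# Pull-down / input read simulation
# ---------------------------------------------------------------------------

def _sample_reads(population: NucleosomePopulation, captured: np.ndarray,
                  depth: int, rng: np.random.Generator, label: str,
                  jitter: int = 0) -> ReadSet:
    """Sample ``depth`` reads with replacement from the captured molecule pool."""
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if depth == 0:
        return ReadSet.empty(label)
    total = int(captured.sum())
    if total == 0:
        raise ValueError(
            f"{label}: captured molecule pool is empty at depth {depth}; "
            "increase the reader's background capture probability or depth")
    weights = captured.ravel().astype(float)
    draw = rng.multinomial(depth, weights / weights.sum())
    idx = np.flatnonzero(draw)
    pos_idx = idx // 4
    cfg = (idx % 4).astype(np.int8)
    reps = draw[idx]
    chrom = np.repeat(population.chroms[pos_idx], reps)
    start = np.repeat(population.starts[pos_idx], reps)
    config_col = np.repeat(cfg, reps)
    if jitter > 0:
        shift = rng.integers(-jitter, jitter + 1, size=len(start))
        start = start + shift
        for c, L in population.chrom_sizes.items():
            m = chrom == c
            start[m] = np.clip(start[m], 0, L - READ_LENGTH)
    df = pd.DataFrame({"chrom": chrom, "start": start.astype(np.int64),
                       "end": (start + READ_LENGTH).astype(np.int64),
                       "config": config_col})
    df = df.sort_values(["chrom", "start", "config"], kind="mergesort",
                        ignore_index=True)
    return ReadSet(df, label, dict(population.chrom_sizes))


def simulate_pulldown(population: NucleosomePopulation, reader: ReaderModel,
                      depth: int, seed: int, jitter: int = 0) -> ReadSet:
    """One CIDOP/ChIP pull-down: capture molecules per the reader's table,
    then sequence the captured pool to ``depth`` reads (with replacement)."""
    rng = np.random.default_rng([seed, 307])
    captured = rng.binomial(population.counts,
                            reader.probabilities[np.newaxis, :])
    return _sample_reads(population, captured, depth, rng, reader.name, jitter)


def simulate_sequential(population: NucleosomePopulation, reader1: ReaderModel,
                        reader2: ReaderModel, depth: int, seed: int,
                        jitter: int = 0) -> ReadSet:
    """Two-step sequential pull-down: the second capture operates only on the
    molecules captured by the first, so only molecules passing both filters
    can contribute reads."""
    rng = np.random.default_rng([seed, 401])
    cap1 = rng.binomial(population.counts, reader1.probabilities[np.newaxis, :])
    cap2 = rng.binomial(cap1, reader2.probabilities[np.newaxis, :])
    label = f"{reader1.name}>{reader2.name}"
    return _sample_reads(population, cap2, depth, rng, label, jitter)


def simulate_input(population: NucleosomePopulation, depth: int,
                   seed: int, jitter: int = 0) -> ReadSet:
    """Input/control track: uniform sampling over all molecules present."""
    rng = np.random.default_rng([seed, 503])
    return _sample_reads(population, population.counts, depth, rng,
                         "input", jitter)
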