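"""End-to-end demo pipeline: simulate -> quantify -> call states ->
coexistence -> profiles/clustering -> enrichment -> report bundle.

Every stochastic stage receives an explicit seed derived from the single
pipeline seed, so the full output bundle is reproducible from the config
alone; the effective config is echoed into the output directory.  Real-data
mode is the same code path with user-supplied BED/bedGraph inputs replacing
the simulator outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coexistence as cx
from . import overlap_enrichment as oe
from . import profiles_clustering as pc
from . import signal_quant as sq
from . import state_caller as st
from . import synthetic_data as sd
from .genomic_io import PeakSet, merge as gmerge, write_bed

logger = logging.getLogger("duomark")

__all__ = ["PipelineConfig", "PipelineResult", "AnalysisBundle", "analyze",
           "run_demo"]


@dataclass
class PipelineConfig:
    """Configuration of the demo pipeline.

    ``depth`` is reads per pull-down library; ``input_depth`` is the input
    library (deeper, since it is the denominator of per-bin enrichment).
    ``threshold`` is the presence-cutoff preset ('default' = genome mean +
    1 SD of nonzero bins, 'stringent' = +2 SD).
    """

    sim: sd.SimConfig = field(default_factory=sd.SimConfig)
    mode: str = "coexistence"
    depth: int = 400_000
    input_depth: int = 1_200_000
    bin_width: int = 3_000
    corr_bin_width: int = 10_000
    threshold: str = "default"
    n_bootstrap: int = 500
    kmeans_k: int = 10
    seed: int = 0
    outdir: str = "duomark_demo"

    def threshold_spec(self) -> st.ThresholdSpec:
        presets = {"default": st.DEFAULT, "stringent": st.STRINGENT}
        if self.threshold not in presets:
            raise ValueError(f"unknown threshold preset {self.threshold!r}")
        return presets[self.threshold]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        sim = data.pop("sim", None)
        cfg = cls(**data)
        if sim is not None:
            for key in ("state_fractions", "gene_length_range"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            cfg.sim = sd.SimConfig(**sim)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["sim"]["state_fractions"] = list(data["sim"]["state_fractions"])
        data["sim"]["gene_length_range"] = list(data["sim"]["gene_length_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class PipelineResult:
    """In-memory handles on everything the demo wrote."""

    config: PipelineConfig
    layout: sd.RegionLayout
    states: st.StateVector
    state_summary: st.StateSummary
    coexistence_report: cx.CoexistenceReport
    sequential_folds: dict[str, float]
    correlation: sq.CorrelationMatrix
    metagene: pd.DataFrame
    clusters: pc.ClusterResult
    enrichment: pd.DataFrame
    factor_overlap_fraction: float
    outdir: Path


def _derive_seed(base: int, stage: int) -> int:
    # keep derived seeds well below 2**31
    return (base * 1009 + stage) % (2**31 - 1)


@dataclass
class AnalysisBundle:
    """In-memory result of the core analysis (no file output)."""

    sim: sd.SimConfig
    layout: sd.RegionLayout
    population: sd.NucleosomePopulation
    reads: dict[str, sd.ReadSet]
    bins: sq.BinSet
    tracks: dict[str, sq.BinnedSignal]
    enrichment_tracks: dict[str, sq.BinnedSignal]
    k9_evidence: sq.BinnedSignal
    k36_evidence: sq.BinnedSignal
    states: st.StateVector
    wt_presence: np.ndarray
    summary: st.StateSummary
    mutant_presence: np.ndarray
    mutant_summary: st.StateSummary
    report: cx.CoexistenceReport
    folds: dict[str, float]


def analyze(config: PipelineConfig) -> AnalysisBundle:
    """Core pipeline: simulate libraries, quantify, call states, summarize
    the wild-type and mutant pull-downs, and run the coexistence test.

    Pure computation (no files); :func:`run_demo` writes the report bundle
    from this.  Evidence tracks follow the emulated study design: K9
    presence from the single K9 reader merged with the K36-pocket-dead
    double reader, K36 presence from two merged single-reader replicates,
    all input-normalized.
    """
    seed = config.seed
    sim = config.sim.with_seed(_derive_seed(seed, 1))
    layout = sd.build_layout(sim)
    population = sd.populate_molecules(layout, config.mode, sim)

    readers = {
        "wt_double": sd.wt_and_reader(),
        "pwwp_dead": sd.pwwp_dead_reader(),
        "k9_single": sd.k9_single_reader(),
        "k36_single": sd.k36_single_reader(),
    }
    reads = {name: sd.simulate_pulldown(population, reader, config.depth,
                                        _derive_seed(seed, 10 + i))
             for i, (name, reader) in enumerate(readers.items())}
    reads["wt_double_rep2"] = sd.simulate_pulldown(
        population, readers["wt_double"], config.depth, _derive_seed(seed, 20))
    reads["k36_single_rep2"] = sd.simulate_pulldown(
        population, readers["k36_single"], config.depth, _derive_seed(seed, 23))
    reads["input"] = sd.simulate_input(population, config.input_depth,
                                       _derive_seed(seed, 21))
    reads["sequential"] = sd.simulate_sequential(
        population, sd.k9_single_reader(), sd.k36_single_reader(),
        config.depth, _derive_seed(seed, 22))

    bins = sq.tile_genome(sim.chrom_sizes, config.bin_width)
    tracks = {name: sq.quantify(rs, bins) for name, rs in reads.items()}
    enr = {name: sq.enrichment_over_input(tracks[name], tracks["input"])
           for name in ("wt_double", "pwwp_dead", "k9_single", "k36_single",
                        "k36_single_rep2")}

    spec = config.threshold_spec()
    k9_evidence = sq.merge_tracks([enr["k9_single"], enr["pwwp_dead"]],
                                  label="k9_merged")
    k36_evidence = sq.merge_tracks([enr["k36_single"],
                                    enr["k36_single_rep2"]],
                                   label="k36_merged")
    k9_presence = st.call_presence(k9_evidence, st.MARK_PRESENCE)
    k36_presence = st.call_presence(k36_evidence, st.MARK_PRESENCE)
    states = st.classify_states(k9_presence, k36_presence, bins)

    wt_presence = st.call_presence(enr["wt_double"], spec)
    summary = st.pulldown_summary(states, wt_presence)
    mutant_presence = st.call_presence(enr["pwwp_dead"], spec)
    mutant_summary = st.pulldown_summary(states, mutant_presence)

    report = cx.coexistence_test(k9_evidence, k36_evidence, states,
                                 n_bootstrap=config.n_bootstrap,
                                 seed=_derive_seed(seed, 30))
    folds = cx.sequential_fold(reads["sequential"], reads["input"], states)
    return AnalysisBundle(sim, layout, population, reads, bins, tracks, enr,
                          k9_evidence, k36_evidence, states, wt_presence,
                          summary, mutant_presence, mutant_summary, report,
                          folds)


def run_demo(config: PipelineConfig) -> PipelineResult:
    """Run the full synthetic analysis and write the report bundle.

    Outputs (all plain text, all reproducible from config + seed):
    truth layout (BED/TSV), per-track bedGraph, state map BED4, state/recovery
    summary TSV, coexistence report TSV + text, sequential folds TSV,
    correlation matrix TSV, metagene TSV, tag-matrix cluster labels TSV,
    segment enrichment TSV, factor overlap TSV and a log of seeds and cutoffs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config_echo.yaml")
    seed = config.seed

    bundle = analyze(config)
    sim, layout, reads = bundle.sim, bundle.layout, bundle.reads
    states, summary, report, folds = (bundle.states, bundle.summary,
                                      bundle.report, bundle.folds)
    layout.write(outdir / "truth")
    for name, track in bundle.tracks.items():
        track.to_bedgraph_frame().to_csv(
            outdir / f"{name}.bedgraph", sep="\t", header=False, index=False,
            float_format="%.6g")

    corr_bins = sq.tile_genome(sim.chrom_sizes, config.corr_bin_width)
    corr_tracks = []
    for n in ("wt_double", "wt_double_rep2", "pwwp_dead", "k9_single",
              "k36_single", "k36_single_rep2"):
        track = sq.quantify(reads[n], corr_bins)
        track.label = n
        corr_tracks.append(track)
    correlation = sq.spearman_matrix(corr_tracks)
    correlation.matrix.to_csv(outdir / "spearman_10kb.tsv", sep="\t",
                              float_format="%.4f")

    states.to_frame().to_csv(outdir / "states.tsv", sep="\t", index=False)
    state_bed = states.to_frame().rename(columns={"state": "name"})
    write_bed(PeakSet(state_bed[["chrom", "start", "end", "name"]]),
              outdir / "states.bed", dialect="BED4")
    summary.to_frame().to_csv(outdir / "state_summary.tsv", sep="\t",
                              index=False, float_format="%.6g")

    report.to_frame().to_csv(outdir / "coexistence.tsv", sep="\t", index=False,
                             float_format="%.6g")
    (outdir / "coexistence.txt").write_text(report.text_block() + "\n")
    pd.DataFrame([folds]).T.rename(columns={0: "fold"}).rename_axis("state") \
        .to_csv(outdir / "sequential_folds.tsv", sep="\t",
                float_format="%.6g")

    # --- profiles & clustering --------------------------------------------
    groups = pc.assign_expression_groups(layout.gene_table)
    metagene = pc.metagene_profile(reads["wt_double"], layout.genes, groups)
    metagene.to_csv(outdir / "metagene_wt_double.tsv", sep="\t",
                    float_format="%.6g")

    anchors = layout.factor_sites
    mats = [pc.tag_density_matrix(reads[n], anchors, window=5000,
                                  bin_width=500, label=n)
            for n in ("wt_double", "k9_single", "k36_single")]
    k = min(config.kmeans_k, len(anchors))
    clusters = pc.kmeans_clusters(mats, k=k, seed=_derive_seed(seed, 40))
    cluster_df = pd.DataFrame({"anchor": mats[0].anchor_ids,
                               "cluster": clusters.labels})
    cluster_df.to_csv(outdir / "factor_site_clusters.tsv", sep="\t",
                      index=False)
    pc.export_cluster_genes(clusters, anchors, layout.genes,
                            outdir=outdir / "cluster_genes")

    # --- enrichment --------------------------------------------------------
    biv_peaks = states.bins.subset_peaks(
        states.mask(st.STATE_BIVALENT), label="bivalent_state")
    biv_merged = gmerge(biv_peaks)
    truth_segments = PeakSet(
        layout.regions.rename(columns={"state": "name"})[
            ["chrom", "start", "end", "name"]].copy(), label="truth_states")
    enrich = oe.segment_enrichment(biv_merged, truth_segments,
                                   sim.chrom_sizes, n_iter=100,
                                   seed=_derive_seed(seed, 50))
    enrich.to_csv(outdir / "segment_enrichment.tsv", sep="\t", index=False,
                  float_format="%.6g")

    frac = oe.fraction_sites_overlaid(layout.factor_sites,
                                      layout.state_peaks("bivalent"))
    pd.DataFrame([{"factor_sites": len(layout.factor_sites),
                   "fraction_overlaid": frac}]) \
        .to_csv(outdir / "factor_overlap.tsv", sep="\t", index=False,
                float_format="%.6g")

    logger.info("demo complete: verdict=%s, bivalent fraction %.3f, "
                "pull-down bivalent composition %s",
                report.verdict, states.fractions()["bivalent"],
                "n/a" if summary.composition is None
                else f"{summary.composition['bivalent']:.3f}")
    return PipelineResult(config, layout, states, summary, report, folds,
                          correlation, metagene, clusters, enrich, frac,
                          outdir)
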