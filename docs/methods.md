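# Methods

## The experiment being modeled

A double reading domain — two histone-modification reader modules fused in
one protein — precipitates mononucleosomes in a ChIP-like reaction. With an
AND-logic design, avid bivalent binding to a nucleosome carrying both
target marks (here H3K9me3 and H3K36me2/3) is much stronger than either
monovalent interaction, so under stringent washing the reagent enriches
doubly modified nucleosomes. Together with single-mark readers,
binding-pocket mutants and a sequential two-step pull-down, this
discriminates true per-nucleosome coexistence from mixtures in which
different molecules (alleles, cells, adjacent nucleosomes) each carry one
mark.

`duomark` implements the analysis layer of that experiment plus a
generative model of the data it produces.

## Generative model

**Genome layout.** Each chromosome is partitioned into regions with
exponential-ish lengths (minimum 6 kb, mean 20 kb). Regions receive one of
four states — unmarked, K9-only, K36-only, bivalent — by a
largest-remaining-quota rule over a random visiting order, so realized base
fractions land within about one region length of the configured targets
(default 0.55/0.15/0.15/0.15). Each region carries a lognormal occupancy
multiplier (σ = 0.5) modeling regional accessibility / MNase-efficiency
differences; it scales molecule numbers, hence coverage, but not mark
densities. Without this term all background bins would be statistically
identical, which no real coverage track is, and replicate rank correlations
would be artificially capped.

**Genes and expression.** One short gene (3–6 kb) is placed inside the
interior of each eligible region. Bivalent regions host lowly expressed
genes (two low tiers), K36-only regions host medium/highly expressed genes,
other regions host non-expressed genes with probability 0.4. RPKM values
are drawn per tier; the five-label grouping used downstream (no expression
set aside, then four rank quartiles) reproduces this structure.

**Mark configurations.** At 200-bp-spaced nucleosome positions (147-bp
footprints), molecules-per-position (default 100, occupancy-scaled) are
assigned per-molecule configurations {none, K9, K36, both}:

* single-mark regions: the mark with probability `mod_density` (0.25 —
  roughly the fraction of molecules in a marked region that carry the
  mark);
* K36 density over expressed gene bodies follows a linear 5′→3′ ramp from
  0.5× to 1.5× (mean exactly 1, so the regional mean density stays at
  `mod_density`);
* bivalent regions, by mode: **coexistence** — `both` with probability
  `mod_density`; **mixture** — exactly one of K9/K36 each with probability
  `mixture_phi × mod_density` (φ default 0.5), never both; **adjacent** —
  alternating positions purely K9- or K36-marked.

Single-mark regions are drawn from a mode-independent random stream, so
the three modes differ only inside bivalent regions.

**Readers and libraries.** A reader is a capture-probability table over
the four configurations. Defaults (0.8 both / 0.3 K9 / 0.01 K36 / 0.005
background) encode a stringent-wash regime: the K9 arm is functional alone
(~100 nM-scale affinity), the K36 arm essentially is not (~100 µM scale),
and bivalent engagement is strongest. These are free parameters, not
fitted values — only affinity ranges and qualitative blot behavior
constrain them. A pull-down captures each molecule binomially by its
configuration's probability, then sequences the captured pool with
replacement to the requested depth (duplicates allowed; no PCR model);
reads are fixed 147-bp footprints (fragment-length jitter available, off by
default since libraries are gel-selected below 200 bp). The sequential
pull-down applies the second reader's table to the first reader's captured
pool. The input samples all molecules uniformly.

**What the generator does not model:** sequencing errors, mappability, GC
bias, diploid phasing, fragment-boundary noise from digestion, or
inter-mark correlation structure beyond the regional states. Passing tests
therefore validate the analysis logic under idealized sampling, not
robustness to alignment artifacts.

## Analysis pipeline

**Quantification.** Fixed-width tiling (3-kb analysis bins, 10-kb
correlation bins); midpoint read assignment (each read counted exactly
once; overlap-weighted assignment available); reads-per-million
normalization, optionally on a common scale set by the largest library.
Per-bin **enrichment over input** (RPM ratio with a pseudocount of 1% of
mean input RPM) is used for all presence calls and the coexistence ratio:
dividing by input cancels the regional coverage term, which otherwise
dominates between-bin variance (bins within a region share occupancy, so
the effective sample size would collapse to the number of regions). The
pseudocount is kept small because a large one re-introduces a
coverage-dependent multiplicative distortion.

**Evidence tracks.** K9 presence is called on the mean of the single-K9
reader and K36-pocket-dead double-reader enrichment tracks; K36 presence
on the mean of two K36 single-reader replicates — mirroring the emulated
study design, where replicate libraries exist and K9 evidence was merged
across reagents.

**Thresholds.** Presence cutoffs are explicit, logged `ThresholdSpec`
objects. Two distinct questions get two rules:

* *mark presence* (state definition): `median + 5·1.4826·MAD` — a
  background-referenced cutoff that calls anything clearly above the
  unmarked level. Critically, it is robust to the mark's density: dual
  regions under the mixture hypothesis carry each mark at half density and
  must still be called present, otherwise the single-mark maps would
  trivially "distinguish" the hypotheses and the four-state comparison
  would be vacuous. Assumes marked bins are a minority (median in the
  background component).
* *pull-down positivity* (composition/recovery): `mean + 1·SD` of nonzero
  bins (`stringent` preset: +2 SD) — distribution-referenced, so only the
  strongest enrichment counts.

Truncated end-of-chromosome bins are excluded from cutoff estimation but
classified normally.

**Four-state map and summaries.** (K9, K36) presence → {neither, K36-only,
K9-only, bivalent}; composition and per-state recovery of any pull-down
follow by counting. Δ-statistics (set mean minus genome-wide mean) are
reported for signal-by-state displays.

**Coexistence test.** The per-mark ratio uses the *unmarked-state baseline*
(mean over neither-state bins), not the genome-wide mean: with the genome
mean, the marked regions' own signal enters the baseline and the ratio no
longer converges to φ (at the default state mix a φ = 0.5 mixture would
read ≈ 0.35). With the unmarked baseline the expectation is exactly φ by
linearity, which is the analytic oracle the tests use
(`mixture_expectation`). Compared bin sets are restricted to state-run
interior bins: bins straddling a region boundary mix two states and bias
set means by a layout-dependent amount. Uncertainty comes from a
stratified bin-level bootstrap (bins are the exchangeable unit; default
500–1000 resamples). The verdict margins ε = 0.05 and δ = 0.25 separate
the two hypotheses with a buffer zone; both are configurable and echoed in
the report, and the report labels the verdict rule as this package's own
formalization — the original comparison was made without a significance
procedure.

**Sequential folds.** fold(state) = library-normalized sequential read
density over the state's bins divided by the input density. Because few
molecules survive two captures and are then resequenced, reads are heavily
clustered and the effective sample size is the number of surviving
molecules, not reads; `sequential_fold_bootstrap` therefore resamples bins
to get honest errors.

**Profiles and clustering.** Metagene profiles rescale bodies to a fixed
bin count with fixed-width flanks, orient minus-strand genes 5′→3′, and
average RPKM-style densities per expression group. Tag-density matrices
count read midpoints in fixed windows around anchor midpoints (NaN padding
at chromosome edges, zero-filled before clustering). Clustering is
scikit-learn k-means (k-means++, Lloyd) with a mandatory seed and rows
ordered by cluster then mean signal; distances are Euclidean on
untransformed densities with an optional per-row max normalization.
Anchors link to the nearest TSS at ≥ 10 kb for per-cluster gene-list
export.

**Enrichment.** Peak shuffling preserves count, lengths and chromosome,
placing each peak uniformly (no exclusion zones; optional non-overlap
constraint off by default). Segment enrichment measures overlap in bases
by default (peak-count mode available) against the shuffle null, with
empirical p = (1 + #null ≥ obs)/(n + 1).

## Problem sizes and defaults

The default study conditions are a 2 × 4 Mb genome, 400 k reads per
pull-down library, 1.2 M input reads, 3-kb bins. These sizes were chosen so
that the coexistence ratio estimator's run-to-run SD (≈ 0.01) cleanly
resolves the ε = 0.05 verdict margin — the limiting variance term (bin-level
density structure from the gene gradient) scales with the number of bins,
not with depth — while a full pipeline run stays in single-digit seconds.
Repeated-run statistical checks use 100 seeded runs at these conditions;
bootstrap sizes are 200–1000 depending on context.

## Degenerate inputs and numerical choices

Empty pull-down pools raise with a suggestion to raise background; zero
library sizes, all-equal percentile tracks, unknown shuffle chromosomes and
over-long peaks raise explicit errors. Constant tracks yield missing (NaN)
Spearman values, never 0. Zero pull-down positives yield an undefined
(None) composition. Coexistence verdicts degrade to `indeterminate` with a
reason when any compared set has < 20 bins, net signal is non-positive, or
the bootstrap degenerates. Ties in k-means assignment are resolved by
scikit-learn's deterministic seeded implementation; RPKM ties in
expression grouping break by transcript id (logged). All interval
arithmetic is 0-based half-open; bookended intervals merge at gap 0.

## Known limitations

* The capture table is a stand-in, not a fitted model; absolute recoveries
  and compositions shift with it, though the qualitative AND-logic pattern
  is robust across reasonable tables.
* The mark-presence cutoff assumes < 50% of bins are marked; layouts
  dominated by one marked state need a fixed or percentile threshold.
* The broad-domain caller is deliberately minimal (threshold + gap-merge +
  length filter) and is not a substitute for a statistical peak caller on
  real data; real-data users supply external peaks as BED.
* Verdict margins were chosen to separate φ = 1 from φ = 0.5 with a buffer;
  mixtures with φ close to 1 (minor contaminating fractions) fall in the
  indeterminate band by design.
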