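# Methods

## Coverage model

Aligned reads (BED6, strand required) are extended to the expected fragment
length — default 150 bp — toward the interior of the sequenced fragment:
`[start, start+150)` on `+`, `[end−150, end)` on `−`, clipped to the
chromosome; reads already at least that long pass through unchanged.
Per-base fragment depth is computed exactly (difference array + cumulative
sum), averaged within fixed 20 bp bins (partial bins by proportional
per-base averaging, so the track equals a per-base oracle to float
precision), and scaled by `1e6 / total_mapped_reads` times an optional
spike-in factor. The conservation identity
`Σ(bin value × bin width) = scale × Σ(fragment lengths)` holds for every
track and is property-tested.

Normalization is depth-based (per million mapped reads). Division by an
input-chromatin track is not folded into the coverage step; where a
ratio is wanted it is explicit via `normalized_occupancy`, which computes
bin-wise `(factor + ε) / (polII + ε)` with ε = 0.1 by default (recorded in
the track metadata). The spike-in factor is `reference_spike_reads /
sample_spike_reads`, i.e. samples are scaled to a common exogenous-chromatin
depth; the direction is configurable.

## Windows and per-gene statistics

All coordinates are 0-based half-open; gene TSS/TES anchors are
strand-aware. Window densities are length-weighted means of bin values
(fractional window bounds supported — needed for percent-scaled body bins).

- Traveling ratio: a = [TSS−30, TSS+300), b = [TSS+300, TES). The
  promoter-proximal extent (~300 bp) reflects where engaged polymerase
  pauses downstream of the TSS; the bounds are configuration, not claims
  about any particular dataset.
- 3′ pausing index: c = [TES, TES+4 kb) against the same b; 4 kb matches
  the profiling flank.
- ε = 0.01 per-bp pseudocount keeps ratios finite on sparse tracks; at
  ε = 0 both ratios are exactly scale-invariant (tested to 1e-12). Genes
  whose body window is empty (length ≤ 300 bp) are skipped with a logged
  reason.
- Average signal for tiering: mean density over [TSS−4 kb, TES+4 kb],
  clipped at chromosome ends.

Tier assignment ranks genes descending by average signal (ties broken by
gene id, stable) and cuts at `ceil(0.30·N)` and `ceil(0.50·N)`. The ceil
rule is the one consistent with all three published partitions
(515→155/103/257, 1994→599/398/997, 680→204/136/340); a floor rule gives
154 for N = 515 and was rejected.

Condition comparisons use the two-sided Mann–Whitney U (exact null when
sample sizes permit and no ties; tie-corrected normal approximation
otherwise), with a permutation test on medians available as a cross-check.

## Metagene profiles

Each gene contributes 200 upstream 20 bp bins (−4 kb → TSS), 100
equal-length body bins (percent of gene length; genes shorter than the bin
count are rejected) and 200 downstream bins (TES → +4 kb), oriented 5′→3′
so index 0 is always −4 kb of the biological TSS. Flank bins beyond a
chromosome end are missing (NaN), not zero — zero-filling would bias the
averaged profile downward at the edges; aggregation is column-wise
nan-mean (median optional). The body bin count of 100 is a resolution
choice exposed in the API. Genes are pre-filtered to those at least 4 kb
(closest-edge gap) from every other annotation, so flanks measure the
gene's own signal; the annotation universe is the gene set itself plus any
extra annotation intervals supplied.

## Chromatin states and DE integration

Mark presence is a ≥1 bp overlap between a called peak and the gene's
window: H3K4me3 ±2 kb of TSS, H3K79me2 the first 5 kb of the body in
transcription direction, H3K27me3 ±5 kb of TSS. The default rule table
follows the standard bivalent-domain definition (bivalent = K4 ∧ K27;
active = (K4 ∨ K79) ∧ ¬K27; silent = K27-only or unmarked) and is
replaceable by any total mapping over the eight flag triples — changing the
table relabels states but never changes the flags.

DE filtering takes |fold change| ≥ 1.5, p ≤ 0.05, FDR ≤ 0.1 by default
(boundary equality included); two alternative named presets
(fold ≥ 1.5 / p ≤ 0.1 / FDR ≤ 0.05 and fold ≥ 2 / FDR ≤ 0.05) are provided
because published threshold conventions differ between summaries and
methods sections. Up and down sets are disjoint by construction.

## Peak annotation

Feature precedence is promoter > 3′ > exon > intron > intergenic. Promoter
and 3′ tests use the peak anchor (summit when available, else midpoint)
within 1 kb of the nearest TSS/TES; exon and intron require overlap of the
peak interval with an exon or gene body. Distances to the TSS are signed in
transcription direction (negative upstream). Ties between equally near
genes break by distance then gene id, so annotations are independent of
gene input order. A gene is "bound" when at least one peak annotates as its
promoter; adding intergenic peaks never changes the bound set.

## Synthetic data

The generator plants a four-component mixture over fragment 5′ ends per
gene: promoter Normal(TSS+μ_p, σ_p) with μ_p = 50 bp, σ_p = 60 bp; body
Uniform[TSS+300, TES); terminal Normal(TES, σ_t) with σ_t = 300 bp;
background Uniform over the chromosome with random strand. Read counts are
Poisson with mean `expression` (default 500 reads/gene, i.e. 10⁵ reads for
a 200-gene cohort); reads are 36 bp at the 5′ end, on the gene strand for
gene components. Control mixture weights are (π_p, π_b, π_t, π_bg) =
(0.40, 0.45, 0.10, 0.05) — a moderately paused gene with a strong body
plateau; the depleted condition multiplies (π_p, π_b) by (1.75, 0.50) and
renormalizes, emulating promoter accumulation with body depletion after
loss of a pause-release factor. The simulated genome places genes ≥ 25 kb
apart (alternating strands, two chromosomes), which keeps every mark window
and profiling flank clear of neighbours.

The analytic body plateau (per-bp normalized depth
`expression·π_b/(L−300) × 150 × 10⁶/total`) is exposed and the simulation
converges to it within 10% at high depth (tested). Mark peaks are
constructed as the inverse of the classification rule and round-trip
exactly; DE tables plant |log2fc| ≥ log2(fold) with p ≤ 10⁻⁶ on selected
genes and sub-threshold fold changes on nulls, with a Benjamini–Hochberg
FDR column, so the default filter recovers planted sets exactly.

What the generator does **not** emulate: fragment-size distributions (5′
ends only, extension recreates plateaus), mappability and GC bias, genes
closer than the isolation distance, overdispersed (negative-binomial)
counts, and input-chromatin structure. Passing tests therefore demonstrate
correctness of the measurement pipeline and sensitivity under the planted
model, not robustness to those real-data artifacts.

## Problem sizes and determinism

Validation experiments use 200-gene cohorts at ~10⁵ reads per condition —
large enough that the TR separation between promoter weights 0.8 and 0.2 is
essentially deterministic (the pooled Spearman reaches its binary-predictor
ceiling of √3/2 ≈ 0.866 in every replicate) while keeping a 50-replicate
run under a minute. All randomness flows through explicit
`numpy.random.default_rng` seeds; identical seeds reproduce identical read
sets, and the demo pipeline's outputs are byte-identical across runs with
the same configuration (each output carries the configuration hash in its
header).

## Known limitations

Coverage holds per-chromosome per-base arrays during computation, which is
fine for simulated or focused genomes but would need a streaming
implementation for mammalian-scale chromosomes at full depth. BAM input,
peak calling, duplicate marking and DE model fitting are upstream of this
package by design — it consumes BED-like intervals and finished DE tables.
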