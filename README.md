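# polpause

Analysis of RNA polymerase II promoter-proximal pausing from ChIP-seq
occupancy. The package turns aligned-read intervals into normalized
coverage tracks and derives the standard quantitative readouts of the
transcription cycle: metagene occupancy profiles, the traveling ratio, the
3′ pausing index, signal-based confidence tiers, chromatin-state calls from
histone-mark peaks, and peak-to-gene integration — together with a
synthetic-data generator with planted ground truth, so every stage is
validated end to end without external downloads.

## Who it is for

Workers studying Pol II pause release and elongation (e.g. after depleting
a CTD phosphatase or pausing factor) who have aligned ChIP-seq reads
(BED6), gene annotations (BED6/BED12/GTF) and peak calls, and want
reproducible per-gene pausing statistics and profile matrices rather than
one-off plotting-tool runs.

## The quantities

For a gene with transcription start site (TSS) and end site (TES) and a
coverage track *c* (reads extended to 150 bp, binned at 20 bp, scaled per
million mapped reads, optionally by an exogenous spike-in factor):

- **Traveling ratio (TR)** = (d(a) + ε) / (d(b) + ε), where d(·) is mean
  per-bp density, a = [TSS−30, TSS+300) is the promoter-proximal window and
  b = [TSS+300, TES) the gene body. TR ≫ 1 means polymerase accumulates at
  the promoter instead of elongating; pausing defects raise TR.
- **3′ pausing index (PI3)** = (d(c) + ε) / (d(b) + ε) with
  c = [TES, TES+4 kb); elevated PI3 indicates polymerase retention past the
  TES (termination/3′-processing delay).
- **Metagene profile**: per-gene signal vectors over 200 × 20 bp upstream
  bins, 100 percent-of-gene-length body bins and 200 downstream bins,
  strand-oriented and averaged over genes ≥ 4 kb from any other annotation.
- **Confidence tiers**: genes ranked by average signal over
  [TSS−4 kb, TES+4 kb] and cut at the top 30% (high) and 50%
  (intermediate); a ranked set of 515 genes splits 155/103/257.
- **Chromatin state**: active / bivalent / silent from H3K4me3 (±2 kb of
  TSS), H3K79me2 (first 5 kb of the body) and H3K27me3 (±5 kb of TSS) peak
  presence; bivalent = K4 ∧ K27, active = (K4 ∨ K79) ∧ ¬K27, silent
  otherwise.

## Worked example

The numbered drivers under `analysis/` run the whole study on simulated
data (200 well-separated genes, ~1×10⁵ reads per condition; the "depleted"
condition reweights the read mixture toward the promoter and away from the
gene body):

```sh
python analysis/01_simulate_data.py
python analysis/02_coverage_tracks.py
python analysis/03_metagene_profiles.py
python analysis/04_pausing_metrics.py
python analysis/05_chromatin_states.py
python analysis/06_peak_annotation.py
```

Output of step 04 (seed 1):

```
control: median TR 14.48, median PI3 0.21, tiers {'low': 100, 'high': 60, 'intermediate': 40}
depleted: median TR 42.52, median PI3 0.37, tiers {'low': 100, 'high': 60, 'intermediate': 40}
TR shift (depleted vs control): p = 1.55e-55, medians 42.52 vs 14.48 (a>b)
PI3 shift (depleted vs control): p = 1.91e-25, medians 0.37 vs 0.21 (a>b)
```

The depleted condition's median TR nearly triples (42.5 vs 14.5; two-sided
Mann–Whitney p ≈ 10⁻⁵⁵ over 200 genes), i.e. the planted pause-release
defect is recovered, and step 03 shows the corresponding metagene change: a
1.54× higher TSS-proximal mean with the body plateau halved (0.48×). Step
05 recovers 100% of the planted chromatin states and step 06 annotates
83.3% of the constructed peaks as promoters, excluding all intergenic
decoys from the bound-gene set.

The same stages are available as a CLI for arbitrary inputs:

```sh
polpause simulate --out data --seed 1
polpause coverage --reads data/reads_control.bed --chrom-sizes data/chrom.sizes --out cov.bedgraph
polpause pausing --track cov.bedgraph --genes data/genes.bed --chrom-sizes data/chrom.sizes --out metrics.tsv
polpause demo --out report --seed 1     # everything end to end
```

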