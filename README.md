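# chipscape

Integrative analysis of two-condition ChIP-seq peak landscapes, built for
the kind of question that arises when a chromatin factor redistributes
between cell states: in naïve (2i/LIF) mouse embryonic stem cells a factor
may bind mostly at promoters, while in the primed (serum/LIF) state it
additionally occupies distal enhancer elements near the same target genes.
`chipscape` takes peak calls (BED), a TSS annotation (GTF or TSV) and
coverage tracks (bedGraph) and answers, reproducibly:

* which peaks are **TSS-proximal** (nearest-bp distance to a TSS ≤ 1 kb,
  inclusive) and which are **distal**, with the nearest gene for every peak;
* how two conditions' peak sets relate — shared vs condition-specific peaks
  (minimum overlap 1 bp) and the overlap of their nearest-gene sets;
* what the signal looks like: depth-adjusted (counts-per-million),
  input-normalised log2(IP/input) matrices over 10 kb windows centred at
  peak summits/midpoints, average profiles, heatmaps, and Pearson
  correlations of per-peak occupancy between factors;
* which distal peaks are **active** (H3K27ac-high) vs **poised**
  (H3K27ac-low) enhancers, split by k-means (k = 2) on per-peak
  acetylation signal;
* whether factor pairs **co-occupy** distal sites: each universe peak is
  marked 0/1 per factor (gap tolerance 200 bp) and the doubly-marked count
  k is tested against a one-sided hypergeometric null,
  P[X ≥ k], X ~ Hypergeom(N, K, n), with Benjamini–Hochberg FDR across
  the tested pairs.

A synthetic-data module generates complete toy landscapes — genome, genes,
two-condition peak sets with planted redistribution, bimodal H3K27ac
states, planted co-occupancy, Poisson-noise coverage — with exact ground
truth, so the whole pipeline is testable end to end without sequencing
data.

## Worked example

Generate a synthetic landscape and run the full pipeline:

```sh
chipscape simulate --seed 1 --outdir demo/bundle
chipscape run --config demo/pipeline.yaml --seed 1 --outdir demo/out
```

with `demo/pipeline.yaml` pointing at the bundle files (see
`scripts/acceptance.py` for a complete config). The run writes per-stage
TSV/JSON plus `report.json`; on the default landscape (seed 1) the
headline numbers are:

```
naive   : 1000 peaks, 700 TSS-proximal (70.0%), 300 distal
primed  : 2700 peaks; 1700 primed-specific, 100% of them distal
genes   : 100% of target genes shared between conditions
enhancers: 2000 distal peaks -> 1700 H3K27ac-low (85.0%), 300 high
cooccupancy (distal H3K27ac-high universe, max gap 200 bp):
  med1/p300, med1/oct4, med1/smc1a all q <= 2.9e-12
```

Read: the primed condition gained distal (enhancer) peaks near the genes
already bound in the naïve condition; most of those enhancers carry little
H3K27ac (poised); and the planted mediator/coactivator/cohesin pairs are
recovered as significantly co-occupying. These fractions are planted by
the generator (70% proximal, 85% low) and recovered by the analysis, not
assumed by it.

Every subcommand is also available on its own (`classify`, `compare`,
`matrix`, `enhancers`, `cooccupancy`), and the same functionality is
importable:

```python
from chipscape import read_bed, read_tss, TSSIndex, classify_peaks

tss = TSSIndex(read_tss("tss.tsv"))
for c in classify_peaks(read_bed("peaks.bed"), tss, tss_threshold=1000):
    print(c.peak.id, c.klass, c.distance_to_tss, c.nearest_gene)
```

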