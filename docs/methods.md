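# Methods

## Coordinate conventions

All internal coordinates are 0-based half-open; GTF input (1-based
inclusive) is converted on read: a '+'-strand gene's TSS is `start − 1`, a
'−'-strand gene's is `end − 1`. Chromosome names are exact strings; an
optional rename map can be applied at read time, because silent coercion
("1" vs "chr1") is a classic source of false non-overlap. Peaks on
chromosomes absent from the annotation are kept and classified distal with
distance +∞ (logged), never dropped.

## TSS-proximal vs distal classification

The distance from a peak to a TSS is the nearest-bp distance: 0 when the
TSS position lies within the peak (including its last base), otherwise the
distance from the closer edge. "Within 1 kb" is inclusive (≤ 1000 bp) and
strand-ignored. This edge-based convention is the most conservative
reading of "peaks located within 1 kb of a TSS"; summit-based distance is
available (`use_summit=True`) for sensitivity analysis. Nearest-gene ties
break deterministically: lower TSS coordinate first, then lexicographic
gene id. Increasing the threshold can only move peaks from distal to
proximal (tested as a monotonicity property).

## Condition comparison

Peak sets are compared un-merged — each peak is a unit — with a peak of A
"shared" when it overlaps at least one peak of B by ≥ `min_overlap` bp
(default 1). Half-open arithmetic means book-ended peaks do not overlap.
Gene-level overlap intersects the nearest-gene label sets of the two
conditions. The redistribution readout is the fraction of
condition-specific peaks classified distal.

## Gap-tolerant overlap

Two intervals are co-located under `max_gap` when they overlap by ≥ 1 bp
or are separated by at most `max_gap` bp. The gap between book-ended
intervals is 0, so with `max_gap = 0` book-ended peaks are co-located
(the same convention as `bedtools merge -d 0`); with `min_overlap`
semantics they are not. Set-level queries use a per-chromosome interval
tree over one set, widened by `max_gap + 1`, with exact post-filtering —
the tree query alone cannot express a minimum-overlap requirement for
contained intervals.

## Signal normalisation and matrices

Each track is depth-adjusted to counts-per-million (every run value scaled
by 1e6 / total signal; idempotent). IP and matched input are binned over
the same windows and enrichment is the bin-wise
`log2((ip + c) / (input + c))` with pseudocount `c = 1.0` (configurable).
The order — depth-adjust both, bin both, then ratio — is the package's
recorded choice among the standard variants; subtraction instead of ratio
was considered and rejected because the log-ratio is scale-free under
depth adjustment.

Windows are 10 kb centred at the peak anchor (narrowPeak summit when
called, otherwise the midpoint ⌊(start+end)/2⌋), at 50 bp bins (200 bins);
10 kb is the analysis window, 50 bp a conventional heatmap resolution that
keeps matrices small. Window spans before position 0 or past the end of
the covered genome contribute value 0 (rows stay rectangular; affected
rows are flagged in `clipped_rows`). Bins integrate the run-length track
exactly via a cumulative integral, so for a track wholly inside the window
the bin sums times bin size reproduce the track integral to ~1e-6 relative
(mass conservation) and shifting the signal by whole bins shifts the row
by the same number of columns (shift covariance); both are tested.

Per-peak occupancy summaries (mean density over the peak interval itself)
feed Pearson correlation between factors; a zero-variance vector yields
NaN entries flagged missing, never a silent 0.

## Enhancer-state calling

Distal peaks are split into H3K27ac-high (active) and -low (poised)
classes by k-means with k = 2 on the per-peak log2(IP/input) summary.
"Low or no" acetylation is one class by design. k-means uses k-means++
initialisation with 10 restarts and a fixed seed (1-D k = 2 is nearly
convex; restarts make the global optimum essentially certain and the seed
makes runs reproducible); centroids are returned sorted so label 0 is
always the low cluster. Fewer distinct values than clusters raises a
degenerate-input error rather than returning an arbitrary split. Heatmap
rows are ordered high-cluster-first, descending signal, with a stable sort
so tied rows keep their input order.

## Co-occupancy enrichment

The statistical population is a reference peak set (default: the
H3K27ac-high distal peaks of the main factor; `distal_all` and
`distal_low` are configurable, and the choice is recorded in the output
metadata). Each universe peak is marked 0/1 by each factor under the
200 bp gap rule — a universe peak counts once however many factor peaks
hit it, as sampling without replacement requires. For a pair (A, B) with
N universe peaks, K marked by A, n marked by B and k marked by both, the
p-value is the one-sided upper tail P[X ≥ k], X ~ Hypergeom(N, K, n);
depletion (lower tail) is exposed as an option. Benjamini–Hochberg FDR is
applied across the requested pair list.

The upper tail is computed in exact rational arithmetic (big-integer
binomials) for N ≤ 10,000 and by log-space summation of pmf terms
(logsumexp) above, so deep tails retain full relative precision; both
routes are tested against an independent rational-precision oracle, and
the log route agrees to better than 1e-10 relative at N = 1000 across the
entire support.

## Synthetic landscapes

The generator emulates the statistical structure of a naïve-to-primed
ESC priming experiment, not its sequence content. Defaults (the study
conditions, scaled to desk size):

| parameter | default | meaning |
|---|---|---|
| chrom_sizes | chr1 12 Mb, chr2 8 Mb | toy genome |
| n_genes | 200 | TSS, uniform with ≥ 20 kb spacing, alternating strands |
| n_peaks_a / n_peaks_b | 1000 / 2700 | naïve / primed main-factor peaks (primed ⊇ naïve, ~2.7× — the primed state gains peaks) |
| frac_tss_a | 0.70 | naïve peaks placed within 1 kb of a TSS (exact count) |
| frac_shared_genes | 0.80 | extra primed distal peaks placed 5.5–50 kb from genes already targeted in the naïve state |
| frac_low_h3k27ac | 0.85 | poised fraction among primed distal peaks (exact count) |
| cooccupancy_probs | jmjd2c→med1, med1→{p300, oct4, smc1a}, each 0.6 | chained partner planting at a fixed 150 bp gap |
| background_rate | 0.01 / bp | Poisson coverage background (mean 0.5 per 50 bp step) |
| peak_height / peak_width | 10.0 / 1000 bp | triangular signal bump; low-state bumps get height/10 |

Design choices:

* **Exact planted counts.** Class proportions are `round(p × n)` by
  construction, not Bernoulli draws, so recovery tolerances measure the
  pipeline rather than generator sampling noise.
* **Unambiguous planted classes.** Distal peaks keep ≥ 5 kb edge distance
  from every TSS (no boundary disputes under the 1 kb rule) and ≥ 2
  bump-widths between distal centres, so no peak's acetylation signal
  bleeds into a neighbour's — peak callers emit disjoint peaks, so
  colliding planted peaks would also be unrealistic.
* **Detectable planted co-occupancy.** Partners sit at a fixed 150 bp gap,
  inside the 200 bp analysis gap; the margin exercises the gap rule.
  Chained partners (p300 planted near med1, which was planted near the
  main factor) are placed on the side of their source facing the original
  site, so co-occupied factors cluster at the same enhancer the way
  coactivator complexes do.
* **TSS placement** uses the exact uniform-with-minimum-spacing
  construction (sorted uniforms in a shrunk domain plus i·spacing) rather
  than whole-set rejection, whose acceptance probability vanishes at the
  default gene density.
* **Seeding.** One global seed expands into per-stage substreams by stable
  hashing (CRC-32) of stage names, so adding a stage never perturbs
  earlier streams; all outputs are pure functions of (config, seed).

What the generator does **not** emulate: read-level data (fragment
lengths, GC bias, duplicates, mappability), realistic peak-width and
height distributions, chromatin-domain correlation structure, or
inter-replicate variability. Passing tests therefore demonstrate that the
analysis recovers planted structure under idealised noise — they say
nothing about upstream alignment/peak-calling quality on real libraries,
and tolerance choices (e.g. ±0.03 on recovered fractions) are meaningful
only relative to this noise model.

## Pipeline

`run_pipeline` executes classify → compare → matrices → enhancer calling →
co-occupancy from a single declarative YAML config; only `--seed` and
`--outdir` can override it, so the config snapshot fully determines a run.
Stages log peak counts after every filter (interval pipelines fail
silently without count audits), write their tables before the next stage
starts, and abort with the stage name on error. All tabular outputs are
byte-reproducible for a fixed (config, seed); PNG heatmaps/profiles are
advisory, and per-stage wall-clock goes to a separate `timings.json` so
`report.json` itself stays deterministic.

Problem sizes in the shipped tests and acceptance script (20 Mb genome,
≤ 2700 peaks per set, 500-peak universes, 1000 null simulations, 100
power landscapes) were chosen so the complete suite runs in about a
minute while keeping every statistical check at sufficient resolution;
the pipeline itself is linear in genome size and peak count.

## Known limitations

* `nearest_tss` and classification consider TSS points only, not gene
  bodies; "promoter" regions defined by CpG islands or H3K4me3 are out of
  scope, as is enhancer–gene assignment by 3D contact.
* The hypergeometric universe must be chosen by the analyst; different
  universes answer different questions, which is why the choice is
  embedded in the output metadata.
* Coverage I/O is bedGraph (optionally gzipped); BAM/bigWig handling is
  out of scope (bigWig reading can be wrapped externally if needed).
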