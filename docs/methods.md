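# Methods

## The super-enhancer model

`sepipe` implements the rank-ordering approach to super-enhancer (SE)
discovery from H3K27ac ChIP-seq peaks. The model's assumptions are the
standard ones: H3K27ac peak signal is a proxy for enhancer activity; active
enhancers cluster in the genome; and a small number of clustered regions
carry disproportionately high aggregate signal and behave qualitatively
differently (super-enhancers) from the bulk of isolated typical enhancers.

The call proceeds in four steps:

1. **TSS exclusion.** Peaks lying entirely inside a window of ±`r` bases
   around any transcription start site are removed (default `r = 2000`).
   The window is `[tss − r, tss + r + 1)` in half-open coordinates, so both
   edge bases are covered; a peak is removed only when fully contained.
   Promoter-proximal H3K27ac marks promoter activity, not enhancers.
2. **Stitching.** Surviving peaks separated by at most `g` bases are merged
   into one candidate enhancer (default `g = 12500`, inclusive). Stitching
   is exactly the connected components of the graph joining peaks with gap
   ≤ `g`; because intervals are one-dimensional a single left-to-right
   sweep per chromosome computes it.
3. **Ranking.** Stitched enhancers are scored by the sum of their member
   peak signals (narrowPeak signalValue; the display-clamped BED score is
   never used). Alternatively a bedGraph track can be supplied, in which
   case the score is the area under the track across the stitched span.
   Enhancers are sorted ascending and both rank and score are min-max
   scaled to [0, 1], giving the familiar hockey-stick curve.
4. **Slope-1 tangent cutoff.** The tangency point of the scaled curve with
   a slope-1 line is the point minimizing `scaled_y − scaled_x`: the line
   of slope 1 through it supports the curve from below. Enhancers with
   signal strictly above the tangency point's signal are super-enhancers;
   the tangency enhancer itself is typical. Exact ties in the minimum are
   resolved toward the point with the greatest `scaled_y`, i.e. toward
   fewer super-enhancers — on a perfectly diagonal (degenerate) curve
   nothing is called.

Degenerate inputs are handled explicitly: an empty post-filter peak set, a
flat curve (all signals equal, no min-max scale) or fewer than
`min_points_for_cutoff` (default 3) enhancers produce a no-SE result with a
warning rather than an arbitrary cutoff.

Signal scale never matters: the call is invariant under multiplying every
peak signal by a positive constant (min-max scaling and ranking see only
relative order and proportions), and under permuting the input peak order
(all sorting is explicit with deterministic tie-breaks).

## Peak annotation

Each peak is represented by a single point — its summit when the
narrowPeak record carries one, otherwise its midpoint — and assigned exactly
one feature class with precedence promoter > exon > intron > distal
intergenic. The promoter window reuses the ±2 kb TSS radius for consistency
with the SE exclusion step; both are configurable. Point-based
classification keeps the classes exhaustive and mutually exclusive without
fractional assignments, matching the summit mode of common annotators.

Nearest-gene assignment minimizes |TSS − midpoint| with ties broken by
lexicographic gene id; the reported distance is signed (`TSS − midpoint`).
When a gene attracts several peaks, the highest-signal peak within
±100 kb of its TSS is kept (ties to the leftmost start).

## Differential analysis

**Peaks.** The two conditions' peak sets are merged into consensus regions
(union, merged where overlapping), each region is scored per condition by
summed peak signal, and tested with the exact conditional binomial test:
given the pooled (rounded) count `n = k_a + k_b`, under the null `k_b` is
binomial with success probability `lib_b / (lib_a + lib_b)`. The fold
change is library-normalized with a symmetric pseudocount of 1:
`log2FC = log2(((k_b + 1)/lib_b) / ((k_a + 1)/lib_a))`, computed as a
difference of two logarithms so that swapping the conditions negates it
bit-exactly. Calls use strict thresholds exactly as printed: up/down iff
`|log2FC| > 1` **and** `p < 0.05`; a region at exactly 1.0 is never called.
The binomial test is discrete and therefore conservative: under an
equal-rate Poisson null its empirical size at nominal 0.05 is ~0.04
(verified by simulation in the acceptance suite). No multiple-testing
correction is applied to the calls (an optional BH column can be derived
downstream); the thresholds are raw-P gates.

**Expression.** Genes are compared by FPKM
(`count × 10⁹ / (library_size × gene_length)`). Fold change is
`(mean_b + 1)/(mean_a + 1)`; significance comes from a two-sided Welch
t-test on `log2(FPKM + 1)` across replicates when both groups have ≥ 2
replicates (otherwise p is set to 1 with a warning). A gene is called at
fold change > 2 (or < 1/2) and p < 0.05, again strict. Welch's test with 3
replicates per group is conservative — its true size on normal data is
≈ 0.037, not 0.05 (Monte-Carlo, 10,000 null genes) — which is the expected
behaviour of the Satterthwaite approximation at tiny n and is asserted as
such in the tests. Externally produced differential-expression tables
(e.g. from a count-model fit) are accepted as a drop-in replacement via
`--de-table`.

## Integration

Differential SEs are joined to genes in four steps: (1) each SE region is
assigned the gene whose TSS is nearest its midpoint, within a ±100 kb
window (configurable); (2) when several SEs map to one gene only the
highest-signal one is kept; (3) the SE must pass a directional linear
fold-change gate (`se_fc_min`, default 1.0 — i.e. any significantly called
SE passes; a printed threshold of "≥ 1" is vacuous on the linear scale, so
the gate is exposed as a parameter rather than silently reinterpreted) and
the gene's expression must change by at least `rna_fc_min` (default 1.2)
in some direction; (4) by default only direction-concordant pairs are
kept. The expression screen at 1.2 is deliberately looser than the
fold-change-2 DE call and is applied to the full expression table without
a second p-gate: the stringent gate belongs to the DE step, the 1.2 screen
to the integration step. Genes absent from the expression table and SEs on
gene-free chromosomes or beyond the window are reported in side lists, not
silently dropped.

## Synthetic data generator

The generator emulates the statistical structure of a two-condition
H3K27ac + RNA-seq study on a small genome so every stage is testable
without any external data. Per chromosome it places, in order:

- **super-enhancer clusters** — runs of 3–8 peaks with intra-cluster gaps
  drawn from 500–11,000 bp (always within the 12.5 kb stitch rule) and
  signals multiplied by 5 over background;
- **typical enhancers** — isolated single peaks (typical enhancers are
  short single elements, 50–1500 bp; only SEs are multi-peak clusters);
- **genes** — non-overlapping spans (2–20 kb, 1–4 exons, random strand)
  kept ≥ 2.5 kb clear of planted clusters so no TSS window can swallow a
  planted peak; the default of 3000 genes over a 4 × 25 Mb genome gives a
  TSS every ~33 kb, the gene-dense surroundings real SE neighbourhoods
  have, and guarantees nearest genes exist within the 100 kb integration
  window;
- **background peaks** — log-normal signals (median 50), a configurable
  fraction planted fully inside TSS ± 2 kb windows (these are removed by
  the TSS filter, exercising it). Background peaks are placed isolated,
  > 13 kb from clusters and from each other: any two background peaks
  within stitch range would form an *unlabelled* multi-peak cluster, which
  would make the planted ground truth ambiguous rather than the call
  wrong.

Condition b equals condition a except that a chosen subset of super
clusters (default 8, split 4 up / 4 down) has its member signals multiplied
or divided by the differential effect (default 4). The chosen clusters are
constrained to have pairwise-distinct nearest genes not shared with any
other super cluster, so the planted SE→gene map is unambiguous. Those
nearest genes receive a concordant expression effect (fold 4) for a
configurable fraction of the differential SEs (default all).

Expression counts are negative-binomial (mean 200, dispersion 0.05, 3
replicates per condition, per-gene baseline means log-normal around 200);
FPKM is computed from gene span lengths with per-replicate total counts as
library sizes.

The background dispersion default (σ = 0.07 on the log scale) is
deliberately tight. The slope-1 tangency admits every point whose local
rank-curve slope exceeds `s_range/n`, so with a heavy background tail the
top handful of background singletons is always called along with the
planted clusters — a property of the tangent rule itself, not a bug in
either the caller or the generator. Keeping the background tight makes the
planted/background separation — the property the benchmark probes — the
generator's decision rather than tail luck. Real H3K27ac signal is far
more dispersed; consequently, recovery rates measured on this benchmark
characterize the pipeline's correctness, not its expected precision on
real tissue data, where no sharp planted/background boundary exists. σ is
a config field for experiments with heavier tails.

Everything is driven by one integer seed (expression uses a derived
stream), and identical configs produce byte-identical fixture files; the
emitted manifest carries sha256 checksums for integrity verification.

## Numerical choices and tie-breaks

- Coordinates are 0-based half-open throughout; GTF (1-based closed) is
  converted at the reader boundary. Adjacent intervals do not overlap and
  have gap 0; the stitch threshold is inclusive.
- TSS of a −-strand gene is `span.end − 1`, the last covered base.
- Ranking ties (equal total signal) break by (chromosome, start);
  tangency ties toward fewer SEs; nearest-gene ties toward the
  lexicographically smaller gene id; best-peak ties toward the leftmost
  start. All outputs are therefore permutation-invariant.
- Counts are rounded to integers only for the binomial test; fold changes
  use the raw values with pseudocount 1.

## Problem sizes

The packaged study conditions are desk-scale: a 100 Mb genome, ~2,400
peaks per condition, 3,000 genes, 30 planted SE clusters. The oracle-
equivalence checks run on 1,000 random curves (n up to 500) and 500 random
peak sets; calibration uses 10,000 null regions; recovery checks use 10
seeds. A full pipeline run takes a few seconds.

## Known limitations

- One representative TSS per gene; no isoform-level models.
- Point-based peak annotation ignores partial overlaps by design.
- The binomial differential test models two pooled libraries, not
  replicate dispersion; with real replicated ChIP-seq a count-model fit
  is preferable (its output can be supplied as an external table).
- The generator does not simulate reads, alignment artifacts, GC or
  copy-number confounders, input-chromatin background, or enhancer–
  promoter contacts; concordance is planted by construction at the
  nearest-gene level.
- No input-control subtraction in SE scoring (flag reserved, default off).
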