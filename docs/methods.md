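# Methods

## Accessibility deviations

The central statistic is the bias-corrected accessibility deviation over a
binarized peak-by-cell matrix X (entry 1 if any fragment was observed). The
expectation under independence of peak popularity and cell depth is
E_ij = row_i · col_j / total, which conditions on cell totals and therefore
absorbs per-cell depth ("fraction of reads in peaks") without an extra
covariate. For an annotation A (peaks × features, boolean) the raw deviation
of feature k in cell j is (observed − expected)/expected summed over the
annotated peaks. Technical bias is removed with background peak sets: each
annotated peak is replaced, in each of `n_background = 50` iterations, by a
peak drawn from the same bin of a grid over rank-normalized (GC fraction,
mean accessibility); the bias-corrected deviation subtracts the mean of the
background raws and the z-score divides by their standard deviation
(ddof = 1). Exact zeros: a feature whose annotated peaks have zero total is
dropped; a zero background sd yields NaN z unless the deviation is exactly
zero. The raw deviation of the all-peaks annotation is identically zero;
under with-replacement background draws the corrected deviation is centered
on zero but not exactly zero, because the resampled annotation multiset is
not the full peak set.

Two small-sample guards matter only far below real scale and are no-ops on
genome-wide data:

* **Background pool floor.** Each bin's draw pool is expanded ring by ring
  (nearest bins by Chebyshev distance in rank space) until it holds at
  least `min_pool = 25` peaks. With pools of a handful of peaks the
  background statistic becomes nearly deterministic for some cells and the
  z-score ratio degenerates. The grid itself stays at `n_bins = 25` per
  axis, the scale appropriate for ~10⁴–10⁵ peaks.
* **k-mer support filter.** k-mers annotating fewer than
  `kmer_min_support = 5` peaks are excluded from the deviation/assembly
  stage. A k-mer backed by one peak has no estimable profile: in cells
  where that peak is closed the raw deviation is −1 against an almost
  deterministic matched background, which produces |z| in the hundreds. In
  real data every 7-mer annotates thousands of peaks and the filter removes
  nothing.

The variability score of a feature is the standard deviation of its z-scores
across cells (NaN entries excluded; undefined below 2 cells). Under an
exchangeable background it sits near 1; values above the seeding threshold
of 2.0 flag cell-type-specific features.

## De novo motif assembly

Features are canonical 7-mers (collapsed with their reverse complement;
7 bp is the typical core binding-site length, and whether the original
k-mer matching collapsed strands is not documented — collapse is this
package's choice). Assembly is greedy: the unused k-mer of maximal
variability ≥ 2.0 seeds a consensus; unused k-mers whose z-profile Pearson
correlation with the seed is ≥ `r_min = 0.7` and whose sequence (either
orientation) matches the growing consensus with an exact overlap of ≥ k−1
bases join it, extending the consensus by at most one base per addition
(width capped at 15). PWM columns are correlation-weighted base frequencies
(seed weight 1). Consumed k-mers cannot seed or join later motifs, so the
output is deterministic for a fixed deviation matrix. Zero-variance columns
in any Pearson computation contribute correlation 0.

## PWM scanning and motif similarity

Scanning reports log-odds in bits against a background (uniform by default)
at every offset on both strands. The p-value of a score is exact: the null
distribution of the total score over independent background-distributed
columns is built by dynamic programming (scores keyed at 9-decimal
resolution), and P(S ≥ s) is read from its survival function. Hits require
p ≤ 1e-4 and are reported 1-based inclusive. Motif-to-motif similarity is
the maximum over ungapped offsets (≥ 5 aligned columns) and orientations of
the mean per-column Pearson correlation of probability columns, calibrated
by column-shuffling the target `n_perm` times with an add-one-corrected
empirical p; ties prefer the smaller |offset|, then the forward orientation.

## TE enrichment

ES_peak and ES_motif are log2 ratios of the feature-conditional subfamily
share to the subfamily's genomic share (formulas in the README). Overlaps
count each (feature, fragment) pair separately in bp; a peak qualifies for
the ES_motif numerator only when an entire motif hit lies inside both the
peak and a fragment of the subfamily. Subfamilies with fewer than 3
intersections are excluded. Significance uses Fisher's exact test on the
quantities behind each ratio — bp units for ES_peak (overlap bp, other ChIP
bp; subfamily bp outside ChIP, remaining genome bp) and peak counts for
ES_motif (qualifying motif peaks, other motif peaks; subfamily-overlapping
non-motif peaks, remaining peaks) — with BH across subfamilies. The
background-corrected robust z transplants every motif hit to its peak's
background peak at the same peak-relative offset, recomputes ES_motif per
iteration, and standardizes by median/MAD with the 1.4826 consistency
constant; a background iteration with zero qualifying peaks takes a
half-count (0.5) numerator floor so the control distribution stays finite
(observed counts are never floored — they passed the ≥3 filter). MAD = 0
yields NaN.

Report rounding for percentages: two significant figures below 10%, nearest
integer above.

## Trajectory statistics

Branch membership and pseudotime are inputs. Branch comparisons use the
two-sided Mann–Whitney U test per feature with BH across features: exact
enumeration of all group assignments for n₁+n₂ ≤ 16 (valid under ties;
two-sided p = min(1, 2·min(tails))), tie-corrected normal approximation
otherwise. Segment profiles split each branch's own empirical pseudotime
range into 10 equal-width bins (last bin right-closed) and average each
feature per bin; empty bins are NaN. Signed positions through the branching
node are carried for display only.

## Consensus projection

Each fragment maps to its consensus through ordered ungapped blocks
(genomic 0-based half-open, consensus 1-based inclusive; antisense
fragments map increasing genomic position to decreasing consensus
position). Counts mode increments every consensus position whose genomic
image lies in a feature, once per (feature, fragment) pair — a peak
spanning several fragments contributes to each. Normalized mode counts
fragments covered by ≥1 feature at each position and divides by the total
number of fragments (1 bp resolution), so values are in [0, 1]. RepeatMasker
.out rows degrade to a single block only when the genomic and consensus
span lengths agree; otherwise a block-alignment table is required.

## Evolutionary dating and conservation

The species ladder nests 17 species into clades ordered outward from mouse
(Muridae → … → Vertebrata); divergence-time labels are metadata only. An
element's acquisition clade is the outermost clade containing ≥ 1 species
with a surviving ortholog — equivalently, the clade at which the most
distantly related ortholog-bearing species first appears; elements with no
ortholog are focal-lineage-specific. With independent presence-flip noise ε
the per-element recovery probability is ≈ (1−ε)^m, m the number of species
outside the true clade, so recovery is intrinsically lower for young
(lineage-specific) elements.

The conservation test compares the mean per-bp score over all motif-site
bases with control draws that place one same-width window per site,
uniformly and without overlap within a draw, into the accessible TE space
outside the motif sites; p = (1 + #{control means ≥ observed})/(n + 1) with
n = 500 draws, so the smallest attainable p is 1/501.

## Synthetic data

The generator emulates the structure of a single-cell accessibility study
of a repeat-rich genome. Defaults define the study conditions: two
chromosomes of 300 kb; four subfamilies (two with planted 7-bp motifs at
fixed consensus positions — carrier fraction 0.8 — and planted acquisition
clades Amniota and Eutheria; two without motifs, dated Rodentia and
Muridae); three populations of 200 cells (progenitor, neuron, glia) on
branches S2_S1, S0_S1 and an off-trajectory branch. Peaks are 500 bp:
motif-carrier fragments get peaks owned by one population per subfamily
(MER130 → progenitor, MamRep434 → neuron); half of the remaining fragments
and 80 TE-free positions get peaks open in all populations; each population
adds TE-free specific peaks, 80% of which carry its subfamily's motif where
one is assigned. Cells open their population's peaks with p_open = 0.85 and
all others with p_noise = 0.05. ChIP peaks (width 200) center on genomic
motif instances with ±20 bp jitter plus 20% false positives; an optional
read mode emits IP reads concentrated at motif sites against uniform input.
The conservation track is 0 everywhere and 2.0 on motif bases; ortholog
presence follows the planted clade with 1% flip noise. All draws come from
one seeded generator in a fixed order, so a (config, seed) pair reproduces
the dataset byte for byte.

Each planted subfamily's peaks belong to a distinct population by design:
two 400–500 bp random consensi share ≈ 24 7-mers by chance, and if both
subfamilies' peaks opened in the same population those shared k-mers would
be more population-specific than either planted motif — a confound of the
synthetic construction, not of the method.

What the generator does not emulate: fragment-length and insertion-bias
structure, nested repeats, doublets, batch effects, gapped consensus
alignments, and realistic motif degeneracy (planted motifs are exact).
Passing tests therefore demonstrate correctness of the computations and
recoverability of planted effects under clean conditions, not performance
on real tissue data.

## Problem sizes

The default synthetic study (≈ 365 peaks × 600 cells, 180 fragments, 8192
k-mer features, 50 background iterations) keeps a full pipeline run under
half a minute; null calibration uses 12 seeds of a single-population
configuration (500 cells, ≈ 170 peaks). The deviation engine is verified
against a dense brute-force oracle on 100 random 20-peak × 10-cell
instances to 1e-10, PWM-scan p-values against exhaustive 4^w enumeration
for w ≤ 6, and the Mann–Whitney path against full permutation enumeration
for group sizes ≤ 8.

## Known limitations

* The deviation z-score is heteroskedastic for features with very few
  annotated peaks; the support filter masks rather than models this.
* ES_motif significance uses a peak-count contingency whose exact
  construction is a package choice; alternative unitizations (fragment
  counts, as in published subfamily-vs-all-TEs tables) are supported
  through `contingency_fisher` directly.
* The ortholog table is consumed as boolean presence; remap-quality
  filtering (e.g. minimum remapped-base ratio) is upstream of this package.
* Motif similarity calibration shuffles whole columns; it does not
  reproduce database-wide q-values.
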