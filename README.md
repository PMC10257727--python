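# tecis

Discovery and evolutionary dating of transposable-element-derived
cis-regulatory elements from single-cell chromatin accessibility.

Transposable elements (TEs) are a major source of new regulatory DNA: a TE
subfamily that carried a transcription-factor binding motif when it spread
through an ancestral genome can deposit hundreds of ready-made enhancers at
once. `tecis` implements an analysis that detects this signature in
scATAC-seq data. Starting from a binarized peak-by-cell matrix and a
RepeatMasker-style repeat annotation, it

1. computes **bias-corrected accessibility deviations** for arbitrary peak
   annotations. For feature *k* (a k-mer, a PWM motif, or a TE subfamily)
   and cell *j*,

       raw_kj = (Σᵢ A_ik X_ij − Σᵢ A_ik E_ij) / Σᵢ A_ik E_ij,
       E_ij   = (rowᵢ / total) · colⱼ,

   corrected by GC/accessibility-matched background peaks: the deviation is
   `raw − mean(background raws)` and the z-score divides by their standard
   deviation;
2. assembles **de novo motifs** from 7-mers whose deviation z-profiles
   correlate with a high-variability seed k-mer (variability = sd of z
   across cells; seeds require v ≥ 2);
3. scores **TE-subfamily enrichment** in transcription-factor ChIP peaks and
   in accessible motifs,

       ES_peak  = log2[(overlap bp / ChIP bp) / (subfamily bp / genome bp)],
       ES_motif = log2[(motif peaks in subfamily / motif peaks) / (subfamily bp / genome bp)],

   with a ≥3-intersection filter, Fisher/Benjamini–Hochberg significance,
   and a robust z-score against backgrounds in which every motif hit is
   transplanted to a matched peak at the same offset;
4. projects ChIP peaks and motif hits onto **TE consensus coordinates**
   through strand-aware block alignments;
5. compares accessibility between **pseudotime branches** (Mann–Whitney/BH,
   10-segment profiles); and
6. **dates** each TE-derived element by the outermost clade of a 17-species
   ladder in which an ortholog survives, and tests motif-site conservation
   against 500 shuffled controls.

A synthetic-data generator (`tecis.simulate`) produces a complete fake study
— genome, TE fragments with consensus alignments, cell populations, ChIP
peaks, ortholog tables, conservation tracks — with every planted parameter
recorded, so the whole pipeline is testable against known ground truth.

## Worked example

```sh
tecis run-all --seed 1 --out runs/demo
```

simulates the default study (600 cells in three populations, four TE
subfamilies, two planted 7-bp motifs) and runs every stage. The report
(`runs/demo/results/report.json`) contains, among others:

```
top_kmer: CAGATGG
top_kmer_variability: 2.72
ES_peak  Neurod2: MER130     es_peak 4.16  q ~ 1e-300
ES_motif denovo_1: MER130    es_motif 5.99  q 5.9e-41  robust_z 4.9
clade counts: Muridae 50, Rodentia 35, Eutheria 45, Amniota 41, ...
conservation: observed 0.23 vs controls ~0.003, empirical p 0.002
```

Read: the planted Neurod2-like k-mer `CAGATGG` is the most cell-type
variable sequence feature (v = 2.72 > 2); the MER130-like subfamily that
carries it is the top-enriched subfamily in the matching ChIP peak set
(ES ≈ 4.2, log2 scale) and in the accessible de novo motif (robust z ≈ 4.9
against offset-preserving background transplants); dating by ortholog
presence recovers the planted acquisition clades; and the motif bases are
more conserved than 500 shuffled control draws can explain (the smallest
attainable empirical p is 1/501 ≈ 0.002).

The same stages are available individually (`tecis simulate`, `deviations`,
`denovo-motifs`, `scan`, `te-enrich`, `te-access`, `trajectory`,
`project-consensus`, `date-elements`, `conserve`, `report`), each reading
and writing plain-text formats (BED, TSV, FASTA, MEME, bedGraph, YAML).

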