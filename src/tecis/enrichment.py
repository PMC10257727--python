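"""TE-subfamily enrichment in TF binding sites and accessible motifs.

Two log2 enrichment scores are computed per repeat subfamily:

* ES_peak = log2( (overlap bp between TF ChIP peaks and the subfamily /
  total ChIP peak bp) / (subfamily bp / genome length) ) — base-pair based,
  with each (peak, fragment) overlap counted separately;
* ES_motif = log2( (number of ATAC peaks whose motif hit is fully contained
  in both the peak and a fragment of the subfamily / number of ATAC peaks
  with the motif) / (subfamily bp / genome length) ) — count based.

Subfamilies intersecting the feature set fewer than three times are excluded
so that a handful of fragments cannot produce an extreme score. Significance
comes from Fisher's exact test on the same quantities (bp units for ES_peak,
peak counts for ES_motif) with BH correction across subfamilies, and from a
background-corrected robust z-score in which every motif hit is transplanted
to covariate-matched background peaks at the same peak-relative offset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats as _st

from tecis.accessibility import BackgroundPeakSets, BinaryAccessibilityMatrix
from tecis.intervals import (
    GenomicInterval,
    PeakSet,
    TEFragment,
    count_intersections,
    total_overlap_bp,
)
from tecis.motifs import MotifHit
from tecis.stats import bh_adjust, fisher_exact_2x2, mannwhitney_u, percent_value, robust_z

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be nonnegative")


@dataclass
class EnrichmentRecord:
    subfamily: str
    es: float
    n_intersections: int
    fisher_p: float = float("nan")
    q: float = float("nan")
    robust_z: float = float("nan")


def contingency_fisher(t: ContingencyTable) -> tuple[float, float]:
    """Two-sided Fisher's exact test; returns (odds ratio ad/bc, p)."""
    return fisher_exact_2x2(t.a, t.b, t.c, t.d)


def subfamily_bp(fragments: Iterable[TEFragment]) -> dict[str, int]:
    out: dict[str, int] = {}
    for fr in fragments:
        out[fr.subfamily] = out.get(fr.subfamily, 0) + len(fr.interval)
    return out


def _fragments_by_subfamily(fragments: Iterable[TEFragment]
                            ) -> dict[str, list[TEFragment]]:
    by: dict[str, list[TEFragment]] = {}
    for fr in fragments:
        by.setdefault(fr.subfamily, []).append(fr)
    return by


def enrichment_score_peak(tf_peaks: PeakSet,
                          subfamily_fragments: Sequence[TEFragment],
                          genome_len: int,
                          min_intersections: int = 3) -> float | None:
    """ES_peak for one subfamily, or None when the >=3-intersection filter
    (or the overlap) excludes it."""
    tf_bp = tf_peaks.total_bp()
    if tf_bp == 0:
        raise ValueError("TF peak set covers zero bp")
    n_inter = count_intersections(tf_peaks, subfamily_fragments)
    if n_inter < min_intersections:
        return None
    overlap = total_overlap_bp(tf_peaks,
                               [fr.interval for fr in subfamily_fragments])
    sub_bp = sum(len(fr.interval) for fr in subfamily_fragments)
    return float(np.log2((overlap / tf_bp) / (sub_bp / genome_len)))


def _hit_interval_genomic(peak: GenomicInterval, hit: MotifHit) -> GenomicInterval:
    """Genomic interval of a motif hit whose coordinates are 1-based inclusive
    positions within the peak sequence."""
    return GenomicInterval(peak.chrom, peak.start + hit.start - 1,
                           peak.start + hit.end, hit.strand)


def _contained(inner_start: int, inner_end: int, outer: GenomicInterval,
               chrom: str) -> bool:
    return (chrom == outer.chrom and outer.start <= inner_start
            and inner_end <= outer.end)


def peaks_with_motif_in_subfamily(atac_peaks: PeakSet,
                                  motif_hits: Mapping[str, Sequence[MotifHit]],
                                  subfamily_fragments: Sequence[TEFragment],
                                  ) -> set[str]:
    """ATAC peak ids carrying a motif hit fully contained in both the peak
    and a fragment of the subfamily."""
    trees: dict[str, IntervalTree] = {}
    for fr in subfamily_fragments:
        iv = fr.interval
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    ids = atac_peaks.ids or [f"region_{i}" for i in range(len(atac_peaks))]
    qualifying: set[str] = set()
    for pid, peak in zip(ids, atac_peaks.intervals):
        for hit in motif_hits.get(pid, ()):  # hits are peak-contained by construction
            g = _hit_interval_genomic(peak, hit)
            tree = trees.get(g.chrom)
            if tree is None:
                continue
            if any(itv.begin <= g.start and g.end <= itv.end
                   for itv in tree.overlap(g.start, g.end)):
                qualifying.add(pid)
                break
    return qualifying


def enrichment_score_motif(atac_peaks: PeakSet,
                           motif_hits: Mapping[str, Sequence[MotifHit]],
                           subfamily_fragments: Sequence[TEFragment],
                           genome_len: int,
                           min_intersections: int = 3,
                           numerator_floor: float | None = None,
                           ) -> float | None:
    """ES_motif for one subfamily, or None under the intersection filter.

    numerator_floor, when given, replaces a zero qualifying-peak count (used
    for background iterations so the control distribution stays finite).
    """
    peaks_with_motif = [pid for pid, hits in motif_hits.items() if hits]
    n_motif = len(peaks_with_motif)
    if n_motif == 0:
        raise ValueError("no ATAC peaks carry the motif")
    qualifying = peaks_with_motif_in_subfamily(atac_peaks, motif_hits,
                                               subfamily_fragments)
    if min_intersections and len(qualifying) < min_intersections:
        return None
    n_qual: float = len(qualifying)
    if n_qual == 0:
        if numerator_floor is None:
            return None
        n_qual = numerator_floor
    sub_bp = sum(len(fr.interval) for fr in subfamily_fragments)
    return float(np.log2((n_qual / n_motif) / (sub_bp / genome_len)))


def enrichment_table_peak(tf_peaks: PeakSet, fragments: Sequence[TEFragment],
                          genome_len: int, min_intersections: int = 3,
                          ) -> pd.DataFrame:
    """ES_peak with Fisher/BH significance for every eligible subfamily.

    The Fisher table is in bp units: (overlap bp, other ChIP bp;
    subfamily bp outside ChIP, remaining genome bp).
    """
    tf_bp = tf_peaks.total_bp()
    rows = []
    for sub, frs in _fragments_by_subfamily(fragments).items():
        n_inter = count_intersections(tf_peaks, frs)
        if n_inter < min_intersections:
            continue
        overlap = total_overlap_bp(tf_peaks, [fr.interval for fr in frs])
        sub_bp = sum(len(fr.interval) for fr in frs)
        es = float(np.log2((overlap / tf_bp) / (sub_bp / genome_len)))
        a = overlap
        b = tf_bp - overlap
        c = sub_bp - overlap
        d = genome_len - sub_bp - b
        _, p = fisher_exact_2x2(a, b, c, d)
        rows.append((sub, es, n_inter, p))
    df = pd.DataFrame(rows, columns=["subfamily", "es_peak",
                                     "n_intersections", "fisher_p"])
    df["q"] = bh_adjust(df["fisher_p"].to_numpy()) if len(df) else []
    return df.sort_values("es_peak", ascending=False, kind="stable") \
        .reset_index(drop=True)


def enrichment_table_motif(atac_peaks: PeakSet,
                           motif_hits: Mapping[str, Sequence[MotifHit]],
                           fragments: Sequence[TEFragment],
                           genome_len: int,
                           min_intersections: int = 3) -> pd.DataFrame:
    """ES_motif with Fisher/BH significance for every eligible subfamily.

    The Fisher table is in peak counts: (motif peaks in subfamily, other
    motif peaks; subfamily-overlapping peaks without the motif, remaining
    peaks).
    """
    peaks_with_motif = {pid for pid, hits in motif_hits.items() if hits}
    n_motif = len(peaks_with_motif)
    if n_motif == 0:
        raise ValueError("no ATAC peaks carry the motif")
    n_total = len(atac_peaks)
    ids = atac_peaks.ids or [f"region_{i}" for i in range(n_total)]
    rows = []
    for sub, frs in _fragments_by_subfamily(fragments).items():
        qualifying = peaks_with_motif_in_subfamily(atac_peaks, motif_hits, frs)
        if len(qualifying) < min_intersections:
            continue
        sub_bp = sum(len(fr.interval) for fr in frs)
        es = float(np.log2((len(qualifying) / n_motif) / (sub_bp / genome_len)))
        # peaks overlapping the subfamily at all (for the non-hit cell)
        trees: dict[str, IntervalTree] = {}
        for fr in frs:
            iv = fr.interval
            trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
        overlapping = {
            pid for pid, iv in zip(ids, atac_peaks.intervals)
            if iv.chrom in trees and trees[iv.chrom].overlap(iv.start, iv.end)
        }
        a = len(qualifying)
        b = n_motif - a
        c = len(overlapping - peaks_with_motif)
        d = n_total - n_motif - c
        _, p = fisher_exact_2x2(a, b, c, d)
        rows.append((sub, es, len(qualifying), p))
    df = pd.DataFrame(rows, columns=["subfamily", "es_motif",
                                     "n_intersections", "fisher_p"])
    df["q"] = bh_adjust(df["fisher_p"].to_numpy()) if len(df) else []
    return df.sort_values("es_motif", ascending=False, kind="stable") \
        .reset_index(drop=True)


def transplant_hits(atac_peaks: PeakSet,
                    motif_hits: Mapping[str, Sequence[MotifHit]],
                    bg: BackgroundPeakSets, iteration: int,
                    ) -> dict[str, list[MotifHit]]:
    """Move every motif hit to its source peak's background peak for one
    background iteration, keeping the peak-relative offset."""
    ids = atac_peaks.ids or [f"region_{i}" for i in range(len(atac_peaks))]
    pos = {pid: i for i, pid in enumerate(ids)}
    new_hits: dict[str, list[MotifHit]] = {pid: [] for pid in ids}
    for pid, hits in motif_hits.items():
        if not hits:
            continue
        tgt_idx = int(bg.index[pos[pid], iteration])
        tgt_id = ids[tgt_idx]
        tgt = atac_peaks.intervals[tgt_idx]
        width = len(tgt)
        for h in hits:
            # clamp: background peaks may be shorter after boundary clipping
            start = min(h.start, max(1, width - (h.end - h.start)))
            end = start + (h.end - h.start)
            if end > width:
                continue
            new_hits[tgt_id].append(MotifHit(tgt_id, start, end, h.strand,
                                             h.score, h.p, motif=h.motif))
    return new_hits


def background_corrected_es_z(observed_es: float, atac_peaks: PeakSet,
                              motif_hits: Mapping[str, Sequence[MotifHit]],
                              subfamily_fragments: Sequence[TEFragment],
                              genome_len: int, bg: BackgroundPeakSets,
                              numerator_floor: float = 0.5) -> float:
    """Robust z of the observed ES_motif against offset-preserving background
    transplants: (observed - median) / (1.4826 * MAD). NaN when MAD is zero."""
    controls = []
    for t in range(bg.n_iterations):
        hits_t = transplant_hits(atac_peaks, motif_hits, bg, t)
        es_t = enrichment_score_motif(atac_peaks, hits_t, subfamily_fragments,
                                      genome_len, min_intersections=0,
                                      numerator_floor=numerator_floor)
        controls.append(es_t)
    return robust_z(observed_es, controls)


def detect_te_derived_accessible_motifs(
        atac_peaks: PeakSet,
        motif_hits: Mapping[str, Sequence[MotifHit]],
        fragments: Sequence[TEFragment],
        ) -> tuple[pd.DataFrame, list[tuple[MotifHit, GenomicInterval, str]]]:
    """Motif hits fully inside a peak AND fully inside a TE fragment.

    Returns a per-(subfamily, motif) count table and the list of
    (hit, genomic interval, subfamily) records.
    """
    trees: dict[str, IntervalTree] = {}
    for fr in fragments:
        iv = fr.interval
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, fr)
    ids = atac_peaks.ids or [f"region_{i}" for i in range(len(atac_peaks))]
    records: list[tuple[MotifHit, GenomicInterval, str]] = []
    for pid, peak in zip(ids, atac_peaks.intervals):
        for hit in motif_hits.get(pid, ()):
            g = _hit_interval_genomic(peak, hit)
            tree = trees.get(g.chrom)
            if tree is None:
                continue
            for itv in tree.overlap(g.start, g.end):
                if itv.begin <= g.start and g.end <= itv.end:
                    records.append((hit, g, itv.data.subfamily))
    counts = pd.DataFrame(
        [(sub, h.motif) for h, _, sub in records],
        columns=["subfamily", "motif"])
    table = (counts.groupby(["subfamily", "motif"]).size()
             .rename("n_hits").reset_index()
             if len(counts) else
             pd.DataFrame(columns=["subfamily", "motif", "n_hits"]))
    return table, records


def te_class_composition(features: PeakSet, fragments: Sequence[TEFragment],
                         mode: str = "chip") -> pd.DataFrame:
    """TE class composition of a feature set.

    mode="chip": bp of overlap per class and the TE bp fraction of the total
    feature bp. mode="atac": number of features overlapping each class and
    the fraction of features with any TE overlap. The formatted percentage
    follows the report rounding rule (two significant figures below 10%).
    """
    if mode not in ("chip", "atac"):
        raise ValueError("mode must be 'chip' or 'atac'")
    by_class: dict[str, list[TEFragment]] = {}
    for fr in fragments:
        by_class.setdefault(fr.te_class, []).append(fr)
    rows = []
    if mode == "chip":
        total = features.total_bp()
        te_total = total_overlap_bp(features,
                                    [fr.interval for fr in fragments])
        for cls, frs in sorted(by_class.items()):
            ov = total_overlap_bp(features, [fr.interval for fr in frs])
            rows.append((cls, ov, ov / total if total else 0.0))
        frac = te_total / total if total else 0.0
        numer, denom = te_total, total
    else:
        n = len(features)
        trees_all = _class_trees(fragments)
        te_any = sum(1 for iv in features
                     if _overlaps_any(iv, trees_all))
        for cls, frs in sorted(by_class.items()):
            trees = _class_trees(frs)
            cnt = sum(1 for iv in features if _overlaps_any(iv, trees))
            rows.append((cls, cnt, cnt / n if n else 0.0))
        frac = te_any / n if n else 0.0
        numer, denom = te_any, n
    df = pd.DataFrame(rows, columns=["te_class", "amount", "fraction"])
    df.attrs["te_fraction"] = frac
    df.attrs["te_numerator"] = numer
    df.attrs["te_denominator"] = denom
    df.attrs["te_percent"] = percent_value(frac)
    return df


def _class_trees(fragments: Sequence[TEFragment]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for fr in fragments:
        iv = fr.interval
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def _overlaps_any(iv: GenomicInterval, trees: dict[str, IntervalTree]) -> bool:
    tree = trees.get(iv.chrom)
    return bool(tree and tree.overlap(iv.start, iv.end))


def per_cell_te_fraction(X: BinaryAccessibilityMatrix,
                         peak_te_flag: np.ndarray,
                         subsample_n: int | None = None,
                         seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Per-cell fraction of accessible peaks overlapping TEs, with group tests.

    Returns (per-cell table, pairwise Mann-Whitney/BH table, Kruskal-Wallis p).
    Cells with zero accessible peaks are excluded with a warning. When
    subsample_n is not None, that many cells per group (default the smallest
    group) are drawn without replacement before testing.
    """
    flag = np.asarray(peak_te_flag, dtype=bool)
    if len(flag) != X.n_peaks:
        raise ValueError("peak_te_flag length mismatch")
    labels = X.labels_array()
    n_open = X.values.sum(axis=0)
    if (n_open == 0).any():
        logger.warning("excluding %d cells with zero accessible peaks",
                       int((n_open == 0).sum()))
    keep = n_open > 0
    frac = (flag @ X.values)[keep] / n_open[keep]
    cells = np.array(X.cell_ids)[keep]
    labels = labels[keep]
    per_cell = pd.DataFrame({"cell_id": cells, "group": labels,
                             "te_fraction": frac})

    groups = sorted(per_cell["group"].unique())
    if len(groups) < 2:
        raise ValueError("group tests need at least 2 cell labels")
    rng = np.random.default_rng(seed)
    if subsample_n is not None:
        if subsample_n == 0:
            subsample_n = per_cell.groupby("group").size().min()
        parts = []
        for g in groups:
            sub = per_cell[per_cell["group"] == g]
            take = min(subsample_n, len(sub))
            parts.append(sub.iloc[rng.choice(len(sub), take, replace=False)])
        per_cell_test = pd.concat(parts, ignore_index=True)
    else:
        per_cell_test = per_cell

    samples = [per_cell_test.loc[per_cell_test["group"] == g, "te_fraction"]
               .to_numpy() for g in groups]
    kw_p = float(_st.kruskal(*samples).pvalue) if len(groups) > 1 else 1.0

    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            _, p = mannwhitney_u(samples[i], samples[j])
            rows.append((groups[i], groups[j], p))
    pw = pd.DataFrame(rows, columns=["group_a", "group_b", "p"])
    pw["q"] = bh_adjust(pw["p"].to_numpy())
    return per_cell, pw, kw_p
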