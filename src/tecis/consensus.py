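"""Strand-aware projection of genomic features onto TE consensus coordinates.

Each repeat fragment carries a block alignment to its subfamily's consensus:
parallel lists of genomic blocks (0-based half-open) and consensus blocks
(1-based inclusive), ungapped within a block. On the antisense strand an
increasing genomic position maps to a decreasing consensus position.
Projection counts, per consensus position, how many (feature, fragment)
pairs cover that position's genomic image; the normalized profile instead
counts fragments covered by >= 1 feature at the position, divided by the
total number of fragments in the genome at 1 bp resolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from tecis.intervals import GenomicInterval, PeakSet, TEFragment


@dataclass
class ConsensusAlignment:
    """Ungapped-block alignment of one genomic fragment to a consensus."""

    fragment_id: str
    genomic_blocks: list[tuple[int, int]]    # 0-based half-open, ordered
    consensus_blocks: list[tuple[int, int]]  # 1-based inclusive, parallel
    strand: str
    chrom: str = ""

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be + or -")
        if len(self.genomic_blocks) != len(self.consensus_blocks):
            raise ValueError("block lists must be parallel")
        prev_end = -1
        for (gs, ge), (cs, ce) in zip(self.genomic_blocks, self.consensus_blocks):
            if ge - gs != ce - cs + 1:
                raise ValueError(
                    f"block length mismatch: genome [{gs},{ge}) vs consensus "
                    f"{cs}-{ce}")
            if gs < prev_end:
                raise ValueError("genomic blocks must be ordered, non-overlapping")
            prev_end = ge

    def genomic_span(self) -> tuple[int, int]:
        return self.genomic_blocks[0][0], self.genomic_blocks[-1][1]


def genomic_to_consensus(pos: int, aln: ConsensusAlignment) -> int | None:
    """Consensus position (1-based) of a genomic position, or None when the
    position falls outside every aligned block."""
    for (gs, ge), (cs, ce) in zip(aln.genomic_blocks, aln.consensus_blocks):
        if gs <= pos < ge:
            if aln.strand == "+":
                return cs + (pos - gs)
            return ce - (pos - gs)
    return None


def consensus_to_genomic(cpos: int, aln: ConsensusAlignment) -> int | None:
    """Inverse of :func:`genomic_to_consensus`."""
    for (gs, ge), (cs, ce) in zip(aln.genomic_blocks, aln.consensus_blocks):
        if cs <= cpos <= ce:
            if aln.strand == "+":
                return gs + (cpos - cs)
            return gs + (ce - cpos)
    return None


@dataclass
class ConsensusProfile:
    subfamily: str
    counts: np.ndarray        # index 0 <-> consensus position 1
    normalized: np.ndarray | None
    n_fragments_total: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "position": np.arange(1, len(self.counts) + 1),
            "count": self.counts,
        })
        if self.normalized is not None:
            df["normalized"] = self.normalized
        return df


def alignment_from_fragment(fr: TEFragment) -> ConsensusAlignment:
    """Degrade a RepeatMasker .out row to a single ungapped block using its
    (begin, end) consensus span. Valid only when the genomic and consensus
    spans have equal length."""
    iv = fr.interval
    cb, ce = fr.consensus_span
    if ce - cb + 1 != len(iv):
        raise ValueError(
            f"fragment {fr.fragment_id or fr.subfamily}: consensus span "
            f"{cb}-{ce} does not match genomic length {len(iv)}; a block "
            "alignment table is required")
    return ConsensusAlignment(
        fragment_id=fr.fragment_id or f"{fr.subfamily}:{iv.chrom}:{iv.start}",
        genomic_blocks=[(iv.start, iv.end)],
        consensus_blocks=[(cb, ce)],
        strand=iv.strand if iv.strand in "+-" else "+",
        chrom=iv.chrom,
    )


def _feature_trees(features: PeakSet | Iterable[GenomicInterval]
                   ) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in features:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def _covered_consensus_slices(aln: ConsensusAlignment, fs: int, fe: int):
    """Consensus index slices (0-based into a length-L array) covered by the
    genomic window [fs, fe) under the alignment."""
    for (gs, ge), (cs, ce) in zip(aln.genomic_blocks, aln.consensus_blocks):
        s, e = max(gs, fs), min(ge, fe)
        if s >= e:
            continue
        if aln.strand == "+":
            lo = cs + (s - gs)
            hi = cs + (e - gs)  # exclusive
        else:
            hi = ce - (s - gs) + 1  # exclusive
            lo = ce - (e - gs) + 1
        yield lo - 1, hi - 1  # half-open 0-based


def project_feature_counts(features: PeakSet,
                           alignments: Sequence[ConsensusAlignment],
                           consensus_len: int,
                           subfamily: str = "",
                           normalized: bool = False) -> ConsensusProfile:
    """Per-consensus-position projection profile.

    counts mode: every (feature, fragment) pair increments every consensus
    position whose genomic image lies within the feature. normalized mode:
    each fragment contributes at most 1 per position (covered by >= 1
    feature), divided by the number of fragments.
    """
    trees = _feature_trees(features)
    counts = np.zeros(consensus_len)
    for aln in alignments:
        gs, ge = aln.genomic_span()
        tree = trees.get(aln.chrom)
        if tree is None:
            continue
        if normalized:
            cover = np.zeros(consensus_len, dtype=bool)
        for itv in tree.overlap(gs, ge):
            for lo, hi in _covered_consensus_slices(aln, itv.begin, itv.end):
                if normalized:
                    cover[lo:hi] = True
                else:
                    counts[lo:hi] += 1
        if normalized:
            counts += cover
    if normalized:
        n = len(alignments)
        if n == 0:
            raise ValueError("normalized profile requires >= 1 fragment")
        return ConsensusProfile(subfamily, counts, counts / n, n)
    return ConsensusProfile(subfamily, counts, None, len(alignments))


def normalized_coverage_profile(features: PeakSet,
                                alignments: Sequence[ConsensusAlignment],
                                consensus_len: int,
                                subfamily: str = "") -> ConsensusProfile:
    """Fraction of fragments whose aligned image at each consensus position
    is covered by >= 1 feature (1 bp resolution)."""
    return project_feature_counts(features, alignments, consensus_len,
                                  subfamily, normalized=True)


def read_enrichment_ratio(ip_reads: PeakSet, input_reads: PeakSet,
                          features: PeakSet) -> tuple[float, float, float]:
    """(IP fraction, input fraction, IP/input ratio) of reads overlapping the
    feature set by >= 1 bp. Ratio is NaN when the input fraction is zero."""
    if len(ip_reads) == 0 or len(input_reads) == 0:
        raise ValueError("read sets must be non-empty")
    trees = _feature_trees(features)

    def _frac(reads: PeakSet) -> float:
        hit = sum(
            1 for iv in reads
            if iv.chrom in trees and trees[iv.chrom].overlap(iv.start, iv.end))
        return hit / len(reads)

    ip_f, in_f = _frac(ip_reads), _frac(input_reads)
    ratio = ip_f / in_f if in_f > 0 else float("nan")
    return ip_f, in_f, ratio


# ---------------------------------------------------------------------------
# Block-alignment TSV dialect

def write_alignments_tsv(alignments: Iterable[ConsensusAlignment], path) -> None:
    """fragment_id, chrom, strand, genome blocks, consensus blocks; blocks are
    semicolon-separated start-end pairs."""
    with open(path, "w") as fh:
        fh.write("fragment_id\tchrom\tstrand\tgenome_blocks\tconsensus_blocks\n")
        for aln in alignments:
            gb = ";".join(f"{s}-{e}" for s, e in aln.genomic_blocks)
            cb = ";".join(f"{s}-{e}" for s, e in aln.consensus_blocks)
            fh.write(f"{aln.fragment_id}\t{aln.chrom}\t{aln.strand}\t{gb}\t{cb}\n")


def read_alignments_tsv(path) -> list[ConsensusAlignment]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        gb = [tuple(map(int, p.split("-"))) for p in row["genome_blocks"].split(";")]
        cb = [tuple(map(int, p.split("-"))) for p in row["consensus_blocks"].split(";")]
        out.append(ConsensusAlignment(str(row["fragment_id"]), gb, cb,
                                      row["strand"], chrom=str(row["chrom"])))
    return out
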