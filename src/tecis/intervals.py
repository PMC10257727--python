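"""Genomic interval engine, BED / RepeatMasker I/O, gene association, term enrichment.

All internal coordinates are 0-based half-open. Standard-format readers and
writers convert at the boundary: BED is already 0-based half-open,
RepeatMasker .out tables are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree
from scipy import stats as _st

from tecis.stats import bh_adjust

# TE classes dropped from annotations: simple repeats, satellites, small RNAs.
DEFAULT_CLASS_BLACKLIST = (
    "Simple_repeat",
    "Satellite",
    "Low_complexity",
    "snRNA",
    "tRNA",
    "rRNA",
    "srpRNA",
    "scRNA",
)


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid coordinates {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class PeakSet:
    """An ordered collection of genomic intervals with optional ids."""

    intervals: list[GenomicInterval]
    ids: list[str] | None = None
    chrom_sizes: dict[str, int] | None = None

    def __post_init__(self):
        if self.ids is not None:
            if len(self.ids) != len(self.intervals):
                raise ValueError("ids length must match intervals")
            if len(set(self.ids)) != len(self.ids):
                raise ValueError("ids must be unique")
        if self.chrom_sizes is not None:
            for iv in self.intervals:
                size = self.chrom_sizes.get(iv.chrom)
                if size is not None and iv.end > size:
                    raise ValueError(
                        f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds "
                        f"chromosome length {size}"
                    )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def total_bp(self) -> int:
        """Total bp covered by the union of the intervals."""
        return sum(e - s for _, ivs in _by_chrom(self.intervals).items()
                   for s, e in _union(ivs))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
                "id": self.ids if self.ids is not None
                else [f"region_{i}" for i in range(len(self.intervals))],
                "strand": [iv.strand for iv in self.intervals],
            }
        )


@dataclass(frozen=True)
class TEFragment:
    """A genomic instance of a repeat subfamily with its consensus span."""

    interval: GenomicInterval
    subfamily: str
    te_class: str
    consensus_span: tuple[int, int]  # 1-based inclusive on the consensus
    fragment_id: str = ""

    def __post_init__(self):
        if not self.subfamily:
            raise ValueError("subfamily must be non-empty")
        b, e = self.consensus_span
        if b > e:
            raise ValueError(f"consensus span begin {b} > end {e}")


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError("gene strand must be + or -")
        if self.tss < 0:
            raise ValueError("tss must be nonnegative")


@dataclass
class TermMap:
    """Gene-set collection over a fixed background (GMT-style)."""

    terms: dict[str, set[str]]
    background: set[str]

    def __post_init__(self):
        for term, genes in self.terms.items():
            extra = genes - self.background
            if extra:
                raise ValueError(
                    f"term {term} contains genes outside background: {sorted(extra)[:3]}"
                )


# ---------------------------------------------------------------------------
# BED I/O

def parse_bed(path, chrom_sizes: dict[str, int] | None = None) -> PeakSet:
    """Read a 3+ column tab-separated BED file (0-based half-open)."""
    intervals: list[GenomicInterval] = []
    ids: list[str] = []
    have_names = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: expected >=3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(
                    f"line {lineno}: start {start} >= end {end}"
                )
            strand = fields[5] if len(fields) >= 6 else "."
            intervals.append(GenomicInterval(fields[0], start, end, strand))
            if len(fields) >= 4:
                have_names = True
                ids.append(fields[3])
            else:
                ids.append(f"region_{lineno}")
    return PeakSet(intervals, ids=ids if have_names else None,
                   chrom_sizes=chrom_sizes)


def write_bed(peaks: PeakSet, path, write_strand: bool = False) -> None:
    with open(path, "w") as fh:
        ids = peaks.ids or [f"region_{i}" for i in range(len(peaks))]
        for iv, name in zip(peaks.intervals, ids):
            if write_strand:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")
            elif peaks.ids is not None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# RepeatMasker .out dialect

def parse_repeatmasker(path, class_blacklist: Sequence[str] = DEFAULT_CLASS_BLACKLIST
                       ) -> list[TEFragment]:
    """Read a RepeatMasker .out-style annotation table.

    Expected whitespace-separated columns (after the optional 3-line header):
    score, divergence, deletion, insertion, chrom, begin, end, (left),
    strand (+ or C), subfamily, class/family, repeat begin, repeat end,
    (repeat left), id. Genomic coordinates are 1-based inclusive and are
    converted to 0-based half-open; strand 'C' becomes '-'. For 'C' rows the
    consensus columns arrive as (left), end, begin per RepeatMasker
    convention. Subfamilies whose class matches the blacklist (simple
    repeats, satellites, low complexity, small RNAs by default) are dropped.
    """
    blacklist = tuple(class_blacklist)
    fragments: list[TEFragment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(("SW", "score", "#")):
                continue
            fields = stripped.split()
            if len(fields) < 14:
                raise ValueError(f"line {lineno}: expected >=14 columns")
            chrom = fields[4]
            try:
                gbegin, gend = int(fields[5]), int(fields[6])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: bad genomic coordinates") from exc
            strand_code = fields[8]
            if strand_code == "+":
                strand = "+"
                cbegin, cend = int(fields[11]), int(fields[12])
            elif strand_code in ("C", "-"):
                strand = "-"
                # (left), end, begin ordering on the complement strand
                cbegin, cend = int(fields[13]), int(fields[12])
            else:
                raise ValueError(f"line {lineno}: unknown strand code {strand_code!r}")
            if cbegin > cend:
                raise ValueError(
                    f"line {lineno}: consensus begin {cbegin} > end {cend}"
                )
            te_class = fields[10].split("/")[0]
            if any(te_class.startswith(b) or fields[10].startswith(b)
                   for b in blacklist):
                continue
            frag_id = fields[14] if len(fields) > 14 else f"frag_{lineno}"
            fragments.append(
                TEFragment(
                    interval=GenomicInterval(chrom, gbegin - 1, gend, strand),
                    subfamily=fields[9],
                    te_class=fields[10],
                    consensus_span=(cbegin, cend),
                    fragment_id=frag_id,
                )
            )
    return fragments


def write_repeatmasker(fragments: Iterable[TEFragment], path) -> None:
    """Write fragments in the .out dialect understood by :func:`parse_repeatmasker`."""
    with open(path, "w") as fh:
        fh.write("score div del ins chrom begin end (left) strand subfamily "
                 "class/family rbegin rend (rleft) id\n\n\n")
        for i, fr in enumerate(fragments):
            iv = fr.interval
            b, e = fr.consensus_span
            if iv.strand == "-":
                cols = ("(0)", str(e), str(b))
                strand = "C"
            else:
                cols = (str(b), str(e), "(0)")
                strand = "+"
            fh.write(
                f"1000 0.0 0.0 0.0 {iv.chrom} {iv.start + 1} {iv.end} (0) "
                f"{strand} {fr.subfamily} {fr.te_class} "
                f"{cols[0]} {cols[1]} {cols[2]} {fr.fragment_id or i}\n"
            )


# ---------------------------------------------------------------------------
# Overlap machinery

def _by_chrom(intervals: Iterable[GenomicInterval]) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return out


def _union(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge (start, end) pairs into a disjoint sorted union."""
    if not pairs:
        return []
    pairs = sorted(pairs)
    merged = [list(pairs[0])]
    for s, e in pairs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def total_overlap_bp(a: PeakSet | Iterable[GenomicInterval],
                     b: PeakSet | Iterable[GenomicInterval]) -> int:
    """Base pairs covered by both set-unions (symmetric)."""
    ua = {c: _union(p) for c, p in _by_chrom(a).items()}
    ub = {c: _union(p) for c, p in _by_chrom(b).items()}
    total = 0
    for chrom in set(ua) & set(ub):
        ia, ib = ua[chrom], ub[chrom]
        i = j = 0
        while i < len(ia) and j < len(ib):
            s = max(ia[i][0], ib[j][0])
            e = min(ia[i][1], ib[j][1])
            if s < e:
                total += e - s
            if ia[i][1] <= ib[j][1]:
                i += 1
            else:
                j += 1
    return total


def _build_trees(intervals: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def count_intersections(features: PeakSet | Iterable[GenomicInterval],
                        fragments: Iterable[TEFragment]) -> int:
    """Number of (feature, fragment) pairs overlapping by >= 1 bp."""
    trees = _build_trees(features)
    n = 0
    for fr in fragments:
        iv = fr.interval
        tree = trees.get(iv.chrom)
        if tree is not None:
            n += len(tree.overlap(iv.start, iv.end))
    return n


def merge_resize(peaks: PeakSet, width: int = 500) -> PeakSet:
    """Merge overlapping peaks, then replace each by a fixed-width interval
    centered on its midpoint, clipped to chromosome bounds."""
    if width <= 0:
        raise ValueError("width must be positive")
    if peaks.chrom_sizes is None:
        raise ValueError("merge_resize requires chrom_sizes")
    out: list[GenomicInterval] = []
    for chrom, pairs in _by_chrom(peaks.intervals).items():
        size = peaks.chrom_sizes[chrom]
        for s, e in _union(pairs):
            mid = (s + e) // 2
            ns = mid - width // 2
            ne = ns + width
            out.append(GenomicInterval(chrom, max(0, ns), min(size, ne)))
    out.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return PeakSet(out, chrom_sizes=peaks.chrom_sizes)


# ---------------------------------------------------------------------------
# GREAT-style gene association

def regulatory_domains(genes: Sequence[GeneModel],
                       chrom_sizes: Mapping[str, int] | None = None,
                       basal_up: int = 5000, basal_down: int = 1000,
                       max_ext: int = 1_000_000) -> dict[str, tuple[str, int, int]]:
    """Basal-plus-extension regulatory domain per gene.

    The basal domain spans basal_up bp upstream and basal_down bp downstream
    of the TSS (strand-aware). Each gene's domain then extends in both
    directions to the nearest other gene's basal domain boundary or max_ext
    from the TSS, whichever is closer. Returns gene_id -> (chrom, start, end).
    """
    basal: dict[str, tuple[str, int, int]] = {}
    for g in genes:
        if g.strand == "+":
            s, e = g.tss - basal_up, g.tss + basal_down
        else:
            s, e = g.tss - basal_down, g.tss + basal_up
        size = None if chrom_sizes is None else chrom_sizes.get(g.chrom)
        s = max(0, s)
        if size is not None:
            e = min(size, e)
        basal[g.gene_id] = (g.chrom, s, e)

    domains: dict[str, tuple[str, int, int]] = {}
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, gs in by_chrom.items():
        gs = sorted(gs, key=lambda g: g.tss)
        size = None if chrom_sizes is None else chrom_sizes.get(chrom)
        for g in gs:
            bs, be = basal[g.gene_id][1], basal[g.gene_id][2]
            lo = max(0, bs - max_ext)
            hi = be + max_ext
            if size is not None:
                hi = min(size, hi)
            # extension stops at the nearest other basal domain boundary
            for other in gs:
                if other.gene_id == g.gene_id:
                    continue
                obs, obe = basal[other.gene_id][1], basal[other.gene_id][2]
                if obe <= bs:
                    lo = max(lo, obe)
                if obs >= be:
                    hi = min(hi, obs)
            start = min(lo, bs)
            end = max(hi, be)
            domains[g.gene_id] = (chrom, start, end)
    return domains


def associate_regions_to_genes(regions: PeakSet, genes: Sequence[GeneModel],
                               basal_up: int = 5000, basal_down: int = 1000,
                               max_ext: int = 1_000_000) -> dict[str, set[str]]:
    """Associate each region with every gene whose regulatory domain it
    overlaps by >= 1 bp (GREAT basal-plus-extension rule)."""
    domains = regulatory_domains(genes, regions.chrom_sizes,
                                 basal_up, basal_down, max_ext)
    trees: dict[str, IntervalTree] = {}
    for gid, (chrom, s, e) in domains.items():
        if s < e:
            trees.setdefault(chrom, IntervalTree()).addi(s, e, gid)
    ids = regions.ids or [f"region_{i}" for i in range(len(regions))]
    out: dict[str, set[str]] = {}
    for rid, iv in zip(ids, regions.intervals):
        tree = trees.get(iv.chrom)
        hits = {h.data for h in tree.overlap(iv.start, iv.end)} if tree else set()
        out[rid] = hits
    return out


# ---------------------------------------------------------------------------
# Over-representation test

def term_enrichment(query: set[str], terms: TermMap) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per term, BH-adjusted.

    p = P(overlap >= observed) drawing |query| genes from the background.
    """
    if not query:
        raise ValueError("empty query gene set")
    extra = query - terms.background
    if extra:
        raise ValueError(f"query genes outside background: {sorted(extra)[:3]}")
    n_bg = len(terms.background)
    n_q = len(query)
    rows = []
    for term, genes in terms.terms.items():
        k = len(query & genes)
        m = len(genes)
        # P(X >= k), X ~ Hypergeom(N=n_bg, K=m, n=n_q)
        p = float(_st.hypergeom.sf(k - 1, n_bg, m, n_q)) if k > 0 else 1.0
        rows.append((term, k, m, p))
    df = pd.DataFrame(rows, columns=["term", "overlap", "term_size", "p"])
    df["q"] = bh_adjust(df["p"].to_numpy())
    return df.sort_values("q", kind="stable").reset_index(drop=True)
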