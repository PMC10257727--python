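"""k-mer peak annotation, de novo motif assembly, PWM scanning and comparison.

De novo motifs are built without a motif database: the k-mer (k = 7, the
typical core length of a transcription-factor binding site) with the highest
accessibility variability seeds a position weight matrix, and k-mers whose
per-cell accessibility z-profiles correlate strongly with the seed and whose
sequences align to the growing consensus with a (k-1)-base exact overlap are
merged in, weighted by their correlation.

PWM scanning reports log-odds (bits) against a background distribution at
every offset on both strands, with an exact p-value computed by dynamic
programming over the independent-column null score distribution (the
approach of FIMO-style scanners).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse

from tecis.accessibility import AnnotationMatrix, DeviationResult, feature_variability

ALPHABET = "ACGT"
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def canonical_kmer(kmer: str) -> str:
    """Lexicographically smaller of a k-mer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class PositionWeightMatrix:
    """Column-stochastic 4 x w probability matrix over A, C, G, T."""

    probs: np.ndarray
    name: str = "motif"
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.shape[0] != 4 or self.probs.shape[1] < 1:
            raise ValueError("probs must be 4 x w with w >= 1")
        if not np.allclose(self.probs.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")
        if self.background.shape != (4,) or (self.background <= 0).any() \
                or not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must be a positive 4-simplex point")

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    def reverse_complement(self) -> "PositionWeightMatrix":
        return PositionWeightMatrix(self.probs[::-1, ::-1].copy(),
                                    name=self.name, background=self.background)

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=0))


@dataclass(frozen=True)
class MotifHit:
    """A motif occurrence; start/end are 1-based inclusive on the sequence."""

    sequence_id: str
    start: int
    end: int
    strand: str
    score: float
    p: float
    motif: str = "motif"


# ---------------------------------------------------------------------------
# k-mer annotation

def kmer_annotation(peak_seqs: Sequence[str], k: int = 7,
                    peak_ids: Sequence[str] | None = None) -> AnnotationMatrix:
    """Annotate peaks by the canonical (reverse-complement collapsed) k-mers
    they contain. k-mers containing N never match; sequences shorter than k
    yield all-false rows."""
    present: list[set[str]] = []
    for seq in peak_seqs:
        seq = seq.upper()
        kmers = set()
        for i in range(len(seq) - k + 1):
            km = seq[i:i + k]
            if "N" not in km:
                kmers.add(canonical_kmer(km))
        present.append(kmers)
    features = sorted(set().union(*present)) if present else []
    fidx = {f: j for j, f in enumerate(features)}
    rows, cols = [], []
    for i, kmers in enumerate(present):
        for km in kmers:
            rows.append(i)
            cols.append(fidx[km])
    mat = sparse.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)),
        shape=(len(peak_seqs), len(features)))
    return AnnotationMatrix(mat, features)


# ---------------------------------------------------------------------------
# De novo assembly

def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 2:
        return 0.0
    a, b = a[ok], b[ok]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _pearson_to_seed(z: np.ndarray, seed_idx: int) -> np.ndarray:
    """Pearson correlation of every row of z with the seed row (vectorized
    for fully finite rows, pairwise-complete fallback otherwise)."""
    zs = z[seed_idx]
    out = np.empty(z.shape[0])
    finite_rows = np.isfinite(z).all(axis=1)
    if np.isfinite(zs).all():
        Z = z[finite_rows]
        a = zs - zs.mean()
        B = Z - Z.mean(axis=1, keepdims=True)
        denom = np.sqrt((a * a).sum()) * np.sqrt((B * B).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, (B @ a) / denom, 0.0)
        out[finite_rows] = r
        rest = np.flatnonzero(~finite_rows)
    else:
        rest = np.arange(z.shape[0])
    for j in rest:
        out[j] = _pearson(zs, z[j])
    return out


def _align_to_consensus(kmer: str, consensus: str, span: tuple[int, int],
                        k: int) -> int | None:
    """Offset at which kmer (already oriented) extends the current consensus
    by at most one base on either side with an exact (k-1)+ overlap.

    span is the (lo, hi) offset range already occupied, with the seed at 0.
    Returns the placement offset or None.
    """
    lo, hi = span
    for off in range(lo - 1, hi + 2):
        # overlap region between [off, off+k) and [lo, lo+len(consensus))
        s = max(off, lo)
        e = min(off + k, lo + len(consensus))
        if e - s < k - 1:
            continue
        if consensus[s - lo:e - lo] == kmer[s - off:e - off]:
            return off
    return None


def assemble_denovo_motifs(dev: DeviationResult, variability_threshold: float = 2.0,
                           r_min: float = 0.7, max_width: int = 15,
                           ) -> list[PositionWeightMatrix]:
    """Greedy de novo motif assembly from k-mer deviations.

    Repeatedly seeds on the unused k-mer of maximal variability (>= the
    threshold), then absorbs unused k-mers whose z-profile Pearson correlation
    with the seed is >= r_min and whose sequence (either orientation) aligns
    to the growing consensus with an exact overlap of k-1 or more bases,
    extending it by at most one base per addition. PWM columns are
    correlation-weighted base frequencies (seed weight 1). All k-mers used
    are consumed. Returns an empty list when no k-mer reaches the threshold.
    """
    kmers = list(dev.feature_ids)
    if not kmers:
        return []
    k = len(kmers[0])
    v = feature_variability(dev)
    z = dev.zscore
    used = np.zeros(len(kmers), dtype=bool)
    pwms: list[PositionWeightMatrix] = []

    order = np.argsort(-np.nan_to_num(v, nan=-np.inf), kind="stable")
    for seed_idx in order:
        if used[seed_idx] or not np.isfinite(v[seed_idx]) \
                or v[seed_idx] < variability_threshold:
            continue
        seed = kmers[seed_idx]
        used[seed_idx] = True
        consensus = seed
        span = (0, 0)  # offsets occupied by member k-mer starts
        members: list[tuple[str, int, float]] = [(seed, 0, 1.0)]

        # correlation of every unused k-mer with the seed profile
        corr = _pearson_to_seed(z, seed_idx)
        cand = [(j, float(corr[j])) for j in np.flatnonzero(~used)
                if corr[j] >= r_min]
        cand.sort(key=lambda jr: (-jr[1], kmers[jr[0]]))

        grew = True
        while grew and len(consensus) < max_width:
            grew = False
            for j, r in cand:
                if used[j]:
                    continue
                for oriented in (kmers[j], revcomp(kmers[j])):
                    off = _align_to_consensus(oriented, consensus, span, k)
                    if off is None:
                        continue
                    lo, hi = span
                    if off < lo:
                        consensus = oriented[0] + consensus
                        lo = off
                    elif off + k > hi + k:
                        consensus = consensus + oriented[-1]
                        hi = off
                    members.append((oriented, off, r))
                    span = (lo, hi)
                    used[j] = True
                    grew = True
                    break
                if grew:
                    break

        lo, _ = span
        width = len(consensus)
        counts = np.zeros((4, width))
        for seq, off, w in members:
            for pos, base in enumerate(seq):
                counts[ALPHABET.index(base), off - lo + pos] += w
        probs = counts / counts.sum(axis=0, keepdims=True)
        pwms.append(PositionWeightMatrix(
            probs, name=f"denovo_{len(pwms) + 1}"))
    return pwms


# ---------------------------------------------------------------------------
# PWM scanning

_LOG_FLOOR = -1e9  # stand-in for log2(0): one mismatch against a 0-prob column


def _logodds(pwm: PositionWeightMatrix) -> np.ndarray:
    with np.errstate(divide="ignore"):
        lo = np.log2(pwm.probs) - np.log2(pwm.background[:, None])
    return np.where(np.isfinite(lo), lo, _LOG_FLOOR)


def _score_distribution(logodds: np.ndarray, background: np.ndarray,
                        decimals: int = 9) -> tuple[np.ndarray, np.ndarray]:
    """Exact null distribution of the total log-odds score (independent
    background-distributed columns). Returns (scores sorted asc, P(S >= s))."""
    dist = {0.0: 1.0}
    for col in logodds.T:
        new: dict[float, float] = {}
        for s, p in dist.items():
            for b in range(4):
                key = round(s + col[b], decimals)
                new[key] = new.get(key, 0.0) + p * background[b]
        dist = new
    scores = np.array(sorted(dist))
    probs = np.array([dist[s] for s in scores])
    # survival function: P(S >= scores[i])
    sf = probs[::-1].cumsum()[::-1]
    return scores, sf


_DIST_CACHE: dict[bytes, tuple[np.ndarray, np.ndarray]] = {}


def _score_distribution_cached(logodds: np.ndarray, background: np.ndarray):
    key = logodds.tobytes() + background.tobytes()
    if key not in _DIST_CACHE:
        if len(_DIST_CACHE) > 256:
            _DIST_CACHE.clear()
        _DIST_CACHE[key] = _score_distribution(logodds, background)
    return _DIST_CACHE[key]


def _pvalue(scores: np.ndarray, sf: np.ndarray, s: float) -> float:
    i = np.searchsorted(scores, round(s, 9) - 1e-7, side="left")
    return float(sf[i]) if i < len(scores) else 0.0


def pwm_scan(seq: str, pwm: PositionWeightMatrix, p_threshold: float = 1e-4,
             sequence_id: str = "seq", both_strands: bool = True) -> list[MotifHit]:
    """Scan a sequence with a PWM; report hits with exact p <= p_threshold.

    Coordinates are 1-based inclusive on the forward sequence. Positions
    containing N never produce a hit.
    """
    seq = seq.upper()
    w = pwm.width
    if len(seq) < w:
        return []
    lo_f = _logodds(pwm)
    scores, sf = _score_distribution_cached(lo_f, pwm.background)
    strands = [("+", lo_f)]
    if both_strands:
        strands.append(("-", _logodds(pwm.reverse_complement())))

    enc = np.full(len(seq), -1, dtype=int)
    for b, ch in enumerate(ALPHABET):
        enc[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(ch)] = b

    n_pos = len(seq) - w + 1
    valid = np.ones(n_pos, dtype=bool)
    enc_clipped = np.where(enc < 0, 0, enc)
    for j in range(w):
        valid &= enc[j:j + n_pos] >= 0

    hits: list[MotifHit] = []
    for strand, lo in strands:
        sc = np.zeros(n_pos)
        for j in range(w):
            sc += lo[enc_clipped[j:j + n_pos], j]
        for i in np.flatnonzero(valid & (sc > _LOG_FLOOR / 2)):
            s = float(sc[i])
            p = _pvalue(scores, sf, s)
            if p <= p_threshold:
                hits.append(MotifHit(sequence_id, int(i) + 1, int(i) + w,
                                     strand, s, p, motif=pwm.name))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def match_motifs_to_peaks(peak_seqs: Sequence[str],
                          pwms: Sequence[PositionWeightMatrix],
                          peak_ids: Sequence[str] | None = None,
                          p_threshold: float = 1e-4,
                          ) -> tuple[AnnotationMatrix, dict[str, list[MotifHit]]]:
    """Peaks x motifs membership from full-containment PWM hits.

    Returns the annotation matrix and, per peak id, the list of hits (peak
    coordinates, 1-based inclusive) for downstream TE containment tests.
    """
    n = len(peak_seqs)
    peak_ids = list(peak_ids) if peak_ids is not None else [
        f"peak_{i}" for i in range(n)]
    names = [p.name for p in pwms]
    mat = np.zeros((n, len(pwms)), dtype=np.int8)
    all_hits: dict[str, list[MotifHit]] = {pid: [] for pid in peak_ids}
    for j, pwm in enumerate(pwms):
        for i, seq in enumerate(peak_seqs):
            hits = pwm_scan(seq, pwm, p_threshold=p_threshold,
                            sequence_id=peak_ids[i])
            if hits:
                mat[i, j] = 1
                all_hits[peak_ids[i]].extend(hits)
    return AnnotationMatrix(sparse.csr_matrix(mat), names), all_hits


# ---------------------------------------------------------------------------
# Motif similarity

def _column_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _best_alignment(pa: np.ndarray, pb: np.ndarray, min_overlap: int):
    """Max mean per-column Pearson over ungapped offsets; ties prefer
    smaller |offset|."""
    wa, wb = pa.shape[1], pb.shape[1]
    best = (-np.inf, 0)
    for off in range(-(wb - min_overlap), wa - min_overlap + 1):
        s = max(0, off)
        e = min(wa, off + wb)
        if e - s < min_overlap:
            continue
        cols = [_column_corr(pa[:, i], pb[:, i - off]) for i in range(s, e)]
        score = float(np.mean(cols))
        if score > best[0] or (score == best[0] and abs(off) < abs(best[1])):
            best = (score, off)
    return best


def motif_similarity(a: PositionWeightMatrix, b: PositionWeightMatrix,
                     min_overlap: int = 5, n_perm: int = 1000,
                     seed: int = 0) -> tuple[float, int, str, float]:
    """Ungapped motif similarity with permutation calibration.

    Score is the mean per-column Pearson correlation of the probability
    columns over the best offset and orientation of b (zero-variance columns
    contribute 0). The p-value is the add-one-corrected fraction of n_perm
    column-shuffled versions of b achieving >= the observed score. Ties
    between equal scores prefer smaller |offset|, then forward orientation.
    """
    if a.width < min_overlap or b.width < min_overlap:
        raise ValueError("motifs narrower than min_overlap cannot be compared")
    pb_rc = b.reverse_complement().probs
    fwd = _best_alignment(a.probs, b.probs, min_overlap)
    rev = _best_alignment(a.probs, pb_rc, min_overlap)
    if rev[0] > fwd[0] or (rev[0] == fwd[0] and abs(rev[1]) < abs(fwd[1])):
        score, offset, orientation = rev[0], rev[1], "reverse"
    else:
        score, offset, orientation = fwd[0], fwd[1], "forward"

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(b.width)
        sp_f = _best_alignment(a.probs, b.probs[:, perm], min_overlap)[0]
        sp_r = _best_alignment(a.probs, pb_rc[:, perm[::-1]], min_overlap)[0]
        if max(sp_f, sp_r) >= score:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return score, offset, orientation, p


# ---------------------------------------------------------------------------
# MEME minimal text I/O

def write_meme(pwms: Iterable[PositionWeightMatrix], path,
               background: np.ndarray | None = None) -> None:
    pwms = list(pwms)
    bg = background if background is not None else (
        pwms[0].background if pwms else np.full(4, 0.25))
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.6f}" for b, f in zip(ALPHABET, bg)) + "\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {pwm.width}\n")
            for col in pwm.probs.T:
                fh.write("  " + "  ".join(f"{x:.6f}" for x in col) + "\n")
            fh.write("\n")


def read_meme(path) -> list[PositionWeightMatrix]:
    pwms: list[PositionWeightMatrix] = []
    background = np.full(4, 0.25)
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            parts = lines[i + 1].split()
            background = np.array([float(parts[j]) for j in (1, 3, 5, 7)])
            i += 2
            continue
        if line.startswith("MOTIF"):
            name = line.split()[1]
            i += 1
            while not lines[i].strip().startswith("letter-probability"):
                i += 1
            w = int(lines[i].split("w=")[1].split()[0])
            cols = []
            for j in range(w):
                cols.append([float(x) for x in lines[i + 1 + j].split()])
            probs = np.array(cols).T
            probs = probs / probs.sum(axis=0, keepdims=True)
            pwms.append(PositionWeightMatrix(probs, name=name,
                                             background=background))
            i += 1 + w
            continue
        i += 1
    return pwms


def hits_to_tsv(hits: Iterable[MotifHit], path) -> None:
    import pandas as pd

    rows = [(h.sequence_id, h.start, h.end, h.strand, h.score, h.p, h.motif)
            for h in hits]
    pd.DataFrame(rows, columns=["sequence", "start", "end", "strand",
                                "score", "p", "motif"]).to_csv(
        path, sep="\t", index=False)
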