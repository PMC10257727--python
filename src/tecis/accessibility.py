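"""Bias-corrected accessibility deviations over a binary peak-by-cell matrix.

For an annotation (set of peaks defining a feature: a k-mer, a motif, a TE
subfamily) the raw deviation of feature k in cell j is

    raw_kj = (sum_i A_ik X_ij - sum_i A_ik E_ij) / sum_i A_ik E_ij

where E is the expectation under independence of peak and cell totals,
E_ij = (row_i / grand_total) * col_j. Technical bias (GC content and mean
accessibility of the annotated peaks) is removed by recomputing the same
statistic with the annotation transplanted onto covariate-matched background
peaks: the bias-corrected deviation is raw minus the background mean, and the
deviation z-score divides by the background standard deviation. The
variability of a feature is the standard deviation of its z-scores across
cells; under an exchangeable background it sits near 1, so values well above
1 flag cell-type-specific features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

logger = logging.getLogger(__name__)


@dataclass
class BinaryAccessibilityMatrix:
    """Peaks x cells 0/1 matrix with ids and optional per-cell labels."""

    values: np.ndarray  # (n_peaks, n_cells) in {0, 1}
    peak_ids: list[str]
    cell_ids: list[str]
    cell_labels: dict[str, str] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values)
        n_peaks, n_cells = self.values.shape
        if len(self.peak_ids) != n_peaks or len(self.cell_ids) != n_cells:
            raise ValueError("id lists inconsistent with matrix shape")
        uniq = np.unique(self.values)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("matrix must be binary")

    @property
    def n_peaks(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def labels_array(self) -> np.ndarray:
        if self.cell_labels is None:
            raise ValueError("no cell labels attached")
        return np.array([self.cell_labels[c] for c in self.cell_ids])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.peak_ids,
                            columns=self.cell_ids)


@dataclass
class AnnotationMatrix:
    """Peaks x features boolean membership (sparse)."""

    membership: sparse.csr_matrix  # (n_peaks, n_features) bool/0-1
    feature_ids: list[str]

    def __post_init__(self):
        self.membership = sparse.csr_matrix(self.membership)
        if self.membership.shape[1] != len(self.feature_ids):
            raise ValueError("feature_ids inconsistent with membership")

    @property
    def n_features(self) -> int:
        return self.membership.shape[1]

    def drop_empty_features(self) -> "AnnotationMatrix":
        counts = np.asarray(self.membership.sum(axis=0)).ravel()
        keep = counts > 0
        if keep.all():
            return self
        dropped = [f for f, k in zip(self.feature_ids, keep) if not k]
        logger.warning("dropping %d features annotating no peak (e.g. %s)",
                       len(dropped), dropped[:3])
        return AnnotationMatrix(self.membership[:, keep],
                                [f for f, k in zip(self.feature_ids, keep) if k])

    def filter_min_support(self, min_peaks: int) -> "AnnotationMatrix":
        """Keep features annotating at least min_peaks peaks.

        A feature backed by one or two peaks has no estimable accessibility
        profile: in cells where its lone peak is closed the deviation is -1
        while a covariate-matched background can be almost deterministic,
        producing arbitrarily large z-scores. Filtering by support removes
        that degeneracy at its root.
        """
        counts = np.asarray(self.membership.sum(axis=0)).ravel()
        keep = counts >= min_peaks
        return AnnotationMatrix(self.membership[:, keep],
                                [f for f, k in zip(self.feature_ids, keep) if k])


@dataclass
class BackgroundPeakSets:
    """For each peak, n_iterations covariate-matched background peak indices."""

    index: np.ndarray  # (n_peaks, n_iterations) int
    n_iterations: int

    def __post_init__(self):
        self.index = np.asarray(self.index, dtype=int)
        if self.index.shape[1] != self.n_iterations:
            raise ValueError("index shape inconsistent with n_iterations")


@dataclass
class DeviationResult:
    deviation: np.ndarray  # (n_features, n_cells) bias-corrected Y
    zscore: np.ndarray     # (n_features, n_cells), NaN where background sd = 0
    variability: np.ndarray  # (n_features,)
    feature_ids: list[str]
    cell_ids: list[str]

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        dev = pd.DataFrame(self.deviation, index=self.feature_ids,
                           columns=self.cell_ids)
        z = pd.DataFrame(self.zscore, index=self.feature_ids,
                         columns=self.cell_ids)
        return dev, z


def binarize(counts, peak_ids=None, cell_ids=None,
             cell_labels=None) -> BinaryAccessibilityMatrix:
    """Binarize a nonnegative count matrix; drop all-zero cells with a warning."""
    counts = np.asarray(counts)
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    values = (counts > 0).astype(np.int8)
    n_peaks, n_cells = values.shape
    peak_ids = list(peak_ids) if peak_ids is not None else [
        f"peak_{i}" for i in range(n_peaks)]
    cell_ids = list(cell_ids) if cell_ids is not None else [
        f"cell_{j}" for j in range(n_cells)]
    keep = values.sum(axis=0) > 0
    if not keep.all():
        dropped = [c for c, k in zip(cell_ids, keep) if not k]
        logger.warning("dropping %d all-zero cells (e.g. %s)",
                       len(dropped), dropped[:3])
        values = values[:, keep]
        cell_ids = [c for c, k in zip(cell_ids, keep) if k]
        if cell_labels is not None:
            cell_labels = {c: cell_labels[c] for c in cell_ids}
    return BinaryAccessibilityMatrix(values, peak_ids, cell_ids, cell_labels)


def expected_matrix(X: BinaryAccessibilityMatrix) -> np.ndarray:
    """Expected accessibility under independence: E_ij = row_i * col_j / total."""
    V = X.values.astype(float)
    total = V.sum()
    if total <= 0:
        raise ValueError("matrix has no fragments")
    return np.outer(V.sum(axis=1), V.sum(axis=0)) / total


def sample_background_peaks(gc: np.ndarray, mean_accessibility: np.ndarray,
                            n_iterations: int = 50, n_bins: int = 25,
                            seed: int = 0,
                            min_pool: int = 25) -> BackgroundPeakSets:
    """Draw covariate-matched background peaks.

    Peaks are binned on an n_bins x n_bins grid over rank-normalized
    (GC fraction, mean accessibility); each peak draws n_iterations background
    peaks with replacement from its own bin. Sparse bins (including empty
    ones) are expanded ring by ring — nearest bins by Chebyshev distance —
    until the pool holds at least min_pool peaks (or everything). Without the
    floor, tiny pools make the iteration spread of the background statistic
    degenerate and the resulting z-scores explode; with every peak alone in
    its bin the "background" would collapse to the peak itself and void the
    bias correction entirely.
    """
    gc = np.asarray(gc, dtype=float)
    acc = np.asarray(mean_accessibility, dtype=float)
    if not (np.isfinite(gc).all() and np.isfinite(acc).all()):
        raise ValueError("covariates must be finite")
    n = len(gc)
    if len(acc) != n:
        raise ValueError("covariate lengths differ")
    rng = np.random.default_rng(seed)

    def _bin(v: np.ndarray) -> np.ndarray:
        # rank-normalize to (0, 1], then cut into n_bins equal bins
        ranks = pd.Series(v).rank(method="average").to_numpy() / n
        b = np.ceil(ranks * n_bins).astype(int) - 1
        return np.clip(b, 0, n_bins - 1)

    bx, by = _bin(gc), _bin(acc)
    members: dict[tuple[int, int], np.ndarray] = {}
    for key in set(zip(bx, by)):
        members[key] = np.flatnonzero((bx == key[0]) & (by == key[1]))

    pool_cache: dict[tuple[int, int], np.ndarray] = {}

    def _pool(key: tuple[int, int]) -> np.ndarray:
        if key in pool_cache:
            return pool_cache[key]
        parts = [members.get(key, np.empty(0, dtype=int))]
        size = len(parts[0])
        radius = 0
        while size < min(min_pool, n):
            radius += 1
            ring = [
                (key[0] + dx, key[1] + dy)
                for dx in range(-radius, radius + 1)
                for dy in range(-radius, radius + 1)
                if max(abs(dx), abs(dy)) == radius
            ]
            for k2 in sorted(ring):
                if k2 in members:
                    parts.append(members[k2])
                    size += len(members[k2])
        pool = np.sort(np.concatenate(parts)) if len(parts) > 1 else parts[0]
        pool_cache[key] = pool
        return pool

    index = np.empty((n, n_iterations), dtype=int)
    for i in range(n):
        pool = _pool((bx[i], by[i]))
        index[i] = rng.choice(pool, size=n_iterations, replace=True)
    return BackgroundPeakSets(index=index, n_iterations=n_iterations)


def gc_fraction(sequences: list[str]) -> np.ndarray:
    """GC fraction per sequence (helper for synthetic genomes)."""
    out = np.empty(len(sequences))
    for i, s in enumerate(sequences):
        s = s.upper()
        acgt = sum(s.count(b) for b in "ACGT")
        out[i] = (s.count("G") + s.count("C")) / acgt if acgt else 0.0
    return out


def _raw_deviation(AT: sparse.csr_matrix, V: np.ndarray, row_tot: np.ndarray,
                   col_tot: np.ndarray, grand: float) -> np.ndarray:
    """Raw deviations (obs - exp)/exp; the expectation term factorizes as
    E = outer(row_tot, col_tot)/grand, so AT @ E = outer(AT @ row_tot, col_tot)/grand."""
    obs = AT @ V
    exp = np.outer(AT @ row_tot, col_tot) / grand
    with np.errstate(invalid="ignore", divide="ignore"):
        return (obs - exp) / exp


def compute_deviations(X: BinaryAccessibilityMatrix, A: AnnotationMatrix,
                       bg: BackgroundPeakSets) -> DeviationResult:
    """Bias-corrected deviations and z-scores for every feature and cell.

    Features whose expected annotated accessibility is zero (annotating only
    zero-total peaks) are dropped with a warning. Background sd of zero
    yields a NaN z entry unless the deviation is exactly zero there too.
    """
    A = A.drop_empty_features()
    V = X.values.astype(float)
    row_tot = V.sum(axis=1)
    col_tot = V.sum(axis=0)
    grand = V.sum()
    if grand <= 0:
        raise ValueError("matrix has no fragments")
    AT = sparse.csr_matrix(A.membership.T.astype(float))
    bad = np.asarray(AT @ row_tot).ravel() <= 0
    if bad.any():
        logger.warning("dropping %d features with zero expectation", bad.sum())
        AT = AT[~bad]
        feature_ids = [f for f, k in zip(A.feature_ids, ~bad) if k]
    else:
        feature_ids = list(A.feature_ids)
    raw = _raw_deviation(AT, V, row_tot, col_tot, grand)

    n_iter = bg.n_iterations
    mean_bg = np.zeros_like(raw)
    m2_bg = np.zeros_like(raw)
    for t in range(n_iter):
        idx = bg.index[:, t]
        raw_t = _raw_deviation(AT, V[idx], row_tot[idx], col_tot, grand)
        delta = raw_t - mean_bg
        mean_bg += delta / (t + 1)
        m2_bg += delta * (raw_t - mean_bg)
    sd_bg = np.sqrt(m2_bg / (n_iter - 1)) if n_iter > 1 else np.zeros_like(raw)

    deviation = raw - mean_bg
    with np.errstate(invalid="ignore", divide="ignore"):
        zscore = np.where(sd_bg > 0, deviation / sd_bg,
                          np.where(deviation == 0, 0.0, np.nan))
    result = DeviationResult(
        deviation=deviation, zscore=zscore,
        variability=_variability(zscore),
        feature_ids=feature_ids, cell_ids=list(X.cell_ids),
    )
    return result


def _variability(zscore: np.ndarray) -> np.ndarray:
    """Per-feature sd of z across cells; NaN with < 2 defined entries."""
    v = np.full(zscore.shape[0], np.nan)
    for k in range(zscore.shape[0]):
        zk = zscore[k]
        zk = zk[np.isfinite(zk)]
        if len(zk) >= 2:
            v[k] = float(np.std(zk, ddof=1))
    return v


def feature_variability(dev: DeviationResult) -> np.ndarray:
    """Variability score per feature (sd of deviation z-scores across cells)."""
    if dev.zscore.shape[1] < 2:
        raise ValueError("variability needs at least 2 cells")
    return _variability(dev.zscore)


def read_matrix_tsv(path, labels_path=None) -> BinaryAccessibilityMatrix:
    """Read a peaks x cells TSV (first column peak ids, header cell ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    labels = None
    if labels_path is not None:
        meta = pd.read_csv(labels_path, sep="\t", index_col=0)
        labels = meta.iloc[:, 0].to_dict()
    return BinaryAccessibilityMatrix(
        df.to_numpy(), list(df.index.astype(str)),
        list(df.columns.astype(str)), labels)


def write_matrix_tsv(X: BinaryAccessibilityMatrix, path, labels_path=None) -> None:
    X.to_frame().to_csv(path, sep="\t")
    if labels_path is not None and X.cell_labels is not None:
        pd.Series(X.cell_labels, name="cell_type").rename_axis("cell_id") \
            .loc[X.cell_ids].to_frame().to_csv(labels_path, sep="\t")
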