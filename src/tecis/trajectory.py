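"""Branch-wise differential statistics and pseudotime segment profiles.

Trajectory inference itself is an input: each cell arrives with a branch
label and a pseudotime value (plus an optional signed position through the
branching node for display). The statistics are a per-feature two-sided
Mann-Whitney U test between two branches with BH correction, and per-branch
pseudotime profiles obtained by splitting each branch's empirical pseudotime
range into equal-width segments (ten by default) and averaging each feature
within a segment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from tecis.stats import bh_adjust, mannwhitney_u


@dataclass
class PseudotimeTable:
    """cell_id -> (branch_id, pseudotime, optional signed position)."""

    table: pd.DataFrame  # columns: cell_id, branch_id, pseudotime[, signed_position]

    def __post_init__(self):
        required = {"cell_id", "branch_id", "pseudotime"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"pseudotime table missing columns {sorted(missing)}")
        if self.table["cell_id"].duplicated().any():
            raise ValueError("duplicate cell ids in pseudotime table")
        if not np.isfinite(self.table["pseudotime"]).all():
            raise ValueError("pseudotime must be finite")

    def cells_on(self, branch: str) -> pd.DataFrame:
        return self.table[self.table["branch_id"] == branch]

    @classmethod
    def read_tsv(cls, path) -> "PseudotimeTable":
        return cls(pd.read_csv(path, sep="\t"))

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def branch_differential(values: pd.DataFrame, pt: PseudotimeTable,
                        branch_a: str, branch_b: str,
                        log2fold_min: float | None = None) -> pd.DataFrame:
    """Per-feature Mann-Whitney U between two branches, BH across features.

    values is features x cells. Returns (feature, delta_mean, p, q) sorted by
    q; a constant feature gets p = 1. With log2fold_min (for nonnegative
    activity matrices) features below the fold threshold are filtered out.
    """
    cells_a = [c for c in pt.cells_on(branch_a)["cell_id"] if c in values.columns]
    cells_b = [c for c in pt.cells_on(branch_b)["cell_id"] if c in values.columns]
    if len(cells_a) < 2 or len(cells_b) < 2:
        raise ValueError("both branches need at least 2 cells")
    A = values[cells_a].to_numpy(dtype=float)
    B = values[cells_b].to_numpy(dtype=float)
    rows = []
    for k, feature in enumerate(values.index):
        a, b = A[k], B[k]
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if len(a) < 2 or len(b) < 2:
            rows.append((feature, float("nan"), float("nan")))
            continue
        pooled = np.concatenate([a, b])
        if np.all(pooled == pooled[0]):
            rows.append((feature, 0.0, 1.0))
            continue
        _, p = mannwhitney_u(a, b)
        rows.append((feature, float(a.mean() - b.mean()), p))
    df = pd.DataFrame(rows, columns=["feature", "delta_mean", "p"])
    df["q"] = bh_adjust(df["p"].to_numpy())
    if log2fold_min is not None:
        means_a = np.nanmean(A, axis=1)
        means_b = np.nanmean(B, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            lfc = np.log2(means_a / means_b)
        df["log2_fold"] = lfc
        df = df[np.abs(df["log2_fold"]) > log2fold_min]
    return df.sort_values("q", kind="stable").reset_index(drop=True)


def segment_profile(values: pd.DataFrame, pt: PseudotimeTable, branch: str,
                    n_segments: int = 10) -> pd.DataFrame:
    """Per-segment feature means along one branch's pseudotime.

    The branch's empirical pseudotime range [min, max] is split into
    n_segments equal-width bins (last bin right-closed); each feature is
    averaged over the cells in each bin. Empty bins are NaN. Returns a
    features x segments frame whose columns are segment midpoints.
    """
    cells = pt.cells_on(branch)
    cells = cells[cells["cell_id"].isin(values.columns)]
    if len(cells) == 0:
        raise ValueError(f"branch {branch!r} has no cells in the value matrix")
    t = cells["pseudotime"].to_numpy(dtype=float)
    lo, hi = float(t.min()), float(t.max())
    width = (hi - lo) / n_segments if hi > lo else 1.0
    bins = np.minimum(((t - lo) / width).astype(int), n_segments - 1)
    V = values[cells["cell_id"].tolist()].to_numpy(dtype=float)
    out = np.full((values.shape[0], n_segments), np.nan)
    for s in range(n_segments):
        members = bins == s
        if members.any():
            out[:, s] = np.nanmean(V[:, members], axis=1)
    midpoints = lo + (np.arange(n_segments) + 0.5) * width
    return pd.DataFrame(out, index=values.index,
                        columns=[float(m) for m in midpoints])
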