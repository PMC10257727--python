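"""Shared statistical utilities: BH correction, exact tests, report rounding."""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats as _st
from statsmodels.stats.multitest import multipletests


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values (monotone, capped at 1).

    NaN p-values propagate as NaN without affecting the other entries.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def fisher_exact_2x2(a: int, b: int, c: int, d: int):
    """Two-sided Fisher's exact test on the table [[a, b], [c, d]].

    Returns (odds_ratio, p). The odds ratio is the sample ad/bc; NaN when a
    margin is empty or bc == 0 with ad == 0.
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("contingency counts must be nonnegative")
    _, p = _st.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c == 0:
        oratio = math.inf if a * d > 0 else float("nan")
    else:
        oratio = (a * d) / (b * c)
    return oratio, float(p)


def mannwhitney_u(x, y, exact_max_total: int = 16):
    """Two-sided Mann-Whitney U test.

    Small samples (n1 + n2 <= exact_max_total) use exact enumeration of all
    group assignments, which remains valid under ties; larger samples use the
    tie-corrected normal approximation. Returns (U of x, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both groups need at least one observation")
    u_obs = _u_statistic(x, y)
    if n1 + n2 <= exact_max_total:
        pooled = np.concatenate([x, y])
        us = np.array([
            _u_statistic(pooled[list(idx)],
                         pooled[[i for i in range(n1 + n2) if i not in set(idx)]])
            for idx in itertools.combinations(range(n1 + n2), n1)
        ])
        p_le = np.mean(us <= u_obs)
        p_ge = np.mean(us >= u_obs)
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        res = _st.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
    return float(u_obs), float(p)


def _u_statistic(x, y) -> float:
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def robust_z(observed: float, controls) -> float:
    """(observed - median) / (1.4826 * MAD); NaN when MAD is zero."""
    c = np.asarray(controls, dtype=float)
    med = float(np.median(c))
    mad = float(np.median(np.abs(c - med)))
    if mad == 0.0:
        return float("nan")
    return (observed - med) / (1.4826 * mad)


def format_percent(fraction: float) -> str:
    """Report rounding: two significant figures below 10%, integer percent above.

    Matches printed conventions such as 5.2% (63777/1236918) and
    38% (63059/163902).
    """
    pct = fraction * 100.0
    if pct == 0:
        return "0%"
    if pct < 10.0:
        # two significant figures
        ndigits = 1 - int(math.floor(math.log10(abs(pct))))
        return f"{round(pct, ndigits):g}%"
    return f"{round(pct):.0f}%"


def percent_value(fraction: float) -> float:
    """Numeric counterpart of :func:`format_percent` (no '%' suffix)."""
    pct = fraction * 100.0
    if pct == 0:
        return 0.0
    if pct < 10.0:
        ndigits = 1 - int(math.floor(math.log10(abs(pct))))
        return round(pct, ndigits)
    return float(round(pct))
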