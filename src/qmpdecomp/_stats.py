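"""Small shared statistical helpers (rank tests, BH adjustment)."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted P values (NaNs passed through)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def spearman_test(x, y, seed: int = 0, n_perm: int = 10_000, exact_n_max: int = 20):
    """Spearman r with a t-approximation P for n > ``exact_n_max`` and a
    seeded permutation P (``n_perm`` draws) for smaller samples.

    Returns (r, P); r is NaN for constant inputs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, np.nan
    r, p = stats.spearmanr(x, y)
    n = len(x)
    if n <= exact_n_max:
        rng = np.random.default_rng(seed)
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        hits = 0
        for _ in range(n_perm):
            rp = np.corrcoef(rx, rng.permutation(ry))[0, 1]
            if abs(rp) >= abs(r) - 1e-12:
                hits += 1
        p = (hits + 1) / (n_perm + 1)
    return float(r), float(p)


def rank_group_test(values: np.ndarray, groups: np.ndarray, method: str = "auto") -> float:
    """Two-sided rank test across groups: Wilcoxon rank-sum for 2 groups,
    Kruskal-Wallis for more.  Constant values across all groups give P = 1.
    """
    values = np.asarray(values, dtype=float)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    if np.ptp(values) == 0:
        return 1.0
    parts = [values[np.asarray(groups) == g] for g in labels]
    if any(len(p) < 2 for p in parts):
        raise ValueError("each group needs at least 2 observations")
    if len(labels) == 2:
        return float(stats.mannwhitneyu(parts[0], parts[1], alternative="two-sided", method=method).pvalue)
    return float(stats.kruskal(*parts).pvalue)
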