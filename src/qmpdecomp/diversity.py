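"""Diversity, ordination, key decomposers, QMP-vs-RMP trend discordance,
and time-decay succession rates.

The central comparison: the same community profiled as absolute copies per
gram (QMP) and as rarefied relative counts (RMP) can show different — even
opposing — successional trends, because relative abundances are constrained
to a constant sum while the total load moves by orders of magnitude.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio.stats.ordination import pcoa as _skbio_pcoa

from ._stats import bh_adjust, rank_group_test, spearman_test
from .core import AbundanceMatrix

logger = logging.getLogger("qmpdecomp")

#: "before day 7" / "after day 14", both read inclusively
DEFAULT_EARLY_DAYS = (1, 3, 7)
DEFAULT_LATE_DAYS = (14, 21, 28, 35)


def shannon(profile) -> float:
    """Shannon index H = -sum p_i ln p_i (natural log) over positive entries.

    Scale-invariant: rescaling a profile by a positive constant leaves H
    unchanged, so QMP and proportion profiles differ only through
    rarefaction subsampling.
    """
    x = np.asarray(profile, dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be nonnegative")
    total = x.sum()
    if total <= 0:
        raise ValueError("Shannon index undefined for a zero-total profile")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def shannon_table(matrix: AbundanceMatrix) -> pd.Series:
    return pd.Series({s: shannon(matrix.data[s]) for s in matrix.samples}, name="shannon")


def bray_curtis(matrix: AbundanceMatrix) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarities (samples x samples).

    All-zero samples have no defined distance to anything and are dropped
    with a log entry.
    """
    totals = matrix.data.sum(axis=0)
    drop = totals.index[totals <= 0]
    if len(drop):
        logger.warning("Bray-Curtis drops %d all-zero samples: %s", len(drop), list(drop)[:5])
    keep = totals.index[totals > 0]
    if len(keep) < 2:
        raise ValueError("need at least 2 non-empty samples")
    d = squareform(pdist(matrix.data[keep].T.to_numpy(dtype=float), metric="braycurtis"))
    return pd.DataFrame(d, index=keep, columns=keep)


def pcoa(distance: pd.DataFrame, n_axes: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal coordinates: eigendecomposition of the double-centred
    -d^2/2 matrix; axes ordered by eigenvalue, relative eigenvalues
    reported against the sum of positive eigenvalues."""
    res = _skbio_pcoa(distance.to_numpy(), number_of_dimensions=min(n_axes, len(distance) - 1))
    scores = pd.DataFrame(
        res.samples.to_numpy()[:, :n_axes],
        index=distance.index,
        columns=[f"PCo{i + 1}" for i in range(min(n_axes, res.samples.shape[1]))],
    )
    eig = res.eigvals.to_numpy()
    rel = eig[: scores.shape[1]] / eig[eig > 0].sum()
    return scores, rel


def group_tests(values: pd.DataFrame, groups: pd.Series, method: str = "auto") -> pd.DataFrame:
    """Per-feature two-sided rank tests across groups with BH correction.

    Wilcoxon rank-sum for two groups, Kruskal-Wallis otherwise; the BH
    family is the feature set being tested.
    """
    g = groups.reindex(values.columns).to_numpy()
    pvals = [rank_group_test(values.loc[f].to_numpy(dtype=float), g, method=method) for f in values.index]
    return pd.DataFrame({"p_value": pvals, "p_adjusted": bh_adjust(pvals)}, index=values.index)


def identify_key_decomposers(
    matrix: AbundanceMatrix,
    pmi_days: pd.Series,
    r_min: float = 0.6,
    p_max: float = 0.001,
    seed: int = 0,
) -> pd.DataFrame:
    """Genera whose absolute abundance correlates positively with PMI.

    Spearman r of each genus's copies per gram against PMI day; a key
    decomposer satisfies r > ``r_min`` and P < ``p_max``.  Constant genera
    (r undefined) are excluded.
    """
    if matrix.data.shape[1] < 10:
        raise ValueError("need at least 10 samples")
    days = pmi_days.reindex(matrix.samples).to_numpy(dtype=float)
    recs = []
    for taxon in matrix.taxa:
        r, p = spearman_test(matrix.data.loc[taxon].to_numpy(dtype=float), days, seed=seed)
        if np.isnan(r):
            continue
        recs.append({"genus": taxon, "r": r, "p_value": p, "key_decomposer": (r > r_min) and (p < p_max)})
    return pd.DataFrame(recs).set_index("genus")


# ---------------------------------------------------------------------------
# QMP vs RMP trend discordance


@dataclass(frozen=True)
class TrendVerdict:
    genus: str
    qmp_direction: str          # up / down / ns
    rmp_direction: str
    qmp_p_adjusted: float
    rmp_p_adjusted: float
    classification: str


def classify_trend(qmp_direction: str, rmp_direction: str) -> str:
    """Pure classification of a (QMP, RMP) direction pair.

    QMP is the reference measure (absolute abundance is not subject to the
    constant-sum constraint), so a significant RMP trend that QMP does not
    confirm in the same direction is a compositional artifact and counts as
    ``contrasting``; a significant QMP trend that RMP misses is
    ``qmp_only`` (RMP blindness).  ``rmp_only`` is reserved for the
    symmetric reading and is not produced by this QMP-referenced scheme.
    """
    q_sig, r_sig = qmp_direction != "ns", rmp_direction != "ns"
    if q_sig and r_sig:
        return "concordant" if qmp_direction == rmp_direction else "contrasting"
    if r_sig:
        return "contrasting"
    if q_sig:
        return "qmp_only"
    return "neither"


def _directions(values: pd.DataFrame, early: np.ndarray, late: np.ndarray) -> tuple[pd.Series, pd.Series]:
    pvals, medsign = [], []
    for taxon in values.index:
        v = values.loc[taxon].to_numpy(dtype=float)
        pvals.append(rank_group_test(v, np.where(early, "early", "late")))
        medsign.append(np.sign(np.median(v[late]) - np.median(v[early])))
    return pd.Series(bh_adjust(pvals), index=values.index), pd.Series(medsign, index=values.index)


def trend_discordance(
    qmp: AbundanceMatrix,
    rmp: AbundanceMatrix,
    pmi_days: pd.Series,
    early_days=DEFAULT_EARLY_DAYS,
    late_days=DEFAULT_LATE_DAYS,
    top_n: int = 100,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Early-vs-late Wilcoxon comparison of the top genera under QMP and RMP.

    The ``top_n`` genera are ranked by mean QMP abundance (ties broken
    lexicographically).  Each is tested early vs late separately on the QMP
    and RMP values, BH-corrected within the top set per mode; directions
    come from the median difference.  Genera absent from the RMP matrix are
    classified ``neither`` with a warning.
    """
    shared = qmp.samples.intersection(rmp.samples)
    if len(shared) < 4:
        raise ValueError("QMP and RMP matrices share too few samples")
    days = pmi_days.reindex(shared)
    early = days.isin(early_days).to_numpy()
    late = days.isin(late_days).to_numpy()
    if early.sum() < 2 or late.sum() < 2:
        raise ValueError("early/late groups must each contain >= 2 samples")
    keep = early | late
    shared = shared[keep]
    early, late = early[keep], late[keep]

    rank = qmp.data[shared].mean(axis=1).sort_values(ascending=False, kind="mergesort")
    # lexicographic tie-break within equal means
    order = sorted(rank.index, key=lambda t: (-rank[t], str(t)))
    top = pd.Index(order[:top_n])
    missing = top.difference(rmp.taxa)
    if len(missing):
        logger.warning("%d top genera absent from the RMP matrix -> 'neither'", len(missing))
    common = top.intersection(rmp.taxa)

    q_padj, q_sign = _directions(qmp.data.loc[top, shared], early, late)
    r_padj, r_sign = _directions(rmp.data.loc[common, shared], early, late)

    def direction(sign: float, padj: float) -> str:
        if np.isnan(padj) or padj >= alpha or sign == 0:
            return "ns"
        return "up" if sign > 0 else "down"

    rows = []
    for genus in top:
        qd = direction(q_sign[genus], q_padj[genus])
        if genus in common:
            rd = direction(r_sign[genus], r_padj[genus])
            cls = classify_trend(qd, rd)
            rp = r_padj[genus]
        else:
            rd, cls, rp = "ns", "neither", np.nan
        rows.append(
            {
                "genus": genus,
                "qmp_direction": qd,
                "rmp_direction": rd,
                "qmp_p_adjusted": q_padj[genus],
                "rmp_p_adjusted": rp,
                "classification": cls,
            }
        )
    return pd.DataFrame(rows).set_index("genus")


def time_decay(
    distance: pd.DataFrame,
    pmi_days: pd.Series,
    log_similarity: bool = False,
) -> dict:
    """Succession rate: OLS of community similarity (1 - Bray-Curtis) on the
    temporal interval |delta day| over all sample pairs.

    Returns slope (the succession rate), intercept, P (regression F-test,
    equivalently the slope t-test) and the pair count.
    """
    days = pmi_days.reindex(distance.index).to_numpy(dtype=float)
    iu = np.triu_indices(len(distance), k=1)
    dt = np.abs(days[iu[0]] - days[iu[1]])
    sim = 1.0 - distance.to_numpy()[iu]
    if len(np.unique(dt)) < 3:
        raise ValueError("time-decay needs >= 3 distinct time intervals")
    if log_similarity:
        if (sim <= 0).any():
            logger.warning("dropping %d nonpositive similarities before log transform", int((sim <= 0).sum()))
        keep = sim > 0
        dt, sim = dt[keep], np.log(sim[keep])
    res = stats.linregress(dt, sim)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "p_value": float(res.pvalue),
        "r_squared": float(res.rvalue**2),
        "n_pairs": int(len(dt)),
    }
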