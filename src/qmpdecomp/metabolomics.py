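"""Untargeted metabolome analysis: normalisation, PCA, PLS-DA/VIP, and
PMI-correlated metabolite clusters.

Feature tables are nonnegative intensities, features x samples, with a
chemical superclass label per feature.  Preprocessing follows the standard
metabolomics recipe: per-sample sum normalisation followed by Pareto
scaling (centre each feature, divide by the square root of its standard
deviation), which tempers the dominance of high-intensity features without
the noise inflation of unit-variance scaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA

from ._stats import bh_adjust, rank_group_test, spearman_test

logger = logging.getLogger("qmpdecomp")

NORMALIZATION_STATES = ("raw", "sum_normalized", "pareto_scaled")


@dataclass
class MetaboliteMatrix:
    """Metabolite features x samples with superclass labels."""

    data: pd.DataFrame
    superclass: pd.Series
    state: str = "raw"
    flagged_zero_variance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.state not in NORMALIZATION_STATES:
            raise ValueError(f"unknown normalization state {self.state!r}")
        if self.state == "raw" and (self.data.to_numpy() < 0).any():
            raise ValueError("raw intensities must be nonnegative")
        if not self.superclass.index.equals(self.data.index):
            self.superclass = self.superclass.reindex(self.data.index)

    @property
    def features(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns


def sum_normalize(matrix: MetaboliteMatrix) -> MetaboliteMatrix:
    """Divide each sample column by its total intensity (columns sum to 1)."""
    totals = matrix.data.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("sum normalisation needs positive column sums")
    return MetaboliteMatrix(matrix.data / totals, matrix.superclass, state="sum_normalized")


def pareto_scale(matrix: MetaboliteMatrix) -> MetaboliteMatrix:
    """Centre each feature and divide by sqrt(SD); zero-variance features
    are centred only and flagged."""
    centred = matrix.data.sub(matrix.data.mean(axis=1), axis=0)
    sd = matrix.data.std(axis=1, ddof=1)
    flat = sd.index[sd == 0]
    if len(flat):
        logger.warning("%d zero-variance features centred but not scaled", len(flat))
    divisor = np.sqrt(sd.where(sd > 0, 1.0))
    return MetaboliteMatrix(
        centred.div(divisor, axis=0),
        matrix.superclass,
        state="pareto_scaled",
        flagged_zero_variance=list(flat),
    )


def normalize(matrix: MetaboliteMatrix) -> MetaboliteMatrix:
    """Sum-normalise then Pareto-scale a raw feature table."""
    if matrix.state != "raw":
        raise ValueError("normalize expects a raw feature table")
    return pareto_scale(sum_normalize(matrix))


def pca(matrix: MetaboliteMatrix, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Centred PCA of samples; returns scores and explained-variance fractions."""
    X = matrix.data.T.to_numpy(dtype=float)
    n_components = min(n_components, min(X.shape) - 1) or 1
    model = PCA(n_components=n_components)
    scores = model.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return pd.DataFrame(scores, index=matrix.samples, columns=cols), model.explained_variance_ratio_


@dataclass
class PlsdaModel:
    """A fitted PLS-DA: one-hot group responses regressed on features."""

    scores: pd.DataFrame            # samples x components
    weights: pd.DataFrame           # features x components (unit norm per component)
    y_loadings: np.ndarray          # groups x components
    groups: pd.Series               # sample -> class label
    explained_y: np.ndarray         # fraction of Y variance per component
    vip: pd.Series                  # per-feature variable importance in projection


def plsda(matrix: MetaboliteMatrix, groups: pd.Series, n_components: int = 2) -> PlsdaModel:
    """PLS-DA on one-hot class coding; reports per-component explained Y
    variance and VIP scores.

    VIP_j = sqrt(p * sum_a SSY_a w_ja^2 / sum_a SSY_a) with unit-norm
    component weights w_a, so sum_j VIP_j^2 = p (the feature count).
    """
    groups = groups.reindex(matrix.samples)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("PLS-DA needs at least 2 groups")
    sizes = groups.value_counts()
    if (sizes < 2).any():
        logger.warning("groups with a single sample retained: %s", list(sizes.index[sizes < 2]))
    X = matrix.data.T.to_numpy(dtype=float)
    n, p = X.shape
    if not 1 <= n_components < min(n, p + 1):
        raise ValueError("n_components must be >= 1 and < min(samples, features)")
    Y = pd.get_dummies(groups).astype(float).to_numpy()
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(X, Y)
    T = pls.x_scores_
    W = pls.x_weights_            # columns are unit norm
    Q = pls.y_loadings_
    Yc = Y - Y.mean(axis=0)
    ssy_total = float((Yc**2).sum())
    if ssy_total == 0:
        raise ValueError("zero total Y variance")
    ssy = np.array([(T[:, a] ** 2).sum() * (Q[:, a] ** 2).sum() for a in range(n_components)])
    w2 = W**2
    vip = np.sqrt(p * (w2 @ ssy) / ssy.sum())
    comp_cols = [f"comp{a + 1}" for a in range(n_components)]
    return PlsdaModel(
        scores=pd.DataFrame(T, index=matrix.samples, columns=comp_cols),
        weights=pd.DataFrame(W, index=matrix.features, columns=comp_cols),
        y_loadings=Q,
        groups=groups,
        explained_y=ssy / ssy_total,
        vip=pd.Series(vip, index=matrix.features, name="VIP"),
    )


def vip_select(
    model: PlsdaModel,
    matrix: MetaboliteMatrix,
    vip_min: float = 1.5,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Rank features by VIP and attach a per-feature Kruskal-Wallis P value
    across groups (BH-adjusted); select VIP > ``vip_min`` and P < ``p_max``.
    """
    groups = model.groups.reindex(matrix.samples).to_numpy()
    pvals = np.array(
        [rank_group_test(matrix.data.loc[f].to_numpy(dtype=float), groups) for f in matrix.features]
    )
    table = pd.DataFrame(
        {
            "VIP": model.vip.reindex(matrix.features),
            "p_value": pvals,
            "p_adjusted": bh_adjust(pvals),
            "superclass": matrix.superclass,
        }
    ).sort_values("VIP", ascending=False)
    table["selected"] = (table["VIP"] > vip_min) & (table["p_adjusted"] < p_max)
    return table


def pmi_correlated_metabolites(
    matrix: MetaboliteMatrix,
    pmi_days: pd.Series,
    r_min: float = 0.6,
    p_max: float = 0.001,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[int, pd.Series]]:
    """Metabolites significantly correlated with PMI, split into a positive
    and a negative cluster.

    Selection: Spearman |r| > ``r_min`` and P < ``p_max`` per feature.
    Selected features are split by Ward hierarchical clustering of their
    z-scored per-day mean trajectories into two clusters; cluster signs are
    assigned by mean correlation.  Returns the per-feature table (r, P,
    cluster) and per-cluster superclass percentage breakdowns.
    """
    if matrix.data.shape[1] < 10:
        raise ValueError("need at least 10 samples")
    days = pmi_days.reindex(matrix.samples).to_numpy(dtype=float)
    recs = []
    for feat in matrix.features:
        r, p = spearman_test(matrix.data.loc[feat].to_numpy(dtype=float), days, seed=seed)
        recs.append({"feature": feat, "r": r, "p_value": p})
    table = pd.DataFrame(recs).set_index("feature")
    table["superclass"] = matrix.superclass
    table["selected"] = (table["r"].abs() > r_min) & (table["p_value"] < p_max)
    selected = table.index[table["selected"]]
    table["cluster"] = 0
    if len(selected) < 2:
        logger.warning("fewer than 2 PMI-correlated metabolites: no clustering performed")
        return table, {}

    day_levels = np.unique(days)
    prof = np.vstack(
        [
            [matrix.data.loc[f].to_numpy(dtype=float)[days == d].mean() for d in day_levels]
            for f in selected
        ]
    )
    prof = (prof - prof.mean(axis=1, keepdims=True)) / np.where(
        prof.std(axis=1, keepdims=True) > 0, prof.std(axis=1, keepdims=True), 1.0
    )
    assign = fcluster(linkage(prof, method="ward"), t=2, criterion="maxclust")
    # label the cluster with the higher mean PMI correlation as positive (cluster 2,
    # matching the convention negative = cluster 1)
    mean_r = {c: table.loc[selected[assign == c], "r"].mean() for c in (1, 2)}
    pos_c = max(mean_r, key=mean_r.get)
    relabel = {pos_c: 2, ({1, 2} - {pos_c}).pop(): 1}
    table.loc[selected, "cluster"] = [relabel[c] for c in assign]
    composition = {}
    for c in (1, 2):
        members = table.index[table["cluster"] == c]
        if len(members):
            composition[c] = (
                table.loc[members, "superclass"].value_counts(normalize=True).mul(100.0)
            )
    return table, composition
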