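"""Microbiota-metabolite concordance: Procrustes, Mantel/partial Mantel,
redundancy analysis (RDA), and random-forest metabolite association.

These are the association analyses that ask whether, and which, microbial
community structure covaries with the tissue metabolome — e.g. whether the
bacterial community carries more independent metabolite signal than the
fungal one once the other domain is controlled for (partial Mantel).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import procrustes as _scipy_procrustes
from sklearn.decomposition import PCA

from .core import subseeds
from .pmi import inc_mse_importance, rf_train

logger = logging.getLogger("qmpdecomp")


@dataclass
class ProcrustesResult:
    """Optimal superimposition of two ordination configurations.

    ``m2`` is the minimised residual sum of squares after centring, unit
    trace scaling and optimal rotation (0 <= m2 <= 1); ``r = sqrt(1 - m2)``.
    """

    m2: float
    r: float
    residuals: pd.Series
    p_value: float | None
    n_permutations: int
    seed: int | None


@dataclass
class MantelResult:
    r: float
    p_value: float | None
    n_permutations: int
    method: str
    controlled: str | None = None


def procrustes(
    config_x: pd.DataFrame,
    config_y: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> ProcrustesResult:
    """Symmetric Procrustes of two sample configurations (e.g. the first
    two ordination axes of each block).

    Both configurations are centred and scaled to unit trace; the optimal
    rotation comes from an SVD, so M^2 = 1 - (sum of singular values)^2.
    The permutation P value is the fraction of row permutations of Y whose
    M^2 is <= the observed one.
    """
    if not config_x.index.equals(config_y.index):
        shared = config_x.index.intersection(config_y.index)
        if len(shared) < 3:
            raise ValueError("Procrustes needs >= 3 shared samples")
        config_x, config_y = config_x.loc[shared], config_y.loc[shared]
    if len(config_x) < 3:
        raise ValueError("Procrustes needs >= 3 samples")
    X = config_x.to_numpy(dtype=float)
    Y = config_y.to_numpy(dtype=float)
    mx, my, m2 = _scipy_procrustes(X, Y)
    residuals = pd.Series(np.linalg.norm(mx - my, axis=1), index=config_x.index, name="residual")
    p = None
    if n_perm:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            _, _, m2p = _scipy_procrustes(X, Y[rng.permutation(len(Y))])
            if m2p <= m2 + 1e-12:
                hits += 1
        p = (hits + 1) / (n_perm + 1)
    return ProcrustesResult(
        m2=float(m2), r=float(np.sqrt(max(0.0, 1.0 - m2))), residuals=residuals,
        p_value=p, n_permutations=n_perm, seed=seed,
    )


def _triangle(d: pd.DataFrame) -> np.ndarray:
    arr = d.to_numpy(dtype=float)
    if arr.shape[0] != arr.shape[1] or not np.allclose(arr, arr.T):
        raise ValueError("distance matrix must be square and symmetric")
    return arr[np.triu_indices(len(arr), k=1)]


def _corr(a: np.ndarray, b: np.ndarray, method: str) -> float:
    if method == "spearman":
        a, b = stats.rankdata(a), stats.rankdata(b)
    elif method != "pearson":
        raise ValueError("method must be 'pearson' or 'spearman'")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant distance matrix: Mantel r undefined")
    return float(np.corrcoef(a, b)[0, 1])


def mantel(
    dx: pd.DataFrame,
    dy: pd.DataFrame,
    method: str = "pearson",
    n_perm: int = 999,
    seed: int = 0,
) -> MantelResult:
    """Mantel test: correlation of the upper triangles of two distance
    matrices, with a one-sided (greater) P value from simultaneous
    row/column permutations of ``dx``."""
    if not dx.index.equals(dy.index):
        raise ValueError("distance matrices must share sample order")
    r = _corr(_triangle(dx), _triangle(dy), method)
    p = None
    if n_perm:
        rng = np.random.default_rng(seed)
        ty = _triangle(dy)
        arr = dx.to_numpy(dtype=float)
        iu = np.triu_indices(len(arr), k=1)
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(len(arr))
            rp = _corr(arr[np.ix_(perm, perm)][iu], ty, method)
            if rp >= r - 1e-12:
                hits += 1
        p = (hits + 1) / (n_perm + 1)
    return MantelResult(r=r, p_value=p, n_permutations=n_perm, method=method)


def partial_mantel(
    dx: pd.DataFrame,
    dy: pd.DataFrame,
    dz: pd.DataFrame,
    method: str = "pearson",
    n_perm: int = 999,
    seed: int = 0,
    controlled_name: str = "dz",
) -> MantelResult:
    """Partial Mantel: correlation of dx and dy controlling for dz via the
    first-order partial correlation of the upper triangles; P from
    simultaneous row/column permutations of ``dx``."""
    for other in (dy, dz):
        if not dx.index.equals(other.index):
            raise ValueError("distance matrices must share sample order")
    tx, ty, tz = (_triangle(d) for d in (dx, dy, dz))
    if method == "spearman":
        tx, ty, tz = (stats.rankdata(t) for t in (tx, ty, tz))

    def partial_r(a: np.ndarray) -> float:
        r_ab = _corr(a, ty, "pearson")
        r_ac = _corr(a, tz, "pearson")
        r_bc = _corr(ty, tz, "pearson")
        denom = np.sqrt((1 - r_ac**2) * (1 - r_bc**2))
        if denom == 0:
            raise ValueError("degenerate partial Mantel: controlling matrix fully explains one input")
        return (r_ab - r_ac * r_bc) / denom

    r = float(partial_r(tx))
    p = None
    if n_perm:
        rng = np.random.default_rng(seed)
        arr = dx.to_numpy(dtype=float)
        if method == "spearman":
            arr = stats.rankdata(arr).reshape(arr.shape)
        iu = np.triu_indices(len(arr), k=1)
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(len(arr))
            if partial_r(arr[np.ix_(perm, perm)][iu]) >= r - 1e-12:
                hits += 1
        p = (hits + 1) / (n_perm + 1)
    return MantelResult(r=r, p_value=p, n_permutations=n_perm, method=method, controlled=controlled_name)


def rda(
    response: pd.DataFrame,
    explanatory: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> dict:
    """Redundancy analysis: PCA of the fitted values from a multivariate
    linear regression of the (centred) response on the standardized
    explanatory table.

    Reports total/constrained/unconstrained inertia, axis scores, biplot
    scores, and a per-variable table with marginal contribution (the
    constrained inertia fraction of that variable alone) and a permutation
    P value (permuting that variable's values).  Collinear explanatory
    columns trigger a condition warning; the pseudo-inverse is used.
    """
    shared = response.index.intersection(explanatory.index)
    if len(shared) < 3:
        raise ValueError("RDA needs >= 3 shared samples")
    Y = response.loc[shared].to_numpy(dtype=float)
    Y = Y - Y.mean(axis=0)
    Xdf = explanatory.loc[shared]
    sd = Xdf.std(axis=0, ddof=0)
    const = sd.index[sd == 0]
    if len(const):
        logger.warning("dropping constant explanatory variables: %s", list(const))
        Xdf = Xdf.drop(columns=const)
        sd = sd.drop(const)
    X = ((Xdf - Xdf.mean(axis=0)) / sd).to_numpy(dtype=float)
    n = len(shared)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        logger.warning("collinear explanatory columns: using pseudo-inverse")

    def constrained_inertia(Xm: np.ndarray) -> float:
        fitted = Xm @ np.linalg.pinv(Xm) @ Y
        return float((fitted**2).sum()) / (n - 1)

    total = float((Y**2).sum()) / (n - 1)
    fitted = X @ np.linalg.pinv(X) @ Y
    constrained = float((fitted**2).sum()) / (n - 1)
    k = min(2, X.shape[1], n - 1)
    pca_model = PCA(n_components=k)
    site_scores = pca_model.fit_transform(fitted)
    biplot = pd.DataFrame(
        np.array([[np.corrcoef(X[:, j], site_scores[:, a])[0, 1] for a in range(k)] for j in range(X.shape[1])]),
        index=Xdf.columns,
        columns=[f"RDA{a + 1}" for a in range(k)],
    )
    rng = np.random.default_rng(seed)
    rows = []
    for j, var in enumerate(Xdf.columns):
        xj = X[:, [j]]
        marg = constrained_inertia(xj)
        p = None
        if n_perm:
            hits = 0
            for _ in range(n_perm):
                if constrained_inertia(xj[rng.permutation(n)]) >= marg - 1e-12:
                    hits += 1
            p = (hits + 1) / (n_perm + 1)
        rows.append({"variable": var, "marginal_inertia": marg, "marginal_fraction": marg / total, "p_value": p})
    variables = pd.DataFrame(rows).set_index("variable").sort_values("marginal_inertia", ascending=False)
    return {
        "total_inertia": total,
        "constrained_inertia": constrained,
        "unconstrained_inertia": total - constrained,
        "constrained_fraction": constrained / total,
        "site_scores": pd.DataFrame(site_scores, index=shared, columns=biplot.columns),
        "biplot_scores": biplot,
        "variables": variables,
        "top_variable": variables.index[0] if len(variables) else None,
    }


def rf_metabolite_association(
    metabolite_data: pd.DataFrame,
    microbial_summary: pd.Series,
    superclass: pd.Series | None = None,
    top_k: int = 20,
    n_trees: int = 500,
    seed: int = 0,
) -> dict:
    """Metabolites most associated with a domain's abundance summary.

    Fits a regression forest of the per-sample microbial summary (by
    convention log10 total copies per gram of the domain) on the metabolite
    features and ranks features by out-of-bag IncMSE.  Returns the ranked
    table and the top-``top_k`` features (full list if fewer exist), with
    superclass labels when given.
    """
    shared = metabolite_data.columns.intersection(microbial_summary.index)
    if len(shared) < 5:
        raise ValueError("too few shared samples")
    X = metabolite_data[shared].T
    y = microbial_summary.loc[shared]
    s_fit, s_imp = subseeds(seed, 2)
    model = rf_train(X, y, n_trees=n_trees, seed=s_fit)
    imp = inc_mse_importance(model, X, y, seed=s_imp).sort_values(ascending=False)
    k = min(top_k, len(imp))
    if k < top_k:
        logger.warning("only %d features available (< top_k=%d): full list returned", k, top_k)
    table = imp.to_frame()
    if superclass is not None:
        table["superclass"] = superclass.reindex(table.index)
    return {"importance": table, "top_features": list(imp.index[:k])}


def top_class_intersection(assoc_a: dict, assoc_b: dict) -> set:
    """Metabolite classes shared between two domains' top association lists."""

    def classes(assoc: dict) -> set:
        tab = assoc["importance"]
        if "superclass" not in tab:
            return set(assoc["top_features"])
        return set(tab.loc[assoc["top_features"], "superclass"].dropna())

    return classes(assoc_a) & classes(assoc_b)
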