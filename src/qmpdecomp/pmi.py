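"""Postmortem-interval regression with random forests.

The workflow mirrors forensic PMI modelling practice: a stratified 2:1
train/test split within each exhumation day, a 1000-tree regression forest,
permutation importance (IncMSE: the increase in mean squared error when one
feature's values are permuted while the others are held fixed, evaluated
out-of-bag), biomarker-set optimisation by ranking features on IncMSE and
scanning top-k subsets with repeated 10-fold cross-validation, and repeated
evaluation (default 100 forest reseeds on the fixed split) reporting
MAE and R^2 as mean +/- SD in days.

Feature tables here are samples x features (the fitting convention);
abundance matrices are transposed on the way in.  Random forests are
invariant to monotone per-feature transforms, so QMP copies per gram and
rarefied counts can be fed directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import RepeatedKFold

from .core import AbundanceMatrix, subseeds

logger = logging.getLogger("qmpdecomp")

DEFAULT_K_GRID = (1, 2, 3, 5, 8, 10, 15, 20, 30, 50)


@dataclass(frozen=True)
class SplitPlan:
    """Per-time-point assignment of replicate samples to train/test."""

    train: pd.Index
    test: pd.Index
    ratio: tuple[int, int]
    seed: int

    def __post_init__(self) -> None:
        if len(self.train.intersection(self.test)):
            raise ValueError("train and test sets overlap")


@dataclass
class ModelEvaluation:
    """MAE / R^2 mean +/- SD over repeated forest refits on a fixed split."""

    train_mae: tuple[float, float]
    test_mae: tuple[float, float] | None
    train_r2: tuple[float, float]
    test_r2: tuple[float, float] | None
    n_runs: int
    features: list[str] = field(default_factory=list)


def features_from_abundance(matrix: AbundanceMatrix, min_prevalence: int = 3) -> pd.DataFrame:
    """Samples x features table from a taxa x samples matrix, keeping
    features present (nonzero) in at least ``min_prevalence`` samples."""
    present = (matrix.data > 0).sum(axis=1)
    keep = present.index[present >= min_prevalence]
    if len(keep) < len(matrix.taxa):
        logger.info("prevalence filter keeps %d/%d features", len(keep), len(matrix.taxa))
    return matrix.data.loc[keep].T


def stratified_split(metadata: pd.DataFrame, ratio: tuple[int, int] = (2, 1), seed: int = 0) -> SplitPlan:
    """Assign replicates to train/test at ``ratio`` within each PMI day.

    Deterministic given ``seed``; each stratum must divide exactly by the
    ratio (e.g. 6 replicates at 2:1 -> 4 train, 2 test), otherwise the
    offending stratum is named in the error.
    """
    r_train, r_test = ratio
    if r_train <= 0 or r_test < 0:
        raise ValueError("ratio parts must be positive (test part may be 0)")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for day, group in metadata.groupby("day"):
        n = len(group)
        denom = r_train + r_test
        if n % denom:
            raise ValueError(f"stratum day={day}: {n} replicates do not divide at ratio {r_train}:{r_test}")
        n_train = n * r_train // denom
        order = rng.permutation(group.index.to_numpy())
        train.extend(order[:n_train])
        test.extend(order[n_train:])
    return SplitPlan(train=pd.Index(train), test=pd.Index(test), ratio=ratio, seed=seed)


def rf_train(
    features: pd.DataFrame,
    pmi_days: pd.Series,
    n_trees: int = 1000,
    seed: int = 0,
) -> RandomForestRegressor:
    """Fit a seeded regression forest of PMI day on the feature table."""
    y = pmi_days.reindex(features.index)
    if y.isna().any():
        raise ValueError("every sample needs a PMI day")
    if len(features) < 2:
        raise ValueError("need at least 2 training samples")
    model = RandomForestRegressor(n_estimators=n_trees, random_state=seed, bootstrap=True)
    model.fit(features.to_numpy(dtype=float), y.to_numpy(dtype=float))
    return model


def inc_mse_importance(
    model: RandomForestRegressor,
    features: pd.DataFrame,
    pmi_days: pd.Series,
    seed: int = 0,
    n_repeats: int = 3,
    out_of_bag: bool = True,
) -> pd.Series:
    """IncMSE per feature: MSE increase after permuting that feature.

    By default the error is evaluated on each tree's out-of-bag samples
    (the training rows it never saw), averaged over trees and permutation
    repeats; with ``out_of_bag=False`` the supplied table is treated as
    held-out data and all trees are evaluated on all rows.  Permuting a
    constant feature changes nothing, so its IncMSE is exactly 0.
    """
    rng = np.random.default_rng(seed)
    X = features.to_numpy(dtype=float)
    y = pmi_days.reindex(features.index).to_numpy(dtype=float)
    n, p = X.shape
    trees = model.estimators_
    if out_of_bag:
        oob_masks = []
        for inbag in model.estimators_samples_:
            mask = np.ones(n, dtype=bool)
            mask[inbag] = False
            oob_masks.append(mask)
    else:
        oob_masks = [np.ones(n, dtype=bool)] * len(trees)
    base_preds = np.stack([t.predict(X) for t in trees])
    base_mse = np.array(
        [((base_preds[i, m] - y[m]) ** 2).mean() if m.any() else np.nan for i, m in enumerate(oob_masks)]
    )
    uses = [set(t.tree_.feature[t.tree_.feature >= 0]) for t in trees]
    inc = np.zeros(p)
    for j in range(p):
        if np.ptp(X[:, j]) == 0:
            continue
        deltas = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(n), j]
            for i, tree in enumerate(trees):
                m = oob_masks[i]
                if not m.any() or np.isnan(base_mse[i]):
                    continue
                if j not in uses[i]:
                    deltas.append(0.0)
                    continue
                mse = ((tree.predict(Xp[m]) - y[m]) ** 2).mean()
                deltas.append(mse - base_mse[i])
        inc[j] = float(np.mean(deltas)) if deltas else 0.0
    return pd.Series(inc, index=features.columns, name="IncMSE")


def optimize_biomarkers(
    features: pd.DataFrame,
    pmi_days: pd.Series,
    k_folds: int = 10,
    repeats: int = 5,
    n_trees: int = 1000,
    seed: int = 0,
    k_grid: tuple[int, ...] | None = None,
    importance_repeats: int = 3,
) -> dict:
    """Rank features by IncMSE, scan top-k subsets by repeated k-fold CV,
    and return the subset minimising mean CV MAE with the full error curve.

    The k-grid is log-spaced ({1,2,3,5,8,...}, capped at the feature count)
    to bound runtime.  By construction the chosen subset's CV error is the
    minimum over the scanned grid, hence <= that of the full feature set
    whenever the full set is on the grid.
    """
    y = pmi_days.reindex(features.index)
    n, p = features.shape
    if k_folds > n:
        raise ValueError("k_folds exceeds the number of samples")
    s_fit, s_imp, s_cv = subseeds(seed, 3)
    model = rf_train(features, y, n_trees=n_trees, seed=s_fit)
    importance = inc_mse_importance(model, features, y, seed=s_imp, n_repeats=importance_repeats)
    ranked = importance.sort_values(ascending=False).index
    grid = sorted({min(k, p) for k in (k_grid or (*DEFAULT_K_GRID, p)) if k >= 1})
    cv = RepeatedKFold(n_splits=k_folds, n_repeats=repeats, random_state=s_cv)
    ynp = y.to_numpy(dtype=float)
    curve = {}
    for k in grid:
        Xk = features[ranked[:k]].to_numpy(dtype=float)
        errs = []
        for f, (tr, te) in enumerate(cv.split(Xk)):
            rf = RandomForestRegressor(n_estimators=n_trees, random_state=s_cv + f)
            rf.fit(Xk[tr], ynp[tr])
            errs.append(np.abs(rf.predict(Xk[te]) - ynp[te]).mean())
        curve[k] = float(np.mean(errs))
    best_k = min(curve, key=lambda k: (curve[k], k))
    return {
        "importance": importance,
        "ranked": list(ranked),
        "k_grid": grid,
        "cv_curve": curve,
        "best_k": best_k,
        "selected": list(ranked[:best_k]),
    }


def _metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float]:
    mae = float(np.abs(y_pred - y_true).mean())
    sst = float(((y_true - y_true.mean()) ** 2).sum())
    r2 = 1.0 - float(((y_pred - y_true) ** 2).sum()) / sst if sst > 0 else np.nan
    return mae, r2


def evaluate(
    features: pd.DataFrame,
    pmi_days: pd.Series,
    split: SplitPlan,
    n_runs: int = 100,
    n_trees: int = 1000,
    seed: int = 0,
) -> ModelEvaluation:
    """Refit the forest ``n_runs`` times with fresh seeds on the fixed
    split; report train and test MAE and R^2 as mean +/- SD."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    y = pmi_days.reindex(features.index)
    Xtr = features.loc[split.train]
    ytr = y.loc[split.train].to_numpy(dtype=float)
    has_test = len(split.test) > 0
    if not has_test:
        logger.warning("empty test set: test metrics omitted")
    Xte = features.loc[split.test] if has_test else None
    yte = y.loc[split.test].to_numpy(dtype=float) if has_test else None
    tr_mae, tr_r2, te_mae, te_r2 = [], [], [], []
    for run_seed in subseeds(seed, n_runs):
        model = rf_train(Xtr, y, n_trees=n_trees, seed=run_seed)
        m, r = _metrics(ytr, model.predict(Xtr.to_numpy(dtype=float)))
        tr_mae.append(m)
        tr_r2.append(r)
        if has_test:
            m, r = _metrics(yte, model.predict(Xte.to_numpy(dtype=float)))
            te_mae.append(m)
            te_r2.append(r)

    def agg(vals):
        return (float(np.mean(vals)), float(np.std(vals)))

    return ModelEvaluation(
        train_mae=agg(tr_mae),
        test_mae=agg(te_mae) if has_test else None,
        train_r2=agg(tr_r2),
        test_r2=agg(te_r2) if has_test else None,
        n_runs=n_runs,
        features=list(features.columns),
    )


def null_mae(pmi_days: pd.Series, split: SplitPlan) -> float:
    """MAE of the no-information predictor (train-mean PMI) on the test set."""
    mean_day = float(pmi_days.loc[split.train].mean())
    return float(np.abs(pmi_days.loc[split.test] - mean_day).mean())


def multi_omics_concat(blocks: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Block-concatenate feature tables (samples x features) on shared
    samples, z-scoring each block per feature and prefixing feature names
    with the block name so no block dominates split choices by scale."""
    if not blocks:
        raise ValueError("no blocks supplied")
    shared = None
    for name, block in blocks.items():
        shared = block.index if shared is None else shared.intersection(block.index)
    if any(len(shared) < len(b.index) for b in blocks.values()):
        logger.warning("multi-omics blocks share %d samples; non-shared samples dropped", len(shared))
    parts = []
    for name, block in blocks.items():
        sub = block.loc[shared]
        sd = sub.std(axis=0, ddof=0)
        z = (sub - sub.mean(axis=0)) / sd.where(sd > 0, 1.0)
        z.columns = [f"{name}__{c}" for c in z.columns]
        parts.append(z)
    return pd.concat(parts, axis=1)
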