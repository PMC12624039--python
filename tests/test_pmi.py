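"""PMI random-forest regression: splits, IncMSE, biomarker optimisation."""

import numpy as np
import pandas as pd
import pytest

from qmpdecomp.pmi import (
    evaluate,
    inc_mse_importance,
    multi_omics_concat,
    null_mae,
    optimize_biomarkers,
    rf_train,
    stratified_split,
)


def _metadata(days=(1, 3, 7, 14, 21, 28, 35), reps=6):
    rows = []
    for d in days:
        for r in range(1, reps + 1):
            rows.append({"sample_id": f"d{d}r{r}", "day": d, "replicate": r})
    return pd.DataFrame(rows).set_index("sample_id")


def _features(meta, n_informative=1, n_noise=3, noise_sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    y = meta["day"].astype(float)
    cols = {}
    for i in range(n_informative):
        cols[f"info{i}"] = y + rng.normal(0, noise_sd, len(y))
    for i in range(n_noise):
        cols[f"noise{i}"] = rng.normal(size=len(y))
    return pd.DataFrame(cols, index=meta.index), y


class TestStratifiedSplit:
    def test_two_to_one_counts(self):
        meta = _metadata()
        split = stratified_split(meta, ratio=(2, 1), seed=0)
        assert len(split.train) == 28 and len(split.test) == 14
        for d, grp in meta.groupby("day"):
            assert len(split.train.intersection(grp.index)) == 4
            assert len(split.test.intersection(grp.index)) == 2

    def test_all_train_ratio(self):
        meta = _metadata()
        split = stratified_split(meta, ratio=(1, 0), seed=0)
        assert len(split.train) == len(meta) and len(split.test) == 0

    def test_seeds_differ_counts_identical(self):
        meta = _metadata()
        a = stratified_split(meta, seed=1)
        b = stratified_split(meta, seed=2)
        assert set(a.train) != set(b.train)
        assert len(a.train) == len(b.train)
        # deterministic given the seed
        c = stratified_split(meta, seed=1)
        assert list(a.train) == list(c.train)

    def test_insufficient_stratum_named(self):
        meta = _metadata(reps=5)
        with pytest.raises(ValueError, match="day=1"):
            stratified_split(meta, ratio=(2, 1), seed=0)


class TestRfTrain:
    def test_perfect_feature_low_training_error(self):
        meta = _metadata()
        X, y = _features(meta)
        model = rf_train(X[["info0"]], y, n_trees=200, seed=0)
        mae = np.abs(model.predict(X[["info0"]].to_numpy()) - y).mean()
        assert mae < 0.5

    def test_constant_features_predict_training_mean(self):
        meta = _metadata()
        X = pd.DataFrame({"c": np.ones(len(meta))}, index=meta.index)
        y = meta["day"].astype(float)
        model = rf_train(X, y, n_trees=200, seed=0)
        preds = model.predict(X.to_numpy())
        assert np.ptp(preds) == 0.0  # no split possible: one prediction for all
        # each tree predicts its bootstrap mean; the forest mean sits at the
        # training mean up to bootstrap error
        assert preds[0] == pytest.approx(y.mean(), abs=1.0)

    def test_same_seed_identical_predictions(self):
        meta = _metadata()
        X, y = _features(meta, n_noise=5, noise_sd=3.0)
        p1 = rf_train(X, y, n_trees=100, seed=7).predict(X.to_numpy())
        p2 = rf_train(X, y, n_trees=100, seed=7).predict(X.to_numpy())
        assert np.array_equal(p1, p2)


class TestIncMse:
    def test_constant_feature_exactly_zero(self):
        meta = _metadata()
        X, y = _features(meta, noise_sd=1.0)
        X["const"] = 5.0
        model = rf_train(X, y, n_trees=100, seed=0)
        imp = inc_mse_importance(model, X, y, seed=0)
        assert imp["const"] == 0.0

    def test_informative_feature_strictly_largest(self):
        meta = _metadata()
        X, y = _features(meta, n_noise=6, noise_sd=1.0, seed=1)
        model = rf_train(X, y, n_trees=300, seed=0)
        imp = inc_mse_importance(model, X, y, seed=0)
        assert imp.idxmax() == "info0"
        assert imp["info0"] > imp.drop("info0").max() * 3

    def test_pure_noise_feature_near_zero(self):
        meta = _metadata()
        X, y = _features(meta, n_noise=6, noise_sd=1.0, seed=2)
        model = rf_train(X, y, n_trees=300, seed=0)
        imp = inc_mse_importance(model, X, y, seed=0, n_repeats=10)
        assert abs(imp[[f"noise{i}" for i in range(6)]].mean()) < 0.1 * y.var()

    def test_held_out_variant_agrees_on_ranking(self):
        meta = _metadata()
        X, y = _features(meta, n_noise=4, noise_sd=1.0, seed=3)
        model = rf_train(X, y, n_trees=200, seed=0)
        oob = inc_mse_importance(model, X, y, seed=0)
        held = inc_mse_importance(model, X, y, seed=0, out_of_bag=False)
        assert oob.idxmax() == held.idxmax() == "info0"


class TestOptimizeBiomarkers:
    def test_recovers_planted_informative_features(self):
        meta = _metadata()
        rng = np.random.default_rng(4)
        y = meta["day"].astype(float)
        X = pd.DataFrame(rng.normal(size=(len(meta), 95)),
                         columns=[f"noise{i}" for i in range(95)], index=meta.index)
        for i in range(5):
            X[f"info{i}"] = y + rng.normal(0, 6, len(y))
        res = optimize_biomarkers(X, y, k_folds=5, repeats=2, n_trees=200, seed=0)
        assert res["best_k"] <= 20
        planted = {f"info{i}" for i in range(5)}
        assert len(planted & set(res["selected"])) >= 4

    def test_all_noise_curve_flat(self):
        meta = _metadata()
        rng = np.random.default_rng(5)
        y = meta["day"].astype(float)
        X = pd.DataFrame(rng.normal(size=(len(meta), 30)), index=meta.index,
                         columns=[f"n{i}" for i in range(30)])
        res = optimize_biomarkers(X, y, k_folds=5, repeats=2, n_trees=100, seed=0)
        curve = np.array(list(res["cv_curve"].values()))
        null = np.abs(y - y.mean()).mean()
        assert curve.max() - curve.min() < 0.5 * null

    def test_chosen_subset_no_worse_than_full_set(self):
        meta = _metadata()
        X, y = _features(meta, n_informative=2, n_noise=20, noise_sd=2.0, seed=6)
        res = optimize_biomarkers(X, y, k_folds=5, repeats=1, n_trees=100, seed=0)
        full_k = X.shape[1]
        assert res["cv_curve"][res["best_k"]] <= res["cv_curve"][full_k] + 1e-12

    def test_too_many_folds_rejected(self):
        meta = _metadata(days=(1, 3), reps=2)
        X, y = _features(meta)
        with pytest.raises(ValueError):
            optimize_biomarkers(X, y, k_folds=10)


class TestEvaluate:
    def test_perfect_predictor(self):
        meta = _metadata()
        X, y = _features(meta)
        split = stratified_split(meta, seed=0)
        ev = evaluate(X[["info0"]], y, split, n_runs=3, n_trees=200, seed=0)
        assert ev.test_mae[0] < 1.0
        assert ev.test_r2[0] > 0.95

    def test_uninformative_features_nonpositive_test_r2(self):
        meta = _metadata()
        X = pd.DataFrame({"c": np.ones(len(meta))}, index=meta.index)
        y = meta["day"].astype(float)
        split = stratified_split(meta, seed=0)
        ev = evaluate(X, y, split, n_runs=1, n_trees=50, seed=0)
        assert ev.test_r2[0] <= 1e-9

    def test_single_run_zero_sd(self):
        meta = _metadata()
        X, y = _features(meta, noise_sd=2.0)
        split = stratified_split(meta, seed=0)
        ev = evaluate(X, y, split, n_runs=1, n_trees=50, seed=0)
        assert ev.train_mae[1] == 0.0 and ev.test_mae[1] == 0.0

    def test_scrambled_test_features_destroy_r2(self):
        meta = _metadata()
        X, y = _features(meta, noise_sd=1.0, seed=7)
        split = stratified_split(meta, seed=0)
        model = rf_train(X.loc[split.train], y, n_trees=200, seed=0)
        rng = np.random.default_rng(8)
        Xte = X.loc[split.test].to_numpy()
        true = y.loc[split.test].to_numpy()
        sst = ((true - true.mean()) ** 2).sum()
        r2_intact = 1 - ((model.predict(Xte) - true) ** 2).sum() / sst
        Xscr = Xte[rng.permutation(len(Xte))]
        for j in range(Xscr.shape[1]):
            Xscr[:, j] = Xscr[rng.permutation(len(Xscr)), j]
        r2_scrambled = 1 - ((model.predict(Xscr) - true) ** 2).sum() / sst
        assert r2_intact > 0.9
        assert r2_scrambled < 0.3


class TestMultiOmics:
    def test_block_widths_and_prefixes(self):
        idx = [f"s{i}" for i in range(10)]
        rng = np.random.default_rng(9)
        blocks = {
            "a": pd.DataFrame(rng.normal(size=(10, 10)), index=idx),
            "b": pd.DataFrame(rng.normal(size=(10, 5)), index=idx),
            "c": pd.DataFrame(rng.normal(size=(10, 20)), index=idx),
        }
        out = multi_omics_concat(blocks)
        assert out.shape == (10, 35)
        assert all(c.startswith(("a__", "b__", "c__")) for c in out.columns)
        # per-block standardization
        assert np.allclose(out.mean(axis=0), 0.0, atol=1e-12)

    def test_sample_mismatch_uses_intersection(self, caplog):
        rng = np.random.default_rng(10)
        a = pd.DataFrame(rng.normal(size=(8, 3)), index=[f"s{i}" for i in range(8)])
        b = pd.DataFrame(rng.normal(size=(6, 3)), index=[f"s{i}" for i in range(6)])
        with caplog.at_level("WARNING", logger="qmpdecomp"):
            out = multi_omics_concat({"a": a, "b": b})
        assert len(out) == 6

    def test_complementary_blocks_beat_single_blocks(self):
        """When two blocks carry complementary halves of the PMI signal the
        combined model's CV error undercuts either single block."""
        meta = _metadata()
        rng = np.random.default_rng(11)
        y = meta["day"].astype(float)
        half = y + rng.normal(0, 14, len(y))     # very noisy alone
        other = (y - half)                        # complementary remainder
        block_a = pd.DataFrame({"a0": half, "a1": rng.normal(size=len(y))}, index=meta.index)
        block_b = pd.DataFrame({"b0": other, "b1": rng.normal(size=len(y))}, index=meta.index)
        combined = multi_omics_concat({"a": block_a, "b": block_b})
        split = stratified_split(meta, seed=0)
        maes = {}
        for name, feats in (("a", block_a), ("b", block_b), ("ab", combined)):
            ev = evaluate(feats, y, split, n_runs=3, n_trees=200, seed=0)
            maes[name] = ev.test_mae[0]
        assert maes["ab"] < min(maes["a"], maes["b"])


def test_null_mae_matches_hand_computation():
    meta = _metadata(days=(1, 3), reps=3)
    split = stratified_split(meta, ratio=(2, 1), seed=0)
    y = meta["day"].astype(float)
    expected = np.abs(y.loc[split.test] - y.loc[split.train].mean()).mean()
    assert null_mae(y, split) == expected
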