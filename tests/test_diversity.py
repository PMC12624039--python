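"""Diversity, ordination, decomposer detection, discordance, time decay."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

from qmpdecomp import cohort, diversity
from qmpdecomp.calibration import qmp_profile, rmp_profile
from qmpdecomp.core import AbundanceMatrix
from qmpdecomp.diversity import (
    bray_curtis,
    classify_trend,
    group_tests,
    identify_key_decomposers,
    pcoa,
    shannon,
    time_decay,
    trend_discordance,
)


class TestShannon:
    def test_uniform_and_single(self):
        assert shannon([1, 1, 1, 1]) == pytest.approx(np.log(4))
        assert shannon([0, 5, 0]) == 0.0

    def test_direct_evaluation(self):
        # p = (1/6, 2/6, 3/6): -sum p ln p = 1.0114
        assert shannon([1, 2, 3]) == pytest.approx(1.0114, abs=5e-5)

    def test_zero_total_undefined(self):
        with pytest.raises(ValueError):
            shannon([0, 0])

    @given(st.floats(min_value=1e-6, max_value=1e6))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_scale_invariance(self, scale):
        x = np.array([3.0, 1.0, 7.0, 2.0])
        assert shannon(x * scale) == pytest.approx(shannon(x), rel=1e-9)


class TestBrayCurtisPcoa:
    def test_identical_and_disjoint(self):
        data = pd.DataFrame({"a": [1, 0], "b": [1, 0], "c": [0, 1]}, index=["t1", "t2"])
        d = bray_curtis(AbundanceMatrix(data, mode="raw_reads"))
        assert d.loc["a", "b"] == pytest.approx(0.0)
        assert d.loc["a", "c"] == pytest.approx(1.0)
        assert np.allclose(np.diag(d), 0.0)
        assert np.allclose(d, d.T)

    def test_pcoa_reproduces_euclidean_distances(self):
        """Gower property: for a Euclidean-embeddable distance matrix the
        pairwise score distances reproduce the input distances."""
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.3, 0.9]])
        d = pd.DataFrame(squareform(pdist(pts)), index=list("abc"), columns=list("abc"))
        scores, rel = pcoa(d, n_axes=2)
        reproduced = squareform(pdist(scores.to_numpy()))
        assert np.allclose(reproduced, d.to_numpy(), atol=1e-8)
        assert rel.sum() <= 1.0 + 1e-9

    def test_all_zero_sample_dropped(self, caplog):
        data = pd.DataFrame({"a": [1, 2], "b": [0, 0], "c": [2, 1]}, index=["t1", "t2"])
        with caplog.at_level("WARNING", logger="qmpdecomp"):
            d = bray_curtis(AbundanceMatrix(data, mode="raw_reads"))
        assert "b" not in d.index


class TestGroupTests:
    def test_exact_minimal_wilcoxon_p(self):
        """Fully separated 6 vs 6 gives the minimal exact two-sided P = 2/924."""
        values = pd.DataFrame([[1, 2, 3, 4, 5, 6, 101, 102, 103, 104, 105, 106]],
                              index=["f"], columns=list("abcdefghijkl"))
        groups = pd.Series(["x"] * 6 + ["y"] * 6, index=values.columns)
        res = group_tests(values, groups, method="exact")
        assert res.loc["f", "p_value"] == pytest.approx(2 / 924, rel=1e-9)

    def test_bh_identity_and_monotonicity(self):
        rng = np.random.default_rng(0)
        values = pd.DataFrame(rng.normal(size=(10, 12)), columns=list("abcdefghijkl"))
        groups = pd.Series(["x"] * 6 + ["y"] * 6, index=values.columns)
        res = group_tests(values, groups)
        assert (res["p_adjusted"] >= res["p_value"] - 1e-12).all()
        same = pd.DataFrame([[1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12]] * 5,
                            columns=values.columns)
        res2 = group_tests(same, groups)
        # m identical hypotheses: BH-adjusted all equal the raw P
        assert np.allclose(res2["p_adjusted"], res2["p_value"])

    def test_constant_values_give_p_one(self):
        values = pd.DataFrame([[5.0] * 12], index=["f"], columns=list("abcdefghijkl"))
        groups = pd.Series(["x"] * 6 + ["y"] * 6, index=values.columns)
        assert group_tests(values, groups).loc["f", "p_value"] == 1.0


class TestKeyDecomposers:
    def test_strictly_increasing_genus_selected(self):
        days = pd.Series(np.repeat([1, 3, 7, 14, 21, 28, 35], 6), index=[f"s{i}" for i in range(42)])
        data = pd.DataFrame({s: [float(days[s]) ** 2] for s in days.index}, index=["riser"])
        mat = AbundanceMatrix(data, mode="copies_per_gram")
        res = identify_key_decomposers(mat, days)
        assert res.loc["riser", "r"] == pytest.approx(1.0)
        assert bool(res.loc["riser", "key_decomposer"])

    def test_noise_genera_essentially_never_selected(self):
        rng = np.random.default_rng(1)
        days = pd.Series(np.repeat([1, 3, 7, 14, 21, 28, 35], 6), index=[f"s{i}" for i in range(42)])
        data = pd.DataFrame(rng.lognormal(10, 1, (500, 42)), columns=days.index)
        res = identify_key_decomposers(AbundanceMatrix(data, mode="copies_per_gram"), days)
        assert int(res["key_decomposer"].sum()) == 0

    def test_planted_decomposers_recovered(self, default_cohort):
        """>= 90% of the planted tissue decomposers pass r>0.6, P<0.001 on QMP."""
        c = default_cohort
        meta = c.metadata
        tissue = meta.index[meta["sample_type"] == "tissue"]
        hits = total = 0
        for domain in ("bacteria", "fungi"):
            qmp, _ = qmp_profile(c.counts[domain], c.spikes[domain], meta["mass_g"])
            sub = qmp.with_data(qmp.data[tissue.intersection(qmp.samples)])
            res = identify_key_decomposers(sub, meta["day"])
            planted = c.dynamics[domain].decomposer
            planted = list(planted.index[planted])
            total += len(planted)
            hits += int(res.reindex(planted)["key_decomposer"].fillna(False).sum())
        assert hits / total >= 0.90


class TestTrendDiscordance:
    def test_classification_contract(self):
        assert classify_trend("up", "up") == "concordant"
        assert classify_trend("up", "down") == "contrasting"
        assert classify_trend("ns", "down") == "contrasting"   # RMP claims, QMP flat
        assert classify_trend("up", "ns") == "qmp_only"        # RMP blindness
        assert classify_trend("ns", "ns") == "neither"

    def test_classification_symmetric_up_to_label_exchange(self):
        swap = {"concordant": "concordant", "neither": "neither",
                "contrasting": {"contrasting", "qmp_only"}, "qmp_only": "contrasting"}
        for a in ("up", "down", "ns"):
            for b in ("up", "down", "ns"):
                fwd, rev = classify_trend(a, b), classify_trend(b, a)
                expected = swap[fwd]
                assert rev in (expected if isinstance(expected, set) else {expected})

    def test_trap_taxon_contrasting_and_lockstep_qmp_only(self, trap_cohort):
        c = trap_cohort
        meta = c.metadata
        qmp, _ = qmp_profile(c.counts["bacteria"], c.spikes["bacteria"], meta["mass_g"])
        rmp = rmp_profile(c.counts["bacteria"], c.spikes["bacteria"].spike_ids, seed=1)
        res = trend_discordance(qmp, rmp, meta["day"])
        assert res.loc["Focal01", "classification"] == "contrasting"
        # background taxa grow in lockstep with the total: QMP up, RMP flat
        background = res.drop(index="Focal01")
        assert (background["classification"] == "qmp_only").mean() > 0.8

    def test_identical_matrices_no_contrast(self, tissue_profiles):
        qmp = tissue_profiles["qmp"]
        res = trend_discordance(qmp, qmp, tissue_profiles["meta"]["day"])
        assert (res["classification"] != "contrasting").all()
        assert set(res["classification"]) <= {"concordant", "neither"}


class TestTimeDecay:
    def _distance(self, days, slope):
        n = len(days)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if i != j:
                    d[i, j] = 0.5 - slope * abs(days[i] - days[j])
        idx = [f"s{i}" for i in range(n)]
        return pd.DataFrame(d, index=idx, columns=idx), pd.Series(days, index=idx)

    def test_noiseless_slope_recovered(self):
        days = np.repeat([1, 3, 7, 14, 21], 2)
        d, s = self._distance(days, slope=-0.01)
        res = time_decay(d, s)
        assert res["slope"] == pytest.approx(-0.01, abs=1e-12)

    def test_permutation_null_is_flat(self):
        rng = np.random.default_rng(0)
        days = np.repeat([1, 3, 7, 14, 21, 28, 35], 3)
        n = len(days)
        base = rng.uniform(0.3, 0.7, (n, n))
        dmat = (base + base.T) / 2
        np.fill_diagonal(dmat, 0.0)
        idx = [f"s{i}" for i in range(n)]
        d = pd.DataFrame(dmat, index=idx, columns=idx)
        slopes, pvals = [], []
        for _ in range(200):
            perm = pd.Series(rng.permutation(days), index=idx)
            res = time_decay(d, perm)
            slopes.append(res["slope"])
            pvals.append(res["p_value"])
        assert abs(np.mean(slopes)) < 5e-4
        assert 0.005 < np.mean(np.array(pvals) < 0.05) < 0.15

    def test_insufficient_intervals_rejected(self):
        days = np.array([1, 1, 3, 3])
        d, s = self._distance(days, slope=-0.01)
        with pytest.raises(ValueError):
            time_decay(d, s)

    def test_tissue_turnover_faster_than_stable_soil(self, default_cohort):
        """QMP time decay is steeper in tissue than in the load-stable
        regular soil control."""
        c = default_cohort
        meta = c.metadata
        qmp, _ = qmp_profile(c.counts["bacteria"], c.spikes["bacteria"], meta["mass_g"])
        slopes = {}
        for stype in ("tissue", "regular_soil"):
            sel = meta.index[meta["sample_type"] == stype].intersection(qmp.samples)
            d = bray_curtis(qmp.with_data(qmp.data[sel]))
            slopes[stype] = time_decay(d, meta["day"])["slope"]
        assert abs(slopes["tissue"]) > abs(slopes["regular_soil"])
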