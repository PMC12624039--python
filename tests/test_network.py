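"""Co-occurrence networks: edges, modularity, overlap, eigengenes."""

import itertools

import numpy as np
import pandas as pd
import pytest

from qmpdecomp import cohort, network
from qmpdecomp.calibration import qmp_profile, rmp_profile
from qmpdecomp.core import AbundanceMatrix
from qmpdecomp.network import (
    CooccurrenceNetwork,
    build_network,
    edge_overlap,
    module_eigengene,
    module_metabolite_correlation,
    network_stats,
)


def _matrix(data: np.ndarray, taxa=None) -> AbundanceMatrix:
    taxa = taxa or [f"g{i}" for i in range(data.shape[0])]
    cols = [f"s{j}" for j in range(data.shape[1])]
    return AbundanceMatrix(pd.DataFrame(data, index=taxa, columns=cols), mode="copies_per_gram")


def _toy_net(edges) -> CooccurrenceNetwork:
    nodes = sorted({n for e in edges for n in e})
    df = pd.DataFrame([{"source": a, "target": b, "r": 0.9, "p_value": 1e-5, "sign": "positive"} for a, b in edges])
    node_df = pd.DataFrame({"degree": 1, "domain": pd.NA, "module": -1}, index=pd.Index(nodes, name="genus"))
    return CooccurrenceNetwork(edges=df, nodes=node_df)


class TestBuildNetwork:
    def test_identical_rank_order_gives_perfect_edge(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(1, 100, 20)
        data = np.vstack([base, base * 3.7, rng.uniform(1, 100, 20)])
        net = build_network(_matrix(data), top_n=3)
        pairs = net.edge_set()
        assert frozenset(("g0", "g1")) in pairs
        edge = net.edges[net.edges.apply(lambda e: {e["source"], e["target"]} == {"g0", "g1"}, axis=1)]
        assert edge["r"].iloc[0] == pytest.approx(1.0)

    def test_independent_noise_yields_no_edges(self):
        """At |r|>0.6 and P<0.001 with n=42, the null edge rate is far below
        one edge per simulated network."""
        total_edges = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            net = build_network(_matrix(rng.lognormal(10, 1, (30, 42))), top_n=30)
            total_edges += len(net.edges)
        assert total_edges <= 1

    def test_degenerate_thresholds_complete_graph(self):
        rng = np.random.default_rng(1)
        net = build_network(_matrix(rng.uniform(1, 10, (6, 15))), r_min=0.0, p_max=1.01, top_n=6)
        assert len(net.edges) == 6 * 5 // 2

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(2)
        base = rng.uniform(1, 100, 42)
        data = np.vstack([base * rng.uniform(0.5, 2) + rng.normal(0, 15, 42) for _ in range(12)])
        data = np.clip(data, 0.1, None)
        loose = build_network(_matrix(data), r_min=0.3, p_max=0.05, top_n=12)
        tight = build_network(_matrix(data), r_min=0.6, p_max=0.05, top_n=12)
        assert tight.edge_set() <= loose.edge_set()

    def test_all_constant_genera_empty_network(self):
        data = np.ones((5, 12))
        net = build_network(_matrix(data), top_n=5)
        assert len(net.edges) == 0
        assert network_stats(net)["modularity"] is None


def brute_force_max_modularity(edges, nodes):
    """Exhaustive maximum modularity over every partition of the nodes."""
    import networkx as nx

    g = nx.Graph(edges)
    g.add_nodes_from(nodes)

    def partitions(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [[first] + part[i]] + part[i + 1:]
            yield [[first]] + part

    best, best_part = -np.inf, None
    for part in partitions(list(nodes)):
        q = nx.community.modularity(g, [set(p) for p in part])
        if q > best:
            best, best_part = q, part
    return best, best_part


class TestNetworkStats:
    def test_two_triangles_modularity_oracle(self):
        """Q = 0.5 for the 2-clique partition of two disjoint triangles,
        confirmed by brute force over all partitions of the 6 nodes."""
        tri1 = [("a", "b"), ("b", "c"), ("a", "c")]
        tri2 = [("d", "e"), ("e", "f"), ("d", "f")]
        best_q, best_part = brute_force_max_modularity(tri1 + tri2, list("abcdef"))
        assert best_q == pytest.approx(0.5, abs=1e-12)
        assert sorted(sorted(p) for p in best_part) == [["a", "b", "c"], ["d", "e", "f"]]
        # the package's greedy detection finds the same optimum
        net = _toy_net(tri1 + tri2)
        network._assign_modules(net)
        assert net.modularity == pytest.approx(0.5, abs=1e-12)
        modules = net.nodes["module"]
        assert len(set(modules[list("abc")])) == 1
        assert len(set(modules[list("def")])) == 1
        assert modules["a"] != modules["d"]

    def test_complete_graph_single_module_q_zero(self):
        import networkx as nx

        g = nx.complete_graph(5)
        assert nx.community.modularity(g, [set(g.nodes)]) == pytest.approx(0.0, abs=1e-12)

    def test_sign_counts_conserved(self, tissue_profiles):
        net = build_network(tissue_profiles["qmp"], top_n=40)
        stats = network_stats(net)
        assert stats["n_positive"] + stats["n_negative"] == stats["n_edges"]


class TestEdgeOverlap:
    def test_identical_and_disjoint(self):
        a = _toy_net([("a", "b"), ("c", "d")])
        assert edge_overlap(a, a)["pct_of_a"] == 100.0
        b = _toy_net([("x", "y")])
        assert edge_overlap(a, b)["shared"] == 0

    def test_partial_overlap_percentages(self):
        a = _toy_net([("a", "b"), ("c", "d"), ("e", "f"), ("g", "h")])
        b = _toy_net([("a", "b"), ("c", "d")] + [(f"x{i}", f"y{i}") for i in range(6)])
        res = edge_overlap(a, b)
        assert res["shared"] == 2
        assert res["pct_of_a"] == pytest.approx(50.0)
        assert res["pct_of_b"] == pytest.approx(25.0)


class TestModuleEigengene:
    def test_perfectly_correlated_pair_explains_everything(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(1, 10, 20)
        mat = _matrix(np.vstack([base, 2 * base]))
        eig = module_eigengene(mat, ["g0", "g1"])
        z = (base - base.mean()) / base.std(ddof=1)
        assert abs(np.corrcoef(eig, z)[0, 1]) == pytest.approx(1.0, abs=1e-9)
        assert np.corrcoef(eig, mat.data.mean(axis=0))[0, 1] > 0

    def test_invariant_to_genus_order(self):
        rng = np.random.default_rng(1)
        mat = _matrix(rng.uniform(1, 10, (4, 15)))
        a = module_eigengene(mat, ["g0", "g1", "g2", "g3"])
        b = module_eigengene(mat, ["g3", "g1", "g0", "g2"])
        assert np.allclose(a, b) or np.allclose(a, -b)

    def test_three_genus_toy_matches_eigendecomposition(self):
        rng = np.random.default_rng(2)
        mat = _matrix(rng.uniform(1, 10, (3, 30)))
        z = mat.data.sub(mat.data.mean(axis=1), axis=0).div(mat.data.std(axis=1, ddof=1), axis=0)
        cov = np.cov(z.to_numpy())
        w, v = np.linalg.eigh(cov)
        lead = v[:, np.argmax(w)]
        expected = z.to_numpy().T @ lead
        eig = module_eigengene(mat, ["g0", "g1", "g2"])
        r = np.corrcoef(eig, expected)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-9)

    def test_constant_submatrix_rejected(self):
        mat = _matrix(np.ones((2, 10)))
        with pytest.raises(ValueError):
            module_eigengene(mat, ["g0", "g1"])


class TestModuleMetaboliteCorrelation:
    def _eigengenes(self, n=30, seed=0):
        rng = np.random.default_rng(seed)
        idx = [f"s{j}" for j in range(n)]
        return pd.DataFrame({"module_1": rng.normal(size=n)}, index=idx)

    def test_monotone_transform_gives_r_one(self):
        eig = self._eigengenes()
        intensities = pd.DataFrame(
            {s: [np.exp(eig.loc[s, "module_1"]), 1.0] for s in eig.index},
            index=["m1", "m2"],
        )
        classes = pd.Series({"m1": "Lipids", "m2": "Other"})
        grid = module_metabolite_correlation(eig, intensities, classes)
        row = grid[(grid["module"] == "module_1") & (grid["superclass"] == "Lipids")].iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["significant"]

    def test_grid_dimensions(self):
        rng = np.random.default_rng(3)
        eig = self._eigengenes(seed=3)
        eig["module_2"] = rng.normal(size=len(eig))
        feats = [f"m{i}" for i in range(12)]
        intensities = pd.DataFrame(rng.lognormal(3, 1, (12, len(eig))), index=feats, columns=eig.index)
        classes = pd.Series([f"C{i % 4}" for i in range(12)], index=feats)
        grid = module_metabolite_correlation(eig, intensities, classes)
        assert len(grid) == 2 * 4

    def test_shuffled_labels_calibrated_alpha(self):
        """With independent data the significant fraction sits near 0.05."""
        rng = np.random.default_rng(4)
        n = 40
        idx = [f"s{j}" for j in range(n)]
        eig = pd.DataFrame(rng.normal(size=(n, 5)), index=idx,
                           columns=[f"module_{k}" for k in range(5)])
        feats = [f"m{i}" for i in range(80)]
        intensities = pd.DataFrame(rng.lognormal(3, 1, (80, n)), index=feats, columns=idx)
        classes = pd.Series([f"C{i}" for i in range(80)], index=feats)  # one feature per class
        grid = module_metabolite_correlation(eig, intensities, classes)
        frac = grid["significant"].mean()
        assert 0.01 <= frac <= 0.12


class TestPlantedStructureRecovery:
    def test_guild_blocks_land_in_distinct_connected_modules(self):
        """Bacterial and fungal decomposer guilds planted with shared latent
        factors resolve into distinct, internally connected modules."""
        c = cohort.simulate_cohort(
            cohort.tissue_design(seed=31), dynamics=cohort.guild_dynamics(seed=31),
            with_metabolites=False, seed=31,
        )
        meta = c.metadata
        mats = []
        for domain in ("bacteria", "fungi"):
            qmp, _ = qmp_profile(c.counts[domain], c.spikes[domain], meta["mass_g"])
            mats.append(qmp.data)
        combined = AbundanceMatrix(pd.concat(mats), mode="copies_per_gram")
        domains = c.taxonomy["domain"]
        net = build_network(combined, top_n=len(combined.taxa), domains=domains)
        bact = [t for t, dyn in [("bacteria", c.dynamics["bacteria"])] for t in dyn.decomposer.index[dyn.decomposer]]
        fung = list(c.dynamics["fungi"].decomposer.index[c.dynamics["fungi"].decomposer])
        mod_b = net.nodes.loc[bact, "module"].mode().iloc[0]
        mod_f = net.nodes.loc[fung, "module"].mode().iloc[0]
        assert mod_b > 0 and mod_f > 0 and mod_b != mod_f
        assert (net.nodes.loc[bact, "module"] == mod_b).mean() >= 0.8
        assert (net.nodes.loc[fung, "module"] == mod_f).mean() >= 0.8
        # each guild is internally connected
        g = net.graph()
        import networkx as nx

        for members in (bact, fung):
            present = [m for m in members if m in g]
            assert nx.is_connected(g.subgraph(present))

    def test_rmp_invents_edges_qmp_does_not(self):
        """In the trap scenario, shared load dynamics make constant-copy taxa
        co-decline in relative terms: spurious RMP edges absent from QMP."""
        c = cohort.simulate_cohort(
            cohort.tissue_design(seed=37), dynamics=cohort.trap_dynamics(n_focal=10, seed=37),
            with_metabolites=False, seed=37,
        )
        meta = c.metadata
        qmp, _ = qmp_profile(c.counts["bacteria"], c.spikes["bacteria"], meta["mass_g"])
        rmp = rmp_profile(c.counts["bacteria"], c.spikes["bacteria"].spike_ids, seed=0)
        focal = [f"Focal{i:02d}" for i in range(1, 11)]
        net_q = build_network(qmp, top_n=100)
        net_r = build_network(rmp, top_n=100)
        focal_pairs = {frozenset(p) for p in itertools.combinations(focal, 2)}
        spurious_rmp = focal_pairs & net_r.edge_set()
        spurious_qmp = focal_pairs & net_q.edge_set()
        assert len(spurious_rmp) >= 10
        assert len(spurious_qmp) <= 2
        assert net_q.edge_set() != net_r.edge_set()
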