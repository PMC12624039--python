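"""Co-occurrence networks on the most abundant genera.

Edges are significant Spearman correlations (|r| > 0.6, P < 0.001 by
default, raw thresholds without multiple-testing correction; a BH option is
available) among the top 100 genera.  Modules come from greedy modularity
maximisation on the unsigned edge set; module eigengenes (first principal
component of the standardized module submatrix) summarise each module per
sample for correlation with metabolite classes.

Relative-abundance (RMP) networks are vulnerable to compositional
artifacts: shared total-load dynamics induce spurious correlations between
taxa whose absolute abundances are unrelated, which is why the QMP/RMP
edge-overlap comparison matters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from ._stats import bh_adjust, spearman_test
from .core import AbundanceMatrix

logger = logging.getLogger("qmpdecomp")


@dataclass
class CooccurrenceNetwork:
    """Genus nodes, signed Spearman edges, modules, and modularity Q."""

    edges: pd.DataFrame                 # source, target, r, p_value, sign
    nodes: pd.DataFrame                 # genus-indexed: domain, degree, module
    isolated: list[str] = field(default_factory=list)
    modularity: float | None = None
    r_min: float = 0.6
    p_max: float = 0.001

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes.index[self.nodes["degree"] > 0])
        for _, e in self.edges.iterrows():
            g.add_edge(e["source"], e["target"], r=e["r"], sign=e["sign"])
        return g

    def edge_set(self) -> set[frozenset]:
        return {frozenset((s, t)) for s, t in zip(self.edges["source"], self.edges["target"])}


def top_genera(matrix: AbundanceMatrix, top_n: int) -> pd.Index:
    """The ``top_n`` most abundant genera by mean abundance (lexicographic
    tie-break)."""
    means = matrix.data.mean(axis=1)
    order = sorted(means.index, key=lambda t: (-means[t], str(t)))
    return pd.Index(order[:top_n])


def build_network(
    matrix: AbundanceMatrix,
    r_min: float = 0.6,
    p_max: float = 0.001,
    top_n: int = 100,
    domains: pd.Series | None = None,
    bh_correct: bool = False,
) -> CooccurrenceNetwork:
    """All-pairs Spearman among the top genera; keep edges passing both
    thresholds.  Constant genera are excluded (their correlation is
    undefined); isolated non-constant genera are recorded separately.
    """
    if matrix.data.shape[1] < 10:
        raise ValueError("need at least 10 samples")
    top = top_genera(matrix, top_n)
    sub = matrix.data.loc[top]
    nonconst = sub.index[sub.nunique(axis=1) > 1]
    if len(nonconst) < 2:
        logger.warning("fewer than 2 non-constant genera: empty network")
        nodes = pd.DataFrame(index=pd.Index([], name="genus"), columns=["domain", "degree", "module"])
        return CooccurrenceNetwork(
            edges=pd.DataFrame(columns=["source", "target", "r", "p_value", "sign"]),
            nodes=nodes, r_min=r_min, p_max=p_max,
        )
    sub = sub.loc[nonconst]
    rho, pval = stats.spearmanr(sub.T.to_numpy(dtype=float))
    rho = np.atleast_2d(rho)
    pval = np.atleast_2d(pval)
    iu = np.triu_indices(len(nonconst), k=1)
    p_upper = pval[iu]
    if bh_correct:
        p_upper = bh_adjust(p_upper)
    keep = (np.abs(rho[iu]) > r_min) & (p_upper < p_max)
    edges = pd.DataFrame(
        {
            "source": nonconst[iu[0][keep]],
            "target": nonconst[iu[1][keep]],
            "r": rho[iu][keep],
            "p_value": p_upper[keep],
        }
    )
    edges["sign"] = np.where(edges["r"] > 0, "positive", "negative")

    degree = pd.Series(0, index=nonconst, dtype=int)
    for col in ("source", "target"):
        degree = degree.add(edges[col].value_counts(), fill_value=0).astype(int)
    nodes = pd.DataFrame({"degree": degree})
    nodes.index.name = "genus"
    nodes["domain"] = domains.reindex(nodes.index) if domains is not None else pd.NA
    nodes["module"] = -1
    isolated = list(nodes.index[nodes["degree"] == 0])
    net = CooccurrenceNetwork(edges=edges, nodes=nodes, isolated=isolated, r_min=r_min, p_max=p_max)
    _assign_modules(net)
    return net


def _assign_modules(net: CooccurrenceNetwork) -> None:
    g = net.graph()
    if g.number_of_edges() == 0:
        net.modularity = None
        return
    communities = list(nx.community.greedy_modularity_communities(g))
    net.modularity = float(nx.community.modularity(g, communities))
    for mod_id, members in enumerate(communities, start=1):
        net.nodes.loc[list(members), "module"] = mod_id


def network_stats(net: CooccurrenceNetwork, min_module_size: int = 7) -> dict:
    """Node/edge/sign counts, modularity Q, and large-module sizes.

    Q is computed on the unsigned edge set by greedy modularity
    maximisation; modules of more than six nodes are reported separately.
    An empty network reports zeros with Q missing.
    """
    n_edges = len(net.edges)
    pos = int((net.edges["sign"] == "positive").sum()) if n_edges else 0
    module_sizes = (
        net.nodes.loc[net.nodes["module"] > 0, "module"].value_counts().sort_index().to_dict()
    )
    by_domain = {}
    connected = net.nodes[net.nodes["degree"] > 0]
    if "domain" in net.nodes and connected["domain"].notna().any():
        by_domain = connected["domain"].value_counts().to_dict()
    return {
        "n_nodes": int((net.nodes["degree"] > 0).sum()),
        "n_isolated": len(net.isolated),
        "nodes_by_domain": by_domain,
        "n_edges": n_edges,
        "n_positive": pos,
        "n_negative": n_edges - pos,
        "modularity": net.modularity,
        "module_sizes": module_sizes,
        "large_modules": {m: s for m, s in module_sizes.items() if s >= min_module_size},
    }


def edge_overlap(net_a: CooccurrenceNetwork, net_b: CooccurrenceNetwork) -> dict:
    """Shared edges between two networks as unordered genus pairs,
    ignoring correlation magnitude, with percentages relative to each
    network's edge count."""
    ea, eb = net_a.edge_set(), net_b.edge_set()
    shared = len(ea & eb)
    return {
        "shared": shared,
        "n_a": len(ea),
        "n_b": len(eb),
        "pct_of_a": 100.0 * shared / len(ea) if ea else 0.0,
        "pct_of_b": 100.0 * shared / len(eb) if eb else 0.0,
    }


def module_eigengene(matrix: AbundanceMatrix, module_genera) -> pd.Series:
    """First principal component of the standardized module submatrix,
    sign-oriented to correlate positively with mean module abundance."""
    genera = pd.Index(module_genera)
    if len(genera) < 2:
        raise ValueError("a module eigengene needs >= 2 genera")
    sub = matrix.data.loc[genera]
    sd = sub.std(axis=1, ddof=1)
    if (sd == 0).all():
        raise ValueError("module submatrix is constant: eigengene undefined")
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd.where(sd > 0, 1.0), axis=0)
    scores = PCA(n_components=1).fit_transform(z.T.to_numpy(dtype=float))[:, 0]
    eig = pd.Series(scores, index=matrix.samples, name="eigengene")
    mean_ab = sub.mean(axis=0)
    if np.corrcoef(eig, mean_ab)[0, 1] < 0:
        eig = -eig
    return eig


def module_eigengenes(matrix: AbundanceMatrix, net: CooccurrenceNetwork, min_size: int = 2) -> pd.DataFrame:
    """Eigengenes for every module with at least ``min_size`` member genera
    present in ``matrix`` (samples x modules)."""
    out = {}
    for mod_id, members in net.nodes.groupby("module").groups.items():
        if mod_id <= 0:
            continue
        present = pd.Index(members).intersection(matrix.taxa)
        if len(present) >= min_size:
            out[f"module_{mod_id}"] = module_eigengene(matrix, present)
    return pd.DataFrame(out)


def module_metabolite_correlation(
    eigengenes: pd.DataFrame,
    metabolite_data: pd.DataFrame,
    superclass: pd.Series,
    p_max: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Spearman grid of module eigengenes vs metabolite class abundances.

    Class abundance is the per-sample sum of sum-normalized intensities
    over the class's member metabolites; classes with no members are
    skipped with a warning.  Returns a long table (module, class, r, P,
    significant at ``p_max``).
    """
    shared = eigengenes.index.intersection(metabolite_data.columns)
    if len(shared) < 5:
        raise ValueError("too few shared samples between eigengenes and metabolites")
    norm = metabolite_data[shared] / metabolite_data[shared].sum(axis=0)
    rows = []
    for cls, members in superclass.groupby(superclass).groups.items():
        members = pd.Index(members).intersection(norm.index)
        if len(members) == 0:
            logger.warning("metabolite class %r has no member features: skipped", cls)
            continue
        class_ab = norm.loc[members].sum(axis=0)
        for module in eigengenes.columns:
            r, p = spearman_test(eigengenes.loc[shared, module], class_ab, seed=seed)
            rows.append(
                {"module": module, "superclass": cls, "r": r, "p_value": p,
                 "significant": bool(p < p_max) if np.isfinite(p) else False}
            )
    return pd.DataFrame(rows)
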