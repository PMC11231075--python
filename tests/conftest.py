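"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from mpxcoloc import AnodeGraph, PanelManifest


@pytest.fixture
def panel() -> PanelManifest:
    return PanelManifest(
        markers=("CD50", "CD162", "CD44", "mIgG2b", "mIgG1", "mIgG2a"),
        isotype_markers=frozenset({"mIgG2b", "mIgG1", "mIgG2a"}),
    )


def make_anode(
    edges: list[tuple[str, str]],
    counts: dict[str, list[float]],
    nodes: list[str] | None = None,
    cell_id: str = "c1",
) -> AnodeGraph:
    """Build an AnodeGraph directly from adjacency and per-marker counts."""
    g = nx.Graph()
    if nodes is None:
        nodes = sorted({v for e in edges for v in e})
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    node_counts = pd.DataFrame(
        {m: v for m, v in counts.items()}, index=pd.Index(nodes, name="node")
    )
    return AnodeGraph(cell_id=cell_id, graph=g, node_counts=node_counts)


def barbell_anode(marker_high: str = "CD50", panel_markers=None) -> AnodeGraph:
    """Two 4-cliques joined by one edge; marker count 5 on one clique, 0 on the other."""
    g = nx.barbell_graph(4, 0)
    nodes = [f"a{i}" for i in g.nodes]
    mapping = dict(zip(g.nodes, nodes))
    g = nx.relabel_nodes(g, mapping)
    x = [5.0] * 4 + [0.0] * 4
    markers = panel_markers or [marker_high]
    counts = {m: (x if m == marker_high else [1.0] * 8) for m in markers}
    return make_anode(list(g.edges), counts, nodes=nodes)


def ppr_linear_solve(g: AnodeGraph, focal: str, alpha: float) -> np.ndarray:
    """Dense linear-system oracle for the personalized PageRank fixed point."""
    nodes = list(g.nodes)
    a = nx.to_numpy_array(g.graph, nodelist=nodes)
    p = a / a.sum(axis=1, keepdims=True)
    e = np.zeros(len(nodes))
    e[nodes.index(focal)] = 1.0
    # w = alpha e + (1-alpha) P^T w  =>  (I - (1-alpha) P^T) w = alpha e
    return np.linalg.solve(np.eye(len(nodes)) - (1 - alpha) * p.T, alpha * e)


def global_assortativity(g: AnodeGraph, marker: str) -> float:
    """Degree-weighted (edge-end Pearson) assortativity computed from the edge list."""
    x = dict(zip(g.nodes, g.marker_vector(marker)))
    ends = []
    for u, v in g.graph.edges:
        ends.append((x[u], x[v]))
        ends.append((x[v], x[u]))
    ends = np.array(ends)
    mu = ends[:, 0].mean()
    var = ends[:, 0].var()
    return float((ends[:, 0] * ends[:, 1]).mean() - mu**2) / var


def brute_force_local_assortativity(
    g: AnodeGraph, marker: str, weights: np.ndarray
) -> np.ndarray:
    """Direct per-focal-node evaluation of the local assortativity formula."""
    nodes = list(g.nodes)
    x = g.marker_vector(marker)
    d = g.degrees()
    mu = (d * x).sum() / d.sum()
    var = (d * x**2).sum() / d.sum() - mu**2
    out = np.zeros(len(nodes))
    for li in range(len(nodes)):
        acc = 0.0
        for vi, v in enumerate(nodes):
            nbr = [x[nodes.index(u)] for u in g.graph.neighbors(v)]
            acc += weights[li, vi] * x[vi] * (sum(nbr) / d[vi])
        out[li] = (acc - mu**2) / var
    return out


def multisite_inclusion_exclusion(sets: list[set]) -> object:
    """Long-form multiple-site similarity via inclusion-exclusion (exact Fractions)."""
    from fractions import Fraction

    t = len(sets)
    size_sum = sum(len(s) for s in sets)
    if size_sum == 0:
        return Fraction(0)
    numer = 0
    for k in range(2, t + 1):
        sign = 1 if k % 2 == 0 else -1
        for combo in itertools.combinations(sets, k):
            inter = set.intersection(*combo)
            numer += sign * len(inter)
    return Fraction(t, t - 1) * Fraction(numer, size_sum)


def rank_then_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman oracle: average ranks followed by the Pearson correlation."""
    from scipy.stats import rankdata

    rx, ry = rankdata(x), rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def exact_rank_sum_oracle(a, b) -> float:
    """Exhaustive two-sided rank-sum p over all C(n, n_a) rank assignments."""
    from scipy.stats import rankdata

    pooled = np.concatenate([np.asarray(a, float), np.asarray(b, float)])
    ranks = rankdata(pooled)
    n1 = len(a)
    obs = ranks[:n1].sum()
    stats = [
        ranks[list(idx)].sum()
        for idx in itertools.combinations(range(len(pooled)), n1)
    ]
    stats = np.array(stats)
    le = (stats <= obs + 1e-9).mean()
    ge = (stats >= obs - 1e-9).mean()
    return min(1.0, 2.0 * min(le, ge))
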