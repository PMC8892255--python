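"""Correlation graphs, Louvain communities and cohort comparison."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from glykit.coordination import (
    build_graph,
    compare_cohort_graphs,
    correlation_matrix,
    louvain_communities,
)
from glykit.errors import ValidationError


def test_correlation_matrix_basics():
    rng = np.random.default_rng(0)
    x = rng.lognormal(0, 0.3, 50)
    df = pd.DataFrame({"a": x, "b": x**2.0, "c": rng.lognormal(0, 0.3, 50)})
    corr = correlation_matrix(df)
    assert corr.loc["a", "a"] == 1.0
    # y = x^2 is exactly linear on the log scale
    assert corr.loc["a", "b"] == pytest.approx(1.0, abs=1e-12)
    assert corr.equals(corr.T)


def test_correlation_matches_hand_computation_on_small_fixture():
    df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0, 5.0], "b": [2.0, 1.0, 4.0, 3.0, 5.0]})
    corr = correlation_matrix(df, transform="raw")
    a, b = df["a"], df["b"]
    brute = np.mean((a - a.mean()) * (b - b.mean())) / (a.std(ddof=0) * b.std(ddof=0))
    assert corr.loc["a", "b"] == pytest.approx(brute, rel=1e-12)


def test_constant_column_reported_missing():
    df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
    with pytest.warns(UserWarning, match="constant"):
        corr = correlation_matrix(df, transform="raw")
    assert np.isnan(corr.loc["a", "b"])


def _matrix(entries, names=("a", "b", "c")):
    m = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for (i, j), r in entries.items():
        m.loc[i, j] = m.loc[j, i] = r
    return m


def test_cutoff_is_strict():
    m = _matrix({("a", "b"): 0.39, ("a", "c"): 0.41})
    g = build_graph(m, cutoff=0.4)
    assert not g.graph.has_edge("a", "b")
    assert g.graph.has_edge("a", "c")


def test_zero_cutoff_gives_complete_graph_and_raising_removes_edges():
    m = _matrix({("a", "b"): 0.2, ("a", "c"): 0.5, ("b", "c"): 0.7})
    assert build_graph(m, cutoff=0.0).n_edges == 3
    edges = [build_graph(m, cutoff=c).n_edges for c in (0.0, 0.3, 0.6, 0.9)]
    assert edges == sorted(edges, reverse=True)


def test_no_edges_below_cutoff():
    g = build_graph(_matrix({}), cutoff=0.4)
    assert g.n_edges == 0


def test_louvain_separates_disjoint_triangles():
    g = nx.Graph()
    for tri in (("a", "b", "c"), ("x", "y", "z")):
        g.add_weighted_edges_from(
            [(tri[0], tri[1], 1.0), (tri[1], tri[2], 1.0), (tri[0], tri[2], 1.0)]
        )
    from glykit.coordination import CorrelationGraph

    cg = louvain_communities(CorrelationGraph(graph=g, cutoff=0.4), seed=0)
    assert sorted(sorted(c) for c in cg.communities) == [["a", "b", "c"], ["x", "y", "z"]]


def test_edgeless_graph_gives_singletons_and_zero_modularity():
    g = build_graph(_matrix({}), cutoff=0.4)
    cg = louvain_communities(g, seed=0)
    assert len(cg.communities) == 3
    assert cg.modularity == 0.0


def _partitions(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def test_louvain_modularity_matches_exhaustive_search():
    """On a 6-node weighted graph the partition is globally optimal."""
    rng = np.random.default_rng(4)
    nodes = list("abcdef")
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for u, v in itertools.combinations(nodes, 2):
        if rng.uniform() < 0.5:
            g.add_edge(u, v, weight=round(float(rng.uniform(0.4, 1.0)), 2))
    best = max(
        nx.community.modularity(g, [set(p) for p in part], weight="weight")
        for part in _partitions(nodes)
    )
    from glykit.coordination import CorrelationGraph

    cg = louvain_communities(CorrelationGraph(graph=g, cutoff=0.4), seed=1)
    assert cg.modularity == pytest.approx(best, abs=1e-9)


def test_louvain_beats_singleton_partition():
    m = _matrix({("a", "b"): 0.9, ("b", "c"): 0.8})
    cg = louvain_communities(build_graph(m), seed=0)
    singleton = nx.community.modularity(
        cg.graph, [{n} for n in cg.graph.nodes], weight="weight"
    )
    assert cg.modularity >= singleton


def _latent_cohorts(n=120, coupled=True, seed=0):
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    cols = {}
    for i, name in enumerate(["p", "q", "r", "s"]):
        noise = rng.standard_normal(n)
        load = 0.8 if coupled else 0.0
        cols[name] = np.exp(load * z + 0.5 * noise)
    return pd.DataFrame(cols)


def test_latent_factor_raises_total_weight_with_significance():
    h = _latent_cohorts(coupled=False, seed=1)
    nh = _latent_cohorts(coupled=True, seed=2)
    gh = build_graph(correlation_matrix(h))
    gnh = build_graph(correlation_matrix(nh))
    cmp = compare_cohort_graphs(gh, gnh, h, nh, n_permutations=99, seed=3)
    assert cmp.total_weight_difference > 0
    assert cmp.permutation_p < 0.05


def test_identical_graphs_compare_to_nothing():
    h = _latent_cohorts(coupled=True, seed=5)
    g1 = build_graph(correlation_matrix(h))
    g2 = build_graph(correlation_matrix(h))
    cmp = compare_cohort_graphs(g1, g2)
    assert cmp.total_weight_difference == 0.0
    assert all(v == 0.0 for v in cmp.edge_weight_differences.values())
    assert cmp.hubs_h == cmp.hubs_nh


def test_hub_ties_listed_lexicographically():
    m = _matrix({("a", "b"): 0.9, ("c", "b"): 0.0})
    g = build_graph(m)
    assert g.hubs() == ["a", "b"]


def test_mismatched_node_sets_rejected():
    g1 = build_graph(_matrix({}, names=("a", "b", "c")))
    g2 = build_graph(_matrix({}, names=("a", "b", "d")))
    with pytest.raises(ValidationError):
        compare_cohort_graphs(g1, g2)
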