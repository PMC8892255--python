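"""Subsystem coordination: correlation graphs and community detection.

Pairwise correlations between per-subject indices (parameters and Pi
numbers) quantify how tightly physiological subsystems covary.  Indices
span orders of magnitude, so correlations default to the log10 scale
(raw-scale Pearson is available via ``transform="raw"``).  Pairs with
|r| above a cutoff (default 0.4, strict inequality) become weighted
edges of an undirected graph; Louvain community detection groups the
coordinated subsystems, with isolated indices ending up as singleton
communities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ValidationError

DEFAULT_CUTOFF = 0.4


def correlation_matrix(
    cohort_values: pd.DataFrame, transform: str = "log10"
) -> pd.DataFrame:
    """Pearson correlation matrix of per-subject indices.

    ``cohort_values``: one row per subject, one column per index.
    Constant columns have undefined correlations; their entries are NaN
    (except the diagonal) and a warning is emitted.
    """
    df = pd.DataFrame(cohort_values)
    if len(df) < 3:
        raise ValidationError("need at least 3 subjects for correlations")
    if transform == "log10":
        if (df <= 0).any().any():
            raise ValidationError("log10 transform requires strictly positive values")
        df = np.log10(df)
    elif transform != "raw":
        raise ValidationError(f"unknown transform {transform!r}; use 'log10' or 'raw'")
    constant = [c for c in df.columns if np.isclose(df[c].std(ddof=0), 0.0)]
    if constant:
        import warnings

        warnings.warn(f"constant columns have undefined correlations: {constant}", stacklevel=2)
    corr = df.corr()  # pandas leaves NaN for constant columns
    np.fill_diagonal(corr.values, 1.0)
    return corr


@dataclass
class CorrelationGraph:
    """Thresholded correlation graph with optional community structure."""

    graph: nx.Graph
    cutoff: float
    communities: list = field(default_factory=list)  # list of frozensets
    modularity: float | None = None

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, node) -> int:
        return self.graph.degree(node)

    def hubs(self) -> list:
        """Max-degree nodes, ties listed lexicographically."""
        if not self.graph.nodes:
            return []
        degrees = dict(self.graph.degree)
        top = max(degrees.values())
        return sorted(n for n, d in degrees.items() if d == top)

    def total_weight(self) -> float:
        return float(sum(d["weight"] for _, _, d in self.graph.edges(data=True)))

    def edge_weights(self) -> dict:
        return {
            tuple(sorted((u, v))): d["weight"]
            for u, v, d in self.graph.edges(data=True)
        }


def build_graph(matrix: pd.DataFrame, cutoff: float = DEFAULT_CUTOFF) -> CorrelationGraph:
    """Edge (i, j) iff |r_ij| > cutoff (strict); weight |r_ij|."""
    g = nx.Graph()
    cols = list(matrix.columns)
    g.add_nodes_from(cols)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            r = matrix.loc[a, b]
            if np.isfinite(r) and abs(r) > cutoff:
                g.add_edge(a, b, weight=float(abs(r)), r=float(r))
    for node in g.nodes:
        g.nodes[node]["degree"] = g.degree(node)
    return CorrelationGraph(graph=g, cutoff=cutoff)


def louvain_communities(cgraph: CorrelationGraph, seed: int = 0) -> CorrelationGraph:
    """Weighted-modularity Louvain partition; deterministic given seed.

    Isolated nodes come out as singleton communities.  The partition and
    its modularity are stored back on the graph object and returned.
    """
    g = cgraph.graph
    if g.number_of_nodes() == 0:
        raise ValidationError("graph has no nodes")
    if g.number_of_edges() == 0:
        comms = [frozenset([n]) for n in sorted(g.nodes, key=str)]
        cgraph.communities = comms
        cgraph.modularity = 0.0
        return cgraph
    comms = nx.community.louvain_communities(g, weight="weight", seed=seed)
    comms = [frozenset(c) for c in comms]
    cgraph.communities = comms
    cgraph.modularity = float(nx.community.modularity(g, comms, weight="weight"))
    return cgraph


@dataclass(frozen=True)
class GraphComparison:
    edge_weight_differences: dict  # edge -> weight_nh - weight_h (0 when absent)
    edge_count_difference: int  # n_edges_nh - n_edges_h
    total_weight_difference: float  # total_nh - total_h
    hubs_h: tuple
    hubs_nh: tuple
    shared_hubs: tuple
    permutation_p: float | None


def compare_cohort_graphs(
    graph_h: CorrelationGraph,
    graph_nh: CorrelationGraph,
    cohort_values_h: pd.DataFrame | None = None,
    cohort_values_nh: pd.DataFrame | None = None,
    n_permutations: int = 200,
    seed: int = 0,
    transform: str = "log10",
) -> GraphComparison:
    """Compare coordination between cohort graphs over the same node set.

    When the underlying per-subject tables are supplied, a label
    permutation test (seeded) assesses whether the non-healthy cohort's
    total edge weight genuinely exceeds the healthy one's.
    """
    if set(graph_h.nodes) != set(graph_nh.nodes):
        raise ValidationError("cohort graphs must share the same node set")
    w_h = graph_h.edge_weights()
    w_nh = graph_nh.edge_weights()
    diffs = {
        e: w_nh.get(e, 0.0) - w_h.get(e, 0.0) for e in sorted(set(w_h) | set(w_nh))
    }
    observed = graph_nh.total_weight() - graph_h.total_weight()
    perm_p = None
    if cohort_values_h is not None and cohort_values_nh is not None:
        rng = np.random.default_rng(seed)
        pooled = pd.concat(
            [pd.DataFrame(cohort_values_h), pd.DataFrame(cohort_values_nh)],
            ignore_index=True,
        )
        n_h = len(cohort_values_h)
        exceed = 0
        for _ in range(n_permutations):
            idx = rng.permutation(len(pooled))
            a = pooled.iloc[idx[:n_h]]
            b = pooled.iloc[idx[n_h:]]
            ga = build_graph(correlation_matrix(a, transform), graph_h.cutoff)
            gb = build_graph(correlation_matrix(b, transform), graph_nh.cutoff)
            if gb.total_weight() - ga.total_weight() >= observed:
                exceed += 1
        perm_p = (exceed + 1) / (n_permutations + 1)
    hubs_h = tuple(graph_h.hubs())
    hubs_nh = tuple(graph_nh.hubs())
    return GraphComparison(
        edge_weight_differences=diffs,
        edge_count_difference=graph_nh.n_edges - graph_h.n_edges,
        total_weight_difference=float(observed),
        hubs_h=hubs_h,
        hubs_nh=hubs_nh,
        shared_hubs=tuple(sorted(set(hubs_h) & set(hubs_nh))),
        permutation_p=perm_p,
    )
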