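"""Synergy network construction and hub/bottleneck statistics.

Vertices are features weighted by individual occurrence frequency;
edges are the most frequently co-occurring feature pairs (top fraction
of the pair ranking, ties at the cutoff all retained).  Centralities
are computed on the unweighted simple graph.
"""

from __future__ import annotations

import math
import warnings

import networkx as nx
import pandas as pd

from .feature_analysis import OccurrenceTable

__all__ = [
    "build_network",
    "degree_distribution",
    "centralities",
    "hubs_and_bottlenecks",
    "export_graphml",
    "export_edgelist_tsv",
]

#: admissible denominators for the "top fraction of all pairs" cutoff
DENOMINATOR_POLICIES = ("n_squared", "unordered", "nonzero")


def _denominator(table: OccurrenceTable, policy: str) -> int:
    n = table.n_features
    if policy == "n_squared":
        return n * n
    if policy == "unordered":
        return n * (n - 1) // 2
    if policy == "nonzero":
        return len(table.pairs)
    raise ValueError(f"unknown denominator policy {policy!r}")


def build_network(table: OccurrenceTable, top_fraction: float = 0.01,
                  denominator: str = "n_squared") -> nx.Graph:
    """Keep the ceil(top_fraction x denominator) highest-count pairs as
    edges (all ties at the cutoff count included); vertices are the
    endpoints of kept edges, weighted by their occurrence frequency."""
    if not (0 < top_fraction <= 1):
        raise ValueError("top_fraction must be in (0, 1]")
    pairs = table.pairs[table.pairs["count"] > 0]
    g = nx.Graph()
    if pairs.empty:
        warnings.warn("all pair counts are zero; network is empty")
        return g
    n_keep = max(1, math.ceil(top_fraction * _denominator(table, denominator)))
    ranked = pairs.sort_values(["count", "feature_a", "feature_b"],
                               ascending=[False, True, True])
    if len(ranked) > n_keep:
        cutoff = int(ranked["count"].iloc[n_keep - 1])
        ranked = ranked[ranked["count"] >= cutoff]
    freq = dict(zip(table.features["feature"], table.features["frequency"]))
    for row in ranked.itertuples(index=False):
        g.add_edge(row.feature_a, row.feature_b,
                   cooccurrence_frequency=float(row.frequency),
                   count=int(row.count))
    for v in g.nodes:
        g.nodes[v]["occurrence_frequency"] = float(freq.get(v, 0.0))
    return g


def degree_distribution(net: nx.Graph) -> tuple[dict, pd.Series]:
    """Per-vertex degree and the histogram over observed degrees."""
    degrees = dict(net.degree())
    hist = pd.Series(degrees, dtype=int).value_counts().sort_index()
    hist.index.name = "degree"
    hist.name = "n_vertices"
    return degrees, hist


def centralities(net: nx.Graph) -> pd.DataFrame:
    """Unweighted closeness ((n-1)/sum of distances, per connected
    component; isolated vertices get 0) and normalized betweenness."""
    close = nx.closeness_centrality(net, wf_improved=False)
    between = nx.betweenness_centrality(net, normalized=True)
    return pd.DataFrame({"closeness": close, "betweenness": between}).sort_index()


def hubs_and_bottlenecks(net: nx.Graph, top_n: int = 20,
                         degree_threshold: int = 10) -> dict:
    """Joint vertex ranking by (degree, closeness, betweenness) plus the
    listing of vertices above the degree threshold."""
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    cent = centralities(net)
    degrees, _ = degree_distribution(net)
    report = cent.copy()
    report.insert(0, "degree", pd.Series(degrees))
    # sort by name first so the stable metric sort breaks ties lexicographically
    report = report.sort_index()
    report = report.sort_values(["degree", "closeness", "betweenness"],
                                ascending=[False, False, False], kind="stable")
    report["degree_rank"] = report["degree"].rank(ascending=False, method="min").astype(int)
    report["closeness_rank"] = report["closeness"].rank(ascending=False, method="min").astype(int)
    report["betweenness_rank"] = report["betweenness"].rank(ascending=False, method="min").astype(int)
    high_degree = sorted([v for v, d in degrees.items() if d > degree_threshold],
                         key=lambda v: (-degrees[v], v))
    return {"ranking": report.head(top_n), "high_degree": high_degree}


def export_graphml(net: nx.Graph, path) -> None:
    nx.write_graphml(net, path)


def export_edgelist_tsv(net: nx.Graph, path) -> None:
    rows = [(a, b, d.get("cooccurrence_frequency", 0.0), d.get("count", 0))
            for a, b, d in net.edges(data=True)]
    pd.DataFrame(rows, columns=["feature_a", "feature_b",
                                "cooccurrence_frequency", "count"]
                 ).sort_values(["cooccurrence_frequency", "feature_a", "feature_b"],
                               ascending=[False, True, True]
                 ).to_csv(path, sep="\t", index=False)
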