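"""Centrality statistics for undirected protein-protein interaction graphs.

Degree is the neighbour count.  Betweenness is Brandes shortest-path
betweenness normalised by (n-1)(n-2)/2, and closeness is the
Wasserman-Faust component-scaled form: (r-1)/sum(d) within the node's
component, scaled by (r-1)/(n-1) where r is the number of reachable nodes
— the conventions of the Cytoscape Network Analyser, so all values land in
[0, 1] and disconnected graphs are handled gracefully.  Users comparing to
tools with other conventions can pass ``normalized=False``.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd


def as_ppi_graph(edges) -> nx.Graph:
    """Build an undirected simple graph: self-loops dropped, parallel edges collapsed."""
    g = nx.Graph()
    for u, v in edges:
        if u != v:
            g.add_edge(u, v)
    return g


def centrality_table(graph: nx.Graph, normalized: bool = True) -> pd.DataFrame:
    """Degree, betweenness and closeness for every node, sorted by degree.

    Isolated nodes get closeness 0 by convention.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    bet = nx.betweenness_centrality(graph, normalized=normalized)
    clo = nx.closeness_centrality(graph, wf_improved=normalized)
    df = pd.DataFrame(
        {
            "node": list(graph.nodes),
            "degree": [graph.degree(n) for n in graph.nodes],
            "betweenness": [bet[n] for n in graph.nodes],
            "closeness": [clo[n] for n in graph.nodes],
        }
    )
    return df.sort_values(["degree", "node"], ascending=[False, True], ignore_index=True)


def high_degree_nodes(records: pd.DataFrame, degree_threshold: int = 75) -> pd.DataFrame:
    """Nodes with degree strictly greater than the threshold, sorted.

    Sorted by degree descending, ties broken by node id.
    """
    hits = records[records["degree"] > degree_threshold]
    return hits.sort_values(["degree", "node"], ascending=[False, True], ignore_index=True)
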