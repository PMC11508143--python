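"""Thresholded co-expression graphs and node centralities.

The TOM matrix is thresholded (default 0.1, "to include all connections")
into an undirected graph whose nodes are the genes with at least one
surviving edge. Whole-network statistics mirror a Cytoscape-style network
analysis: node/edge counts, average and median degree, the diameter of the
largest connected component, and the average clustering coefficient. Node
importance is measured by four centralities — degree (DG), betweenness (BW),
closeness (CN) and the local clustering coefficient (CC) — all on the
unweighted graph, with BW and CN computed and normalized within each
connected component so every value lies in [0, 1] even on fragmented
networks.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd


def build_network(tom: pd.DataFrame, min_weight: float = 0.1) -> nx.Graph:
    """Threshold a TOM (or adjacency) matrix into an undirected graph.

    An edge (i, j) exists iff t[i, j] >= min_weight for i != j; genes with no
    surviving edge are excluded from the graph entirely.
    """
    if not 0 < min_weight <= 1:
        raise ValueError(f"min_weight must be in (0, 1], got {min_weight}")
    vals = tom.to_numpy(dtype=float)
    n = vals.shape[0]
    ii, jj = np.where(np.triu(vals >= min_weight, k=1))
    g = nx.Graph()
    genes = np.asarray(tom.index, dtype=object)
    g.add_weighted_edges_from(
        (genes[i], genes[j], float(vals[i, j])) for i, j in zip(ii, jj)
    )
    return g


@dataclass
class NetworkStats:
    """Cytoscape-style whole-network summary."""

    n_nodes: int
    n_edges: int
    average_degree: float
    median_degree: float
    diameter: int
    average_clustering: float
    empty: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(self)])


def network_properties(g: nx.Graph) -> NetworkStats:
    """Node/edge counts, degree summaries, largest-component diameter and
    average clustering coefficient; an empty graph yields all-zero stats with
    the ``empty`` flag set."""
    n, e = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        return NetworkStats(0, 0, 0.0, 0.0, 0, 0.0, empty=True)
    degrees = np.array([d for _, d in g.degree()])
    largest = max(nx.connected_components(g), key=len)
    diameter = nx.diameter(g.subgraph(largest)) if len(largest) > 1 else 0
    return NetworkStats(
        n_nodes=n,
        n_edges=e,
        average_degree=2.0 * e / n,
        median_degree=float(np.median(degrees)),
        diameter=int(diameter),
        average_clustering=float(nx.average_clustering(g)),
    )


def node_centralities(g: nx.Graph) -> pd.DataFrame:
    """Per-node DG, BW, CN and CC on the unweighted graph.

    DG is the raw degree (edge count). BW is betweenness normalized by
    (n_c - 1)(n_c - 2)/2 within the node's connected component of size n_c;
    CN is classic closeness (n_c - 1) / sum of shortest-path distances within
    the component; CC is the local clustering coefficient. Isolated
    components of size < 3 give BW = 0; size-1 components give CN = 0.
    """
    nodes = list(g.nodes())
    if not nodes:
        return pd.DataFrame(columns=["DG", "BW", "CN", "CC"])
    dg = pd.Series(dict(g.degree()), dtype=float)
    cc = pd.Series(nx.clustering(g), dtype=float)
    bw = pd.Series(0.0, index=nodes)
    cn = pd.Series(0.0, index=nodes)
    for comp in nx.connected_components(g):
        comp = list(comp)
        nc = len(comp)
        if nc == 1:
            continue
        h = ig.Graph.from_networkx(g.subgraph(comp))
        names = h.vs["_nx_name"]
        if nc > 2:
            raw_bw = np.asarray(h.betweenness(directed=False))
            bw.loc[names] = raw_bw / ((nc - 1) * (nc - 2) / 2.0)
        cn.loc[names] = np.asarray(h.closeness(mode="all"))
    out = pd.DataFrame({"DG": dg, "BW": bw, "CN": cn, "CC": cc})
    out.index.name = "gene_id"
    return out.loc[nodes]


def write_edge_list(g: nx.Graph, path) -> None:
    """Cytoscape-importable TSV: source, target, weight."""
    rows = sorted(
        (str(u), str(v), d.get("weight", 1.0)) if str(u) <= str(v) else (str(v), str(u), d.get("weight", 1.0))
        for u, v, d in g.edges(data=True)
    )
    df = pd.DataFrame(rows, columns=["source", "target", "weight"])
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_edge_list(path) -> nx.Graph:
    df = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    g.add_weighted_edges_from(df.itertuples(index=False, name=None))
    return g
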