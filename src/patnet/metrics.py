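"""Node centralities and global characteristics of a psychosocial network.

Centralities follow the symptom-network conventions:

* degree — number of retained edges on the node;
* strength — sum of absolute edge weights (weighted degree);
* betweenness — fraction of all-pairs shortest paths through the node, with
  edge length 1/|w| (a stronger correlation is a shorter path), normalised by
  (n-1)(n-2)/2;
* closeness — Wasserman–Faust component-scaled closeness on the same lengths:
  (reachable / (n-1)) * (reachable / sum of distances); isolated nodes get 0.

Global metrics mirror the usual desktop-tool report: average degree 2E/n,
density 2E/(n(n-1)), diameter and average path length as unweighted hop
metrics on the largest connected component (the estimated networks are
disconnected, so a convention is required), number of connected components,
mean binary local clustering coefficient (nodes of degree < 2 contribute 0),
and the modularity of the partition found by deterministic greedy
(Clauset–Newman–Moore) modularity maximisation.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from typing import Union

import networkx as nx
import pandas as pd

from .network import NetworkResults

GraphLike = Union[nx.Graph, NetworkResults]


def _as_graph(network: GraphLike) -> nx.Graph:
    if isinstance(network, NetworkResults):
        return network.graph(retained_only=True)
    return network


def centralities(network: GraphLike) -> pd.DataFrame:
    """Per-node centrality report, in node (catalog) order."""
    g = _as_graph(network)
    rows = []
    if len(g) == 0:
        return pd.DataFrame(
            columns=["id", "label", "subscale", "degree", "strength",
                     "betweenness", "closeness"]
        )
    betweenness = nx.betweenness_centrality(g, weight="length", normalized=True)
    closeness = nx.closeness_centrality(g, distance="length", wf_improved=True)
    for node, data in g.nodes(data=True):
        strength = sum(
            d.get("abs_weight", abs(d.get("weight", 1.0)))
            for _, _, d in g.edges(node, data=True)
        )
        rows.append(
            {
                "id": node,
                "label": data.get("label", str(node)),
                "subscale": data.get("subscale", ""),
                "degree": g.degree(node),
                "strength": float(strength),
                "betweenness": float(betweenness[node]),
                "closeness": float(closeness[node]),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GlobalMetrics:
    """Whole-network characteristics."""

    average_degree: float
    network_diameter: int
    graph_density: float
    modularity: float
    connected_components: int
    average_clustering_coef: float
    average_path_length: float

    def to_dict(self) -> dict:
        return asdict(self)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"metric": k, "value": v} for k, v in asdict(self).items()]
        )


def global_metrics(network: GraphLike) -> GlobalMetrics:
    """Global characteristics of the (thresholded) network.

    Diameter and average path length are unweighted hop metrics on the
    largest connected component; for a component of a single node both are 0.
    Modularity is NaN on an edgeless graph (undefined).
    """
    g = _as_graph(network)
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("global metrics need at least 2 nodes (density undefined)")
    e = g.number_of_edges()
    components = list(nx.connected_components(g))
    largest = g.subgraph(max(components, key=len))
    if largest.number_of_nodes() > 1:
        diameter = int(nx.diameter(largest))
        apl = float(nx.average_shortest_path_length(largest))
    else:
        diameter, apl = 0, 0.0
    if e > 0:
        communities = nx.community.greedy_modularity_communities(g)
        modularity = float(nx.community.modularity(g, communities))
    else:
        modularity = float("nan")
    return GlobalMetrics(
        average_degree=2.0 * e / n,
        network_diameter=diameter,
        graph_density=2.0 * e / (n * (n - 1)),
        modularity=modularity,
        connected_components=len(components),
        average_clustering_coef=float(nx.average_clustering(g)),
        average_path_length=apl,
    )
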