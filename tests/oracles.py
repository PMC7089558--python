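"""Independent brute-force oracles for graph centralities.

These enumerate *all* simple paths between every node pair (depth-first, with
pruning only on the running length bound), so they share no code path with the
networkx Dijkstra/Brandes implementations they check. Practical up to ~8
nodes.
"""

from __future__ import annotations

import math

import networkx as nx


def _all_shortest_simple_paths(g: nx.Graph, source, target, length_attr: str):
    """Return (min_length, list of minimal simple paths) via exhaustive DFS."""
    best = [math.inf]
    paths: list[list] = []

    def dfs(node, visited, length, path):
        if length > best[0] + 1e-12:
            return
        if node == target:
            if length < best[0] - 1e-12:
                best[0] = length
                paths.clear()
            if abs(length - best[0]) <= 1e-12:
                paths.append(list(path))
            return
        for nbr in g.neighbors(node):
            if nbr in visited:
                continue
            w = g.edges[node, nbr].get(length_attr, 1.0)
            visited.add(nbr)
            path.append(nbr)
            dfs(nbr, visited, length + w, path)
            path.pop()
            visited.remove(nbr)

    dfs(source, {source}, 0.0, [source])
    return best[0], paths


def brute_betweenness(g: nx.Graph, length_attr: str = "length") -> dict:
    """Normalized betweenness: sum over pairs of the fraction of shortest
    paths through the node, divided by (n-1)(n-2)/2."""
    nodes = list(g.nodes)
    n = len(nodes)
    score = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            dist, paths = _all_shortest_simple_paths(g, s, t, length_attr)
            if not paths:
                continue
            sigma = len(paths)
            for v in nodes:
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p[1:-1])
                score[v] += through / sigma
    norm = (n - 1) * (n - 2) / 2.0
    if norm > 0:
        score = {v: x / norm for v, x in score.items()}
    return score


def brute_closeness(g: nx.Graph, length_attr: str = "length") -> dict:
    """Wasserman-Faust component-scaled closeness from exhaustive shortest
    path lengths; isolated nodes score 0."""
    nodes = list(g.nodes)
    n = len(nodes)
    out = {}
    for v in nodes:
        dists = []
        for u in nodes:
            if u == v:
                continue
            d, paths = _all_shortest_simple_paths(g, v, u, length_attr)
            if paths:
                dists.append(d)
        if not dists or sum(dists) == 0:
            out[v] = 0.0
            continue
        reachable = len(dists)
        out[v] = (reachable / sum(dists)) * (reachable / (n - 1))
    return out


def brute_strength(g: nx.Graph, weight_attr: str = "abs_weight") -> dict:
    return {
        v: sum(d.get(weight_attr, abs(d.get("weight", 1.0)))
               for _, _, d in g.edges(v, data=True))
        for v in g.nodes
    }


def random_weighted_graph(rng, n_max: int = 8, p_edge: float = 0.4) -> nx.Graph:
    """Random undirected graph with |w| in (0.1, 1] edge weights and the
    ``length`` = 1/|w| attribute the package uses for path metrics."""
    n = int(rng.integers(3, n_max + 1))
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.uniform() < p_edge:
                w = float(rng.uniform(0.1, 1.0))
                sign = 1.0 if rng.uniform() < 0.8 else -1.0
                g.add_edge(i, j, weight=sign * w, abs_weight=w, length=1.0 / w)
    return g
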