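"""Independent oracles used by the tests.

The centrality oracle enumerates every simple path exhaustively, with no
shortest-path algorithm shared with the implementation, so agreement is a
genuine cross-check.
"""

from itertools import combinations

import numpy as np

REL_TIE_TOL = 1e-12


def _all_simple_paths(adj, start, goal):
    """All simple paths start -> goal by DFS on an adjacency dict."""
    paths, stack = [], [(start, [start])]
    while stack:
        node, path = stack.pop()
        if node == goal:
            paths.append(path)
            continue
        for nbr in adj[node]:
            if nbr not in path:
                stack.append((nbr, path + [nbr]))
    return paths


def brute_force_centralities(graph):
    """Betweenness (unnormalised) and closeness by exhaustive enumeration.

    Edge 'length' attributes define path length. Shortest paths per pair are
    all simple paths within relative tie tolerance of the minimum total
    length; betweenness credit is split over them. Closeness is per
    connected component: (n_c - 1) / sum of shortest distances.
    """
    nodes = list(graph.nodes)
    adj = {n: list(graph.neighbors(n)) for n in nodes}
    length = {(u, v): d["length"] for u, v, d in graph.edges(data=True)}
    length.update({(v, u): l for (u, v), l in list(length.items())})

    betw = {n: 0.0 for n in nodes}
    dist = {n: {} for n in nodes}
    for s, t in combinations(nodes, 2):
        paths = _all_simple_paths(adj, s, t)
        if not paths:
            continue
        lengths = [sum(length[(p[i], p[i + 1])] for i in range(len(p) - 1))
                   for p in paths]
        dmin = min(lengths)
        shortest = [p for p, l in zip(paths, lengths)
                    if l <= dmin * (1 + REL_TIE_TOL) + 1e-300]
        dist[s][t] = dist[t][s] = dmin
        for p in shortest:
            for v in p[1:-1]:
                betw[v] += 1.0 / len(shortest)

    # connected components from reachability
    close = {}
    for n in nodes:
        reachable = set(dist[n])
        if not reachable:
            close[n] = 0.0
            continue
        close[n] = len(reachable) / sum(dist[n].values())
    return betw, close


def random_connected_graph(rng, max_nodes=8):
    """Random positive-weight connected graph for oracle comparison."""
    import networkx as nx

    while True:
        n = int(rng.integers(4, max_nodes + 1))
        p = float(rng.uniform(0.35, 0.9))
        w = rng.uniform(0.05, 1.0, size=(n, n))
        keep = rng.uniform(size=(n, n)) < p
        g = nx.Graph()
        g.add_nodes_from(range(n))
        for i in range(n):
            for j in range(i + 1, n):
                if keep[i, j]:
                    g.add_edge(i, j, weight=w[i, j], length=1.0 / w[i, j])
        if nx.is_connected(g):
            return g
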