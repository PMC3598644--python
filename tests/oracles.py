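"""Brute-force reference implementations used to cross-check the package.

These stay independent of the code paths they verify: plain BFS over
adjacency dicts, explicit shortest-path counting, and dense power
iteration for PageRank.
"""

from collections import deque

import numpy as np


def adjacency(graph):
    adj = {v: set() for v in graph.nodes}
    for a, b in graph.edges:
        adj[a].add(b)
        adj[b].add(a)
    return adj


def bfs_distances(adj, source):
    dist = {source: 0}
    q = deque([source])
    while q:
        v = q.popleft()
        for w in adj[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                q.append(w)
    return dist


def closeness_oracle(graph):
    """Component-wise closeness: (reachable-1)/sum(dist); isolated -> 0."""
    adj = adjacency(graph)
    out = []
    for v in sorted(adj):
        dist = bfs_distances(adj, v)
        total = sum(dist.values())
        out.append((len(dist) - 1) / total if total > 0 else 0.0)
    return np.array(out)


def _path_counts(adj, source):
    """Geodesic distances and shortest-path counts from one source."""
    dist = {source: 0}
    sigma = {source: 1}
    q = deque([source])
    while q:
        v = q.popleft()
        for w in adj[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                sigma[w] = 0
                q.append(w)
            if dist[w] == dist[v] + 1:
                sigma[w] += sigma[v]
    return dist, sigma


def betweenness_oracle(graph):
    """Unnormalized betweenness by explicit pair-by-pair path counting."""
    adj = adjacency(graph)
    nodes = sorted(adj)
    dist = {}
    sigma = {}
    for s in nodes:
        dist[s], sigma[s] = _path_counts(adj, s)
    out = []
    for v in nodes:
        score = 0.0
        for i, s in enumerate(nodes):
            for t in nodes[i + 1:]:
                if v in (s, t) or t not in dist[s]:
                    continue
                if v in dist[s] and v in dist[t]:
                    if dist[s][v] + dist[t][v] == dist[s][t]:
                        score += sigma[s][v] * sigma[t][v] / sigma[s][t]
        out.append(score)
    return np.array(out)


def pagerank_oracle(graph, damping=0.85, tol=1e-14, max_iter=100000):
    """Dense power iteration; dangling mass spread uniformly."""
    nodes = sorted(graph.nodes)
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    deg = np.zeros(n)
    A = np.zeros((n, n))
    for a, b in graph.edges:
        A[index[a], index[b]] = 1.0
        A[index[b], index[a]] = 1.0
    deg = A.sum(axis=1)
    x = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        flow = np.zeros(n)
        for j in range(n):
            if deg[j] > 0:
                flow += x[j] * A[j] / deg[j]
            else:
                flow += x[j] / n
        new = (1.0 - damping) / n + damping * flow
        if np.abs(new - x).sum() < tol:
            return new
        x = new
    return x


def pearson_oracle(x, y):
    """Closed-form Pearson correlation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


def random_graphs(n_graphs=100, max_n=12, seed=0):
    """Seeded Erdős–Rényi graphs (as networkx objects) for oracle sweeps."""
    import networkx as nx

    rng = np.random.default_rng(seed)
    graphs = []
    for _ in range(n_graphs):
        n = int(rng.integers(2, max_n + 1))
        p = float(rng.uniform(0.15, 0.7))
        g = nx.Graph()
        g.add_nodes_from(range(n))
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < p:
                    g.add_edge(i, j)
        graphs.append(g)
    return graphs
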