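"""Residue-interaction graph and node-centrality scores.

Residues are nodes; an undirected unit-length edge joins two residues whose
closest heavy atoms lie within a distance cutoff.  Raw centralities
(closeness, betweenness, PageRank) are converted to rank percentiles in
(0, 1] before entering the feature table, so only the ordering matters.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
from scipy.spatial import cKDTree
from scipy.stats import rankdata

from .structure import ProteinChain

DEFAULT_CONTACT_CUTOFF = 4.5  # Å, minimum heavy-atom distance


class UndefinedCentralityError(ValueError):
    """Centrality requested on a graph where it is undefined (single node)."""


def build_contact_graph(chain: ProteinChain, cutoff: float = DEFAULT_CONTACT_CUTOFF) -> nx.Graph:
    """Contact graph: edge (i, j) iff min heavy-atom distance ≤ *cutoff* Å.

    The graph always contains one node per residue (indices 0..n-1) and may
    be disconnected.
    """
    if len(chain) == 0:
        raise ValueError("empty chain")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    graph = nx.Graph()
    graph.add_nodes_from(range(len(chain)))
    coords = []
    owner = []
    for i, res in enumerate(chain.residues):
        for atom in res.atoms:
            coords.append(atom.coord)
            owner.append(i)
    coords = np.asarray(coords)
    owner = np.asarray(owner)
    tree = cKDTree(coords)
    for a, b in tree.query_pairs(cutoff):
        i, j = owner[a], owner[b]
        if i != j:
            graph.add_edge(int(min(i, j)), int(max(i, j)))
    return graph


def read_contact_table(text: str, n_residues: int) -> nx.Graph:
    """Adapter for an externally produced contact table.

    Each non-empty, non-comment line holds two whitespace-separated 1-based
    residue ordinals forming one undirected contact.
    """
    graph = nx.Graph()
    graph.add_nodes_from(range(n_residues))
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"contact table line {lineno}: expected two ordinals")
        i, j = int(parts[0]) - 1, int(parts[1]) - 1
        if not (0 <= i < n_residues and 0 <= j < n_residues):
            raise ValueError(f"contact table line {lineno}: ordinal out of range")
        if i != j:
            graph.add_edge(i, j)
    return graph


def _as_vector(graph: nx.Graph, mapping: dict) -> np.ndarray:
    return np.array([mapping[v] for v in sorted(graph.nodes)], dtype=float)


def closeness_centrality(graph: nx.Graph) -> np.ndarray:
    """Closeness = (n_reachable − 1) / Σ geodesic distances, per component.

    Isolated nodes score 0.  Raises on a single-node graph, where the
    measure is undefined.
    """
    if graph.number_of_nodes() < 2:
        raise UndefinedCentralityError("closeness undefined on a single-node graph")
    return _as_vector(graph, nx.closeness_centrality(graph, wf_improved=False))


def betweenness_centrality(graph: nx.Graph) -> np.ndarray:
    """Unnormalized betweenness over unordered node pairs."""
    if graph.number_of_nodes() < 2:
        raise UndefinedCentralityError("betweenness undefined on a single-node graph")
    return _as_vector(graph, nx.betweenness_centrality(graph, normalized=False))


def pagerank_centrality(graph: nx.Graph, damping: float = 0.85) -> np.ndarray:
    """Stationary PageRank on the undirected graph; scores sum to 1.

    Iterated until the successive-vector L1 change drops below 1e-12.
    """
    if not 0 < damping < 1:
        raise ValueError("damping must be in (0, 1)")
    n = graph.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph")
    scores = nx.pagerank(graph, alpha=damping, tol=1e-12 / n, max_iter=100000)
    return _as_vector(graph, scores)


def rank_percentile(scores: np.ndarray) -> np.ndarray:
    """Ascending rank percentile in (0, 1]; ties take their mean rank.

    The strict maximum maps to exactly 1.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("no scores")
    return rankdata(scores, method="average") / scores.size
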