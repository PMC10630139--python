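"""Shared Leiden clustering helpers on a dense embedding.

Builds a symmetrized k-nearest-neighbor graph with scikit-learn and runs
leidenalg's RBConfiguration partition directly; a prebuilt graph can be
reused across resolutions when sweeping.
"""

from __future__ import annotations

import igraph as ig
import leidenalg
import numpy as np
from sklearn.neighbors import NearestNeighbors


def knn_graph(X: np.ndarray, n_neighbors: int = 15) -> ig.Graph:
    """Undirected kNN graph (union symmetrization) over rows of ``X``."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    k = int(min(n_neighbors, n - 1))
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)
    src = np.repeat(np.arange(n), k)
    dst = idx[:, 1:].ravel()  # drop self
    edges = {(min(a, b), max(a, b)) for a, b in zip(src, dst)}
    g = ig.Graph(n=n, edges=sorted(edges), directed=False)
    return g


def leiden_partition(graph: ig.Graph, resolution: float = 1.0, seed: int = 0) -> np.ndarray:
    part = leidenalg.find_partition(
        graph, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=seed, n_iterations=2)
    return np.asarray(part.membership)


def leiden_cluster(X: np.ndarray, resolution: float = 1.0, seed: int = 0,
                   n_neighbors: int = 15) -> np.ndarray:
    """Leiden community labels for rows of ``X``."""
    return leiden_partition(knn_graph(X, n_neighbors), resolution=resolution, seed=seed)
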