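"""Cell subpopulation detection from the cell loading matrix.

A shared-nearest-neighbor (SNN) graph is built over cells using their
columns of ``H`` (k = 20 nearest neighbors by default) and partitioned
with the Leiden algorithm at resolution 1.
"""
from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors


@dataclass
class ClusterResult:
    labels: np.ndarray
    k_neighbors: int
    resolution: float

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))


def build_snn_graph(H: np.ndarray, k: int = 20, weight: str = "jaccard") -> ig.Graph:
    """Shared-nearest-neighbor graph over the columns (cells) of ``H``.

    Each cell's k nearest neighbors (Euclidean, excluding the cell
    itself) define a neighbor set; the edge weight between two cells is
    the overlap of their neighbor sets — Jaccard
    ``|N(i) ∩ N(j)| / |N(i) ∪ N(j)|`` by default, or the shared count
    over k with ``weight="fraction"``. Zero-weight edges are dropped.
    """
    H = np.asarray(H, dtype=float)
    if not np.all(np.isfinite(H)):
        raise ValueError("H must be finite")
    n = H.shape[1]
    if n <= k:
        raise ValueError(f"need more cells than neighbors (n={n}, k={k})")
    if weight not in ("jaccard", "fraction"):
        raise ValueError("weight must be 'jaccard' or 'fraction'")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(H.T)
    _, idx = nn.kneighbors(H.T)
    idx = idx[:, 1:]  # drop self
    B = sp.csr_matrix((np.ones(idx.size), (np.repeat(np.arange(n), k), idx.ravel())),
                      shape=(n, n))
    shared = (B @ B.T).tocoo()  # |N(i) ∩ N(j)|
    mask = shared.row < shared.col
    rows, cols, inter = shared.row[mask], shared.col[mask], shared.data[mask]
    if weight == "jaccard":
        weights = inter / (2 * k - inter)
    else:
        weights = inter / k
    keep = weights > 0
    g = ig.Graph(n=n, edges=list(zip(rows[keep].tolist(), cols[keep].tolist())))
    g.es["weight"] = weights[keep].tolist()
    return g


def leiden_cluster(graph: ig.Graph, resolution: float = 1.0,
                   seed: int | None = 0, k_neighbors: int = 20) -> ClusterResult:
    """Leiden partition (RB-configuration modularity) of an SNN graph."""
    if graph.vcount() == 0:
        raise ValueError("empty graph")
    weights = graph.es["weight"] if "weight" in graph.es.attributes() else None
    part = leidenalg.find_partition(
        graph, leidenalg.RBConfigurationVertexPartition,
        weights=weights, resolution_parameter=resolution,
        seed=-1 if seed is None else int(seed))
    labels = np.asarray(part.membership)
    # contiguous IDs ordered by first appearance
    _, labels = np.unique(labels, return_inverse=True)
    first = {l: np.argmax(labels == l) for l in np.unique(labels)}
    order = sorted(first, key=first.get)
    remap = {old: new for new, old in enumerate(order)}
    labels = np.asarray([remap[l] for l in labels])
    return ClusterResult(labels=labels, k_neighbors=k_neighbors,
                         resolution=resolution)


def cluster_cells(H: np.ndarray, k: int = 20, resolution: float = 1.0,
                  seed: int | None = 0, weight: str = "jaccard") -> ClusterResult:
    """Convenience wrapper: SNN graph construction + Leiden partition."""
    g = build_snn_graph(H, k=k, weight=weight)
    return leiden_cluster(g, resolution=resolution, seed=seed, k_neighbors=k)
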