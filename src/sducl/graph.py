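"""Spatial relationship graph: KNN adjacency and its derived matrices.

Spots are connected to their K nearest neighbors by Euclidean distance in
the metric (pixel) coordinates; the directed KNN relation is symmetrized by
union so the adjacency is a 0/1 symmetric matrix with zero diagonal.  From A
we derive the self-loop-normalized adjacency D̂^(-1/2)(A+I)D̂^(-1/2) used by
graph-convolution layers and the combinatorial Laplacian L = D − A that
generates signal diffusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

__all__ = ["SpatialGraph", "build_knn_graph", "normalized_adjacency", "laplacian"]


@dataclass
class SpatialGraph:
    """Adjacency and derived operators of the spot KNN graph."""

    A: np.ndarray          # (N, N) symmetric 0/1, zero diagonal
    A_hat_norm: np.ndarray  # D̂^{-1/2} (A + I) D̂^{-1/2}
    L: np.ndarray          # combinatorial Laplacian D − A
    k: int

    @property
    def n_nodes(self) -> int:
        return self.A.shape[0]

    def edge_list(self) -> np.ndarray:
        """Upper-triangular edge list as an (n_edges, 2) int array."""
        iu, ju = np.nonzero(np.triu(self.A, 1))
        return np.column_stack([iu, ju])

    def save_edge_list(self, path) -> None:
        np.savetxt(path, self.edge_list(), fmt="%d", delimiter="\t")


def _knn_indices(coords: np.ndarray, k: int) -> np.ndarray:
    """k nearest neighbor indices per node, self excluded, ties by index.

    Regular grids produce many exact distance ties, which generic KNN
    libraries break arbitrarily; for reproducibility neighbors are ranked by
    (distance, index).  Small problems use the exact pairwise matrix; large
    ones a tree query with a tie-stable re-ranking of its candidate set.
    """
    n = coords.shape[0]
    if n <= 4096:
        from scipy.spatial.distance import cdist

        d2 = cdist(coords, coords, "sqeuclidean")
        np.fill_diagonal(d2, np.inf)
        # lexsort: primary key distance, secondary key column index
        order = np.lexsort((np.tile(np.arange(n), (n, 1)), d2), axis=1)
        return order[:, :k]
    extra = min(n - 1, k + 8)  # headroom so boundary ties rank stably
    nn = NearestNeighbors(n_neighbors=extra + 1).fit(coords)
    dist, idx = nn.kneighbors(coords)
    out = np.empty((n, k), dtype=int)
    for i in range(n):
        cand = sorted((d, j) for d, j in zip(dist[i], idx[i]) if j != i)
        out[i] = [j for _, j in cand[:k]]
    return out


def build_knn_graph(coords: np.ndarray, k: int = 6) -> SpatialGraph:
    """Build the spatial KNN graph over spot coordinates.

    Parameters
    ----------
    coords
        ``(N, 2)`` (or ``(N, d)``) metric positions.
    k
        Neighbors per node (default 6, matching the hexagonal packing of
        Visium spots).  Edges are symmetrized by union: (i, j) is an edge if
        j is among i's k nearest OR i among j's.  Distance ties are broken
        by smaller node index, so the graph is deterministic.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 spots to build a graph")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of spots ({n})")
    if k < 1:
        raise ValueError("k must be positive")

    idx = _knn_indices(coords, k)
    A = np.zeros((n, n), dtype=float)
    rows = np.repeat(np.arange(n), k)
    A[rows, idx.ravel()] = 1.0
    A = np.maximum(A, A.T)  # union symmetrization
    np.fill_diagonal(A, 0.0)
    return SpatialGraph(A=A, A_hat_norm=normalized_adjacency(A), L=laplacian(A), k=k)


def normalized_adjacency(A: np.ndarray) -> np.ndarray:
    """Self-loop symmetric normalization D̂^(-1/2)(A+I)D̂^(-1/2)."""
    A = np.asarray(A, dtype=float)
    A_hat = A + np.eye(A.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(A_hat.sum(axis=1))
    return A_hat * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def laplacian(A: np.ndarray) -> np.ndarray:
    """Combinatorial Laplacian L = D − A (rows sum to zero)."""
    A = np.asarray(A, dtype=float)
    return np.diag(A.sum(axis=1)) - A
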