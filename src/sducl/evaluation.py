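"""Clustering of learned embeddings and the six evaluation metrics.

External metrics (require ground truth): Adjusted Rand Index, Normalized
Mutual Information (arithmetic-mean normalization), V-measure, and Purity,
all computed from the contingency table of the two partitions.  Internal
metrics (no labels needed): Silhouette Coefficient and Davies–Bouldin Index
on Euclidean distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Dict, Optional

import numpy as np

__all__ = [
    "ClusteringReport",
    "cluster_embeddings",
    "external_metrics",
    "internal_metrics",
    "evaluate",
]


@dataclass
class ClusteringReport:
    labels_pred: np.ndarray
    metrics: Dict[str, float]
    n_clusters: int
    method: str
    seed: int = 0

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "method": self.method,
                "n_clusters": self.n_clusters,
                "seed": self.seed,
                "metrics": self.metrics,
            },
            indent=2,
        )


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


def cluster_embeddings(
    H: np.ndarray,
    n_clusters: int,
    method: str = "kmeans",
    seed: int = 0,
    leiden_resolution: float = 1.0,
) -> np.ndarray:
    """Partition embedding rows into spatial-domain clusters.

    ``kmeans`` (default, 20 restarts) and ``gmm`` need ``n_clusters``;
    ``leiden`` clusters a KNN graph of the embeddings at the given
    resolution and ignores ``n_clusters``.  Deterministic given ``seed``.
    """
    H = np.asarray(H, dtype=float)
    N = H.shape[0]
    if method in ("kmeans", "gmm"):
        if not 2 <= n_clusters <= N:
            raise ValueError(f"n_clusters={n_clusters} out of range [2, {N}]")
    if method == "kmeans":
        from sklearn.cluster import KMeans

        return KMeans(
            n_clusters=n_clusters, n_init=20, random_state=seed
        ).fit_predict(H)
    if method == "gmm":
        from sklearn.mixture import GaussianMixture

        return GaussianMixture(
            n_components=n_clusters, covariance_type="full", random_state=seed,
            n_init=5,
        ).fit_predict(H)
    if method == "leiden":
        import igraph as ig
        import leidenalg
        from sklearn.neighbors import kneighbors_graph

        knn = kneighbors_graph(H, n_neighbors=min(15, N - 1), mode="connectivity")
        knn = knn.maximum(knn.T).tocoo()
        g = ig.Graph(
            n=N, edges=list(zip(knn.row.tolist(), knn.col.tolist()))
        ).simplify()
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=leiden_resolution,
            seed=seed,
        )
        return np.asarray(part.membership)
    raise ValueError(f"unknown clustering method {method!r}")


# ---------------------------------------------------------------------------
# External metrics (ground truth available)
# ---------------------------------------------------------------------------


def _contingency(labels_true, labels_pred) -> np.ndarray:
    t_codes, _ = _codes(labels_true)
    p_codes, _ = _codes(labels_pred)
    n_t, n_p = t_codes.max() + 1, p_codes.max() + 1
    C = np.zeros((n_t, n_p), dtype=np.int64)
    np.add.at(C, (t_codes, p_codes), 1)
    return C


def _codes(labels):
    labels = np.asarray(labels)
    _, codes = np.unique(labels, return_inverse=True)
    return codes, None


def _entropy(counts: np.ndarray) -> float:
    counts = counts[counts > 0].astype(float)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def adjusted_rand_index(labels_true, labels_pred) -> float:
    """ARI from the pair-counting contingency formula."""
    C = _contingency(labels_true, labels_pred)
    n = C.sum()
    sum_comb = sum(comb(int(nij), 2) for nij in C.ravel())
    sum_a = sum(comb(int(a), 2) for a in C.sum(axis=1))
    sum_b = sum(comb(int(b), 2) for b in C.sum(axis=0))
    total = comb(int(n), 2)
    expected = sum_a * sum_b / total if total else 0.0
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:  # both partitions trivial
        return 1.0
    return float((sum_comb - expected) / (max_index - expected))


def normalized_mutual_information(labels_true, labels_pred) -> float:
    """NMI with arithmetic-mean normalization: I(T;P) / ((H(T)+H(P))/2)."""
    C = _contingency(labels_true, labels_pred).astype(float)
    n = C.sum()
    h_t = _entropy(C.sum(axis=1))
    h_p = _entropy(C.sum(axis=0))
    nz = C > 0
    outer = np.outer(C.sum(axis=1), C.sum(axis=0))
    mi = float(np.sum(C[nz] / n * np.log(C[nz] * n / outer[nz])))
    denom = 0.5 * (h_t + h_p)
    if denom == 0:
        return 1.0
    return mi / denom


def v_measure(labels_true, labels_pred) -> float:
    """Harmonic mean of homogeneity and completeness."""
    C = _contingency(labels_true, labels_pred).astype(float)
    n = C.sum()
    h_t = _entropy(C.sum(axis=1))
    h_p = _entropy(C.sum(axis=0))
    # conditional entropies from the nonzero cells of the joint table
    rows, cols = np.nonzero(C)
    nij = C[rows, cols]
    row_tot = C.sum(axis=1)[rows]
    col_tot = C.sum(axis=0)[cols]
    h_t_given_p = float(-np.sum(nij / n * np.log(nij / col_tot)))
    h_p_given_t = float(-np.sum(nij / n * np.log(nij / row_tot)))
    homogeneity = 1.0 if h_t == 0 else 1.0 - h_t_given_p / h_t
    completeness = 1.0 if h_p == 0 else 1.0 - h_p_given_t / h_p
    if homogeneity + completeness == 0:
        return 0.0
    return float(2 * homogeneity * completeness / (homogeneity + completeness))


def purity(labels_true, labels_pred) -> float:
    """Fraction of spots in their cluster's majority ground-truth class."""
    C = _contingency(labels_true, labels_pred)
    return float(C.max(axis=0).sum() / C.sum())


def external_metrics(labels_true, labels_pred) -> Dict[str, float]:
    """ARI, NMI, V-measure and Purity against ground-truth labels."""
    return {
        "ARI": adjusted_rand_index(labels_true, labels_pred),
        "NMI": normalized_mutual_information(labels_true, labels_pred),
        "V_measure": v_measure(labels_true, labels_pred),
        "Purity": purity(labels_true, labels_pred),
    }


# ---------------------------------------------------------------------------
# Internal metrics (label-free)
# ---------------------------------------------------------------------------


def internal_metrics(H: np.ndarray, labels_pred) -> Dict[str, float]:
    """Silhouette Coefficient and Davies–Bouldin Index on Euclidean distance."""
    from sklearn.metrics import davies_bouldin_score, silhouette_score

    labels_pred = np.asarray(labels_pred)
    if len(np.unique(labels_pred)) < 2:
        return {"SC": float("nan"), "DBI": float("nan")}
    return {
        "SC": float(silhouette_score(H, labels_pred, metric="euclidean")),
        "DBI": float(davies_bouldin_score(H, labels_pred)),
    }


def evaluate(
    H: np.ndarray,
    n_clusters: int,
    labels_true=None,
    method: str = "kmeans",
    seed: int = 0,
) -> ClusteringReport:
    """Cluster embeddings and score the partition with all applicable metrics."""
    labels_pred = cluster_embeddings(H, n_clusters, method=method, seed=seed)
    metrics = internal_metrics(H, labels_pred)
    if labels_true is not None:
        metrics.update(external_metrics(labels_true, labels_pred))
    return ClusteringReport(
        labels_pred=labels_pred,
        metrics=metrics,
        n_clusters=int(len(np.unique(labels_pred))),
        method=method,
        seed=seed,
    )
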