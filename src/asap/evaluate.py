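"""Clustering of topic proportions and external agreement metrics.

ARI and NMI are delegated to scikit-learn (NMI with the arithmetic-mean
entropy normalization); purity is the fraction of cells belonging to
their cluster's majority type.  Clustering builds a 15-nearest-
neighbour graph on normalized topic proportions and partitions it with
the Leiden algorithm (igraph/leidenalg backend); a seeded k-means
fallback covers environments without that backend.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger("asap")


def _check_pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    a, b = np.asarray(a), np.asarray(b)
    if a.ndim != 1 or b.ndim != 1:
        raise ValueError("labelings must be 1-D")
    if a.size != b.size:
        raise ValueError(f"label length mismatch: {a.size} vs {b.size}")
    if a.size == 0:
        raise ValueError("empty labeling")
    return a, b


def adjusted_rand_index(a, b) -> float:
    """Hubert-Arabie adjusted Rand index; 1 for identical partitions
    (including the trivial single-cluster pair), ~0 for independent
    random partitions."""
    a, b = _check_pair(a, b)
    if len(set(a.tolist())) == 1 and len(set(b.tolist())) == 1:
        return 1.0
    return float(adjusted_rand_score(a, b))


def normalized_mutual_info(a, b) -> float:
    """Mutual information normalized by the arithmetic mean of the two
    label entropies; in [0, 1], 1 iff the partitions agree up to
    relabeling."""
    a, b = _check_pair(a, b)
    if len(set(a.tolist())) == 1 and len(set(b.tolist())) == 1:
        return 1.0
    return float(normalized_mutual_info_score(a, b, average_method="arithmetic"))


def purity(clusters, truth) -> float:
    """Fraction of cells whose cluster's majority type is their own:
    (1/n) sum_clusters max_type |cluster intersect type|."""
    clusters, truth = _check_pair(clusters, truth)
    total = 0
    for c in np.unique(clusters):
        members = truth[clusters == c]
        _, counts = np.unique(members, return_counts=True)
        total += counts.max()
    return float(total) / clusters.size


def _leiden_labels(
    knn_indices: np.ndarray, resolution: float, seed: int
) -> np.ndarray:
    import igraph
    import leidenalg

    n = knn_indices.shape[0]
    edges = {
        (min(i, j), max(i, j))
        for i in range(n)
        for j in knn_indices[i]
        if i != j
    }
    g = igraph.Graph(n=n, edges=sorted(edges))
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    return np.asarray(part.membership)


def cluster_topics(
    proportions: np.ndarray,
    n_neighbors: int = 15,
    method: str = "leiden",
    resolution: float = 1.0,
    seed: int = 0,
    n_clusters: int | None = None,
) -> np.ndarray:
    """Partition samples by community detection on their k-NN graph.

    ``proportions`` is the (n x K) normalized topic matrix (a
    ``TopicProportions.proportions`` array works directly).  With
    ``method='kmeans'`` (or when the Leiden backend is unavailable) a
    seeded k-means on the proportions is used instead; ``n_clusters``
    defaults to K in that case.
    """
    P = np.asarray(proportions, dtype=np.float64)
    if hasattr(proportions, "proportions"):
        P = np.asarray(proportions.proportions, dtype=np.float64)
    n = P.shape[0]
    if n < n_neighbors + 1:
        raise ValueError(f"need more than {n_neighbors} samples, got {n}")
    if method == "leiden":
        try:
            nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(P)
            _, idx = nn.kneighbors(P)
            return _leiden_labels(idx[:, 1:], resolution, seed)
        except ImportError:
            logger.warning("leidenalg backend unavailable; falling back to k-means")
            method = "kmeans"
    if method == "kmeans":
        k = n_clusters if n_clusters is not None else P.shape[1]
        km = KMeans(n_clusters=k, random_state=seed, n_init=10)
        return km.fit_predict(P)
    raise ValueError(f"unknown clustering method {method!r}")
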