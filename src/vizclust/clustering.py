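"""Clustering of 2-D embeddings: k-means with elbow selection, and Leiden
community detection on a kNN graph of the map coordinates.

Clustering operates on the embedding coordinates (the maps being compared),
not on the high-dimensional expression data.
"""

from __future__ import annotations

import logging

import igraph
import leidenalg
import numpy as np
from sklearn.cluster import KMeans

from .types import ClusterResult, Embedding, ValidationError

__all__ = [
    "kmeans_cluster",
    "elbow_select_k",
    "knn_graph",
    "leiden_cluster",
    "leiden_on_embedding",
]

logger = logging.getLogger(__name__)

# Below this ratio of elbow curvature to total WSS drop the k selection is
# considered low-confidence and the boundary default 2 is returned.
ELBOW_MIN_STRENGTH = 0.5


def _coords(emb: Embedding | np.ndarray) -> np.ndarray:
    if isinstance(emb, Embedding):
        return emb.coords
    return np.asarray(emb, dtype=float)


def _sample_ids(emb: Embedding | np.ndarray, n: int) -> list[str]:
    if isinstance(emb, Embedding):
        return emb.sample_ids
    return [f"S{i:04d}" for i in range(n)]


def kmeans_cluster(emb: Embedding | np.ndarray, k: int, seed: int = 0) -> ClusterResult:
    """Lloyd's k-means with 10 seeded restarts (best inertia kept)."""
    X = _coords(emb)
    n = X.shape[0]
    if not 2 <= k < n:
        raise ValidationError(f"k must satisfy 2 <= k < n_samples ({n}), got {k}")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
    # relabel contiguously in order of first appearance for determinism
    labels = _canonical_labels(km.labels_)
    return ClusterResult(
        labels=labels,
        sample_ids=_sample_ids(emb, n),
        method="kmeans",
        params={"k": k, "inertia": float(km.inertia_)},
        seed=seed,
    )


def _canonical_labels(raw: np.ndarray) -> np.ndarray:
    mapping: dict[int, int] = {}
    out = np.empty_like(np.asarray(raw, dtype=int))
    for i, lab in enumerate(raw):
        out[i] = mapping.setdefault(int(lab), len(mapping))
    return out


def _wss_curve(X: np.ndarray, ks: list[int], seed: int) -> np.ndarray:
    return np.array(
        [
            KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X).inertia_
            for k in ks
        ]
    )


def elbow_select_k(
    emb: Embedding | np.ndarray,
    k_min: int = 2,
    k_max: int = 10,
    seed: int = 0,
    return_details: bool = False,
):
    """Pick k by the elbow of the within-cluster sum-of-squares curve.

    Computes WSS(k) for k in [k_min, k_max] and returns the interior k
    maximizing the discrete second difference WSS(k-1) - 2 WSS(k) +
    WSS(k+1); ties go to the smallest k. If the maximal curvature is small
    relative to the total WSS drop (no clear elbow, e.g. a single blob),
    the boundary default ``k_min`` is returned and a low-confidence
    warning is logged.
    """
    X = _coords(emb)
    n = X.shape[0]
    if np.allclose(X, X[0]):
        raise ValidationError("degenerate embedding: all points identical")
    k_max = min(k_max, n - 1)
    if k_max < k_min + 2:
        raise ValidationError("k range too narrow for an interior elbow")
    ks = list(range(k_min, k_max + 1))
    wss = _wss_curve(X, ks, seed)
    second_diff = wss[:-2] - 2.0 * wss[1:-1] + wss[2:]
    best_interior = int(np.argmax(second_diff))  # ties -> smallest k
    strength = float(second_diff[best_interior]) / max(
        float(wss[0] - wss[-1]), 1e-12
    )
    low_confidence = strength < ELBOW_MIN_STRENGTH
    k = k_min if low_confidence else ks[best_interior + 1]
    if low_confidence:
        logger.warning(
            "elbow selection low-confidence (strength %.3f); "
            "returning boundary default k=%d",
            strength,
            k,
        )
    if return_details:
        return k, {
            "ks": ks,
            "wss": wss.tolist(),
            "strength": strength,
            "low_confidence": low_confidence,
        }
    return k


def knn_graph(emb: Embedding | np.ndarray, n_neighbors: int) -> igraph.Graph:
    """Undirected union of directed kNN relations on the map coordinates.

    Euclidean distances; ties broken by sample index (stable sort); edge
    weights are 1.
    """
    X = _coords(emb)
    n = X.shape[0]
    if n_neighbors >= n:
        raise ValidationError(
            f"n_neighbors ({n_neighbors}) must be < n_samples ({n})"
        )
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    order = np.argsort(d2, axis=1, kind="stable")
    edges: set[tuple[int, int]] = set()
    for i in range(n):
        row = order[i][order[i] != i][:n_neighbors]
        for j in row:
            edges.add((min(i, int(j)), max(i, int(j))))
    return igraph.Graph(n=n, edges=sorted(edges))


def leiden_cluster(
    graph: igraph.Graph,
    resolution: float = 1.0,
    seed: int = 0,
    sample_ids: list[str] | None = None,
    extra_params: dict | None = None,
) -> ClusterResult:
    """Leiden community detection (RB modularity) at the given resolution."""
    if graph.vcount() == 0:
        raise ValidationError("empty graph")
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    labels = _canonical_labels(np.asarray(part.membership))
    n = graph.vcount()
    params = {"resolution": resolution}
    if extra_params:
        params |= extra_params
    return ClusterResult(
        labels=labels,
        sample_ids=sample_ids or [f"S{i:04d}" for i in range(n)],
        method="leiden",
        params=params,
        seed=seed,
    )


def leiden_on_embedding(
    emb: Embedding | np.ndarray,
    n_neighbors: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
) -> ClusterResult:
    """kNN graph on the embedding coordinates followed by Leiden."""
    g = knn_graph(emb, n_neighbors)
    n = _coords(emb).shape[0]
    return leiden_cluster(
        g,
        resolution=resolution,
        seed=seed,
        sample_ids=_sample_ids(emb, n),
        extra_params={"n_neighbors": n_neighbors},
    )
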