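"""Unsupervised analysis of the binary term matrix.

Entities are compared by Jaccard (default) or Euclidean distance on their
binary vocabulary profiles, embedded in 2-3 dimensions (PCA by default,
t-SNE/UMAP opt-in), clustered (agglomerative hierarchical on distances, or
k-means on an embedding), and the resulting partition is compared with a
user-supplied grouping variable via the adjusted Rand index (ARI).

The ARI is the pair-counting agreement between two partitions corrected for
chance: with contingency counts ``n_ij``, row sums ``a_i``, column sums
``b_j`` and ``n`` entities,

    ARI = (sum_ij C(n_ij,2) - E) / (max' - E),
    E = sum_i C(a_i,2) * sum_j C(b_j,2) / C(n,2),
    max' = (sum_i C(a_i,2) + sum_j C(b_j,2)) / 2.

It is invariant under label renaming, equals 1 iff the partitions are
identical up to relabeling, and is ~0 for random agreement.  When the
denominator vanishes (both partitions all-singletons or both one-cluster)
the value is defined as 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score

from .data_model import BinaryTermMatrix
from .errors import ValidationError

__all__ = [
    "Embedding",
    "Partition",
    "distance_matrix",
    "reduce_dimensions",
    "linkage_matrix",
    "cluster_hierarchical",
    "cluster_kmeans",
    "adjusted_rand_index",
    "top_terms_per_cluster",
    "suggest_k",
]

METRICS = ("jaccard", "euclidean")
REDUCERS = ("pca", "tsne", "umap")
LINKAGES = ("ward", "average", "complete")


@dataclass
class Embedding:
    """Low-dimensional coordinates of the entities."""

    entity_ids: list[str]
    coordinates: np.ndarray
    method: str
    seed: int = 0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape[0] != len(self.entity_ids):
            raise ValidationError("one coordinate row per entity required")
        if not np.isfinite(self.coordinates).all():
            raise ValidationError("embedding coordinates must be finite")


@dataclass
class Partition:
    """Cluster labels over an ordered entity list."""

    entity_ids: list[str]
    labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.entity_ids) != len(self.labels):
            raise ValidationError("labels and entity_ids must have equal length")

    def relabelled(self) -> np.ndarray:
        """Labels as consecutive integers (first-occurrence order)."""
        mapping: dict = {}
        out = np.empty(len(self.labels), dtype=np.int64)
        for i, lab in enumerate(self.labels):
            out[i] = mapping.setdefault(lab, len(mapping))
        return out


def distance_matrix(matrix: BinaryTermMatrix, metric: str = "jaccard") -> np.ndarray:
    """Symmetric entity-entity distances with a zero diagonal.

    Jaccard distance of two all-zero rows is defined as 0 (two entities with
    no vocabulary are indistinguishable, not maximally distant).
    """
    if metric not in METRICS:
        raise ValidationError(f"metric must be one of {METRICS}, got {metric!r}")
    n = len(matrix.entity_ids)
    if n < 2:
        raise ValidationError("distance matrix needs at least 2 entities")
    x = matrix.values.astype(float)
    return squareform(pdist(x, metric))


def reduce_dimensions(
    matrix: BinaryTermMatrix,
    method: str = "pca",
    d: int = 2,
    seed: int = 0,
    **params,
) -> Embedding:
    """Embed the binary matrix in ``d`` dimensions.

    PCA scores are exact principal-component projections of the centered
    rows (deterministic); t-SNE and UMAP are stochastic but bit-for-bit
    reproducible given ``seed``.  Extra keyword arguments are passed to the
    underlying estimator (e.g. ``perplexity`` for t-SNE, ``n_neighbors`` for
    UMAP).
    """
    if method not in REDUCERS:
        raise ValidationError(f"method must be one of {REDUCERS}, got {method!r}")
    n, n_terms = matrix.shape
    if d > min(n, n_terms):
        raise ValidationError(f"d={d} exceeds min(n_entities, n_terms)={min(n, n_terms)}")
    x = matrix.values.astype(float)
    if method == "pca":
        coords = PCA(n_components=d, svd_solver="full").fit_transform(x)
    elif method == "tsne":
        if n < 3:
            raise ValidationError("t-SNE needs at least 3 entities")
        perplexity = params.pop("perplexity", min(30.0, max(2.0, (n - 1) / 3)))
        if perplexity >= n:
            raise ValidationError(
                f"perplexity ({perplexity}) must be < number of entities ({n}); "
                "lower --perplexity or add entities"
            )
        coords = TSNE(
            n_components=d, perplexity=perplexity, random_state=seed,
            init="pca", **params,
        ).fit_transform(x)
    else:
        if n < 3:
            raise ValidationError("UMAP needs at least 3 entities")
        import umap  # deferred: heavy import

        n_neighbors = params.pop("n_neighbors", min(15, n - 1))
        coords = umap.UMAP(
            n_components=d, n_neighbors=n_neighbors, random_state=seed, **params,
        ).fit_transform(x)
    return Embedding(list(matrix.entity_ids), np.asarray(coords, dtype=float),
                     method=method, seed=seed)


def linkage_matrix(dist: np.ndarray, linkage: str = "ward") -> np.ndarray:
    """Agglomerative merge tree (scipy linkage format) for dendrogram export."""
    if linkage not in LINKAGES:
        raise ValidationError(f"linkage must be one of {LINKAGES}, got {linkage!r}")
    return scipy_linkage(squareform(dist, checks=False), method=linkage)


def cluster_hierarchical(
    dist: np.ndarray,
    entity_ids: list[str],
    linkage: str = "ward",
    k: int = 2,
) -> Partition:
    """Cut the agglomerative tree at ``k`` clusters (deterministic)."""
    n = len(entity_ids)
    if not 1 <= k <= n:
        raise ValidationError(f"k must be in [1, {n}], got {k}")
    z = linkage_matrix(dist, linkage)
    labels = fcluster(z, t=k, criterion="maxclust")
    return Partition(list(entity_ids), labels.tolist())


def cluster_kmeans(embedding: Embedding, k: int, seed: int = 0) -> Partition:
    """K-means on embedding coordinates; multi-start, best inertia kept."""
    n = len(embedding.entity_ids)
    if not 1 <= k <= n:
        raise ValidationError(f"k must be in [1, {n}], got {k}")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(embedding.coordinates)
    return Partition(list(embedding.entity_ids), labels.tolist())


def adjusted_rand_index(p: Partition, q: Partition) -> float:
    """Pair-counting adjusted Rand index between two partitions of the same
    ordered entity list."""
    if p.entity_ids != q.entity_ids:
        raise ValidationError("partitions must cover the same entities in the same order")
    a = p.relabelled()
    b = q.relabelled()
    n = len(a)
    contingency = np.zeros((a.max() + 1 if n else 1, b.max() + 1 if n else 1),
                           dtype=np.int64)
    np.add.at(contingency, (a, b), 1)

    def comb2(x):
        return x * (x - 1) // 2

    sum_ij = int(comb2(contingency).sum())
    sum_a = int(comb2(contingency.sum(axis=1)).sum())
    sum_b = int(comb2(contingency.sum(axis=0)).sum())
    pairs = comb2(n)
    if pairs == 0:
        return 1.0
    # exact rational arithmetic: every quantity is an integer ratio
    expected = Fraction(sum_a * sum_b, pairs)
    maximum = Fraction(sum_a + sum_b, 2)
    if maximum == expected:
        # both all-singletons or both one-cluster
        return 1.0
    return float((sum_ij - expected) / (maximum - expected))


def top_terms_per_cluster(
    matrix: BinaryTermMatrix,
    p: Partition,
    n: int = 10,
) -> dict:
    """Per cluster, terms present in the cluster ranked by within-cluster
    presence count, ties broken lexicographically."""
    if p.entity_ids != matrix.entity_ids:
        raise ValidationError("partition and matrix must cover the same entities in order")
    out = {}
    labels = np.asarray(p.labels, dtype=object)
    for label in sorted(set(p.labels), key=str):
        rows = matrix.values[labels == label]
        sums = rows.sum(axis=0)
        ranked = sorted(
            ((int(s), t) for t, s in zip(matrix.terms, sums) if s > 0),
            key=lambda st: (-st[0], st[1]),
        )
        out[label] = [t for _, t in ranked[:n]]
    return out


def suggest_k(dist: np.ndarray, k_range, linkage: str = "ward") -> int:
    """The k in ``k_range`` maximizing mean silhouette over hierarchical
    cuts; ties go to the smallest k."""
    n = dist.shape[0]
    ks = [k for k in k_range]
    if not ks:
        raise ValidationError("k_range must be non-empty")
    if any(k < 2 or k > n - 1 for k in ks):
        raise ValidationError(f"k_range must lie within [2, {n - 1}]")
    z = linkage_matrix(dist, linkage)
    best_k, best_score = None, -np.inf
    for k in sorted(ks):
        labels = fcluster(z, t=k, criterion="maxclust")
        if len(set(labels)) < 2:
            continue
        score = silhouette_score(dist, labels, metric="precomputed")
        if score > best_score:
            best_k, best_score = k, score
    if best_k is None:
        raise ValidationError("no candidate k produced >= 2 clusters")
    return best_k
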