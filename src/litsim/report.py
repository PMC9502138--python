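"""Static analysis report: the batch replacement for an interactive app.

``analyze`` runs the full downstream pipeline on a binary term matrix —
distances, embedding, clustering, per-cluster characteristic terms, and the
comparison of the text-based grouping with a user-supplied grouping variable
via the adjusted Rand index — and writes a reproducible report directory:

- ``labels.tsv``    entity id, cluster label, grouping label, all-zero flag
- ``embedding.tsv`` entity id + embedding coordinates
- ``ari.txt``       the adjusted Rand index (when a grouping column is given)
- ``cluster_terms.tsv`` per-cluster top terms
- ``scatter.png``   embedding colored by cluster (marker shape by grouping)
- ``dendrogram.png`` merge tree (hierarchical clustering only)

Entities whose matrix row is all zero are kept (dropping them would
desynchronize partitions) but flagged in ``labels.tsv``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd
from scipy.cluster.hierarchy import dendrogram

from . import analysis
from .analysis import Embedding, Partition
from .data_model import BinaryTermMatrix, EntityTable
from .errors import ValidationError

__all__ = ["AnalysisResult", "analyze"]


@dataclass
class AnalysisResult:
    """In-memory counterpart of the report directory."""

    matrix: BinaryTermMatrix
    embedding: Embedding
    partition: Partition
    cluster_terms: dict
    k: int
    ari: float | None = None
    grouping: list[str] | None = None


def _resolve_k(k, meta: EntityTable | None, group_col: str | None,
               dist, n: int) -> int:
    if k != "auto":
        return int(k)
    if meta is not None and group_col:
        labels = meta.grouping_labels(group_col)
        return len(set(labels))
    hi = min(10, n - 1)
    return analysis.suggest_k(dist, range(2, hi + 1))


def analyze(
    matrix: BinaryTermMatrix,
    meta: EntityTable | None = None,
    group_col: str | None = None,
    reduce: str = "pca",
    metric: str = "jaccard",
    cluster: str = "hclust",
    linkage: str = "ward",
    k="auto",
    n_terms: int = 10,
    seed: int = 0,
    outdir=None,
) -> AnalysisResult:
    """Run the downstream analysis; optionally write the report to ``outdir``.

    With ``k='auto'``, k defaults to the number of distinct grouping labels
    when a grouping column is supplied (mirroring validation against
    expert-curated categories), else to the silhouette-best hierarchical cut.
    """
    if cluster not in ("hclust", "kmeans"):
        raise ValidationError(f"cluster must be 'hclust' or 'kmeans', got {cluster!r}")
    grouping = None
    if group_col:
        if meta is None:
            raise ValidationError("a metadata table is required for --group-col")
        if meta.entity_ids != matrix.entity_ids:
            raise ValidationError(
                "metadata and matrix must cover the same entities in the same order"
            )
        grouping = meta.grouping_labels(group_col)

    dist = analysis.distance_matrix(matrix, metric=metric)
    k_val = _resolve_k(k, meta, group_col, dist, len(matrix.entity_ids))
    embedding = analysis.reduce_dimensions(matrix, method=reduce, d=2, seed=seed)
    if cluster == "hclust":
        partition = analysis.cluster_hierarchical(
            dist, matrix.entity_ids, linkage=linkage, k=k_val
        )
    else:
        partition = analysis.cluster_kmeans(embedding, k_val, seed=seed)
    cluster_terms = analysis.top_terms_per_cluster(matrix, partition, n=n_terms)
    ari = None
    if grouping is not None:
        ari = analysis.adjusted_rand_index(
            partition, Partition(matrix.entity_ids, list(grouping))
        )
    result = AnalysisResult(
        matrix=matrix, embedding=embedding, partition=partition,
        cluster_terms=cluster_terms, k=k_val, ari=ari, grouping=grouping,
    )
    if outdir is not None:
        _write_report(result, Path(outdir), dist, metric, linkage, cluster)
    return result


def _write_report(result: AnalysisResult, outdir: Path, dist, metric, linkage,
                  cluster) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    matrix = result.matrix
    zero_row = matrix.values.sum(axis=1) == 0 if matrix.values.size else \
        [True] * len(matrix.entity_ids)

    labels = pd.DataFrame({
        "ID": matrix.entity_ids,
        "CLUSTER": result.partition.labels,
        "ALL_ZERO_ROW": [int(z) for z in zero_row],
    })
    if result.grouping is not None:
        labels.insert(2, "GROUP", result.grouping)
    labels.to_csv(outdir / "labels.tsv", sep="\t", index=False)

    coords = result.embedding.coordinates
    emb = pd.DataFrame({"ID": matrix.entity_ids})
    for j in range(coords.shape[1]):
        emb[f"DIM{j + 1}"] = coords[:, j]
    emb.to_csv(outdir / "embedding.tsv", sep="\t", index=False)

    if result.ari is not None:
        (outdir / "ari.txt").write_text(f"{result.ari:.6f}\n", encoding="utf-8")

    rows = [
        {"CLUSTER": lab, "RANK": i + 1, "TERM": term}
        for lab, terms in result.cluster_terms.items()
        for i, term in enumerate(terms)
    ]
    pd.DataFrame(rows, columns=["CLUSTER", "RANK", "TERM"]).to_csv(
        outdir / "cluster_terms.tsv", sep="\t", index=False
    )

    _scatter_plot(result, outdir / "scatter.png")
    if cluster == "hclust":
        _dendrogram_plot(dist, matrix.entity_ids, linkage, outdir / "dendrogram.png")


def _scatter_plot(result: AnalysisResult, path: Path) -> None:
    coords = result.embedding.coordinates
    fig, ax = plt.subplots(figsize=(6, 5))
    labels = result.partition.labels
    for lab in sorted(set(labels), key=str):
        mask = [l == lab for l in labels]
        ax.scatter(coords[mask, 0], coords[mask, 1], label=f"cluster {lab}", s=30)
    ax.set_xlabel("dim 1")
    ax.set_ylabel("dim 2")
    ax.set_title(f"{result.embedding.method} embedding, k={result.k}")
    ax.legend(fontsize=7, loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _dendrogram_plot(dist, entity_ids, linkage, path: Path) -> None:
    z = analysis.linkage_matrix(dist, linkage)
    fig, ax = plt.subplots(figsize=(max(6, len(entity_ids) * 0.2), 4))
    dendrogram(z, labels=entity_ids, ax=ax, leaf_font_size=6)
    ax.set_ylabel("merge distance")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
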