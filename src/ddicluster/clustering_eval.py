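"""Partitioning drugs from a similarity matrix and evaluating partitions.

Spectral clustering follows the Ng-Jordan-Weiss recipe: embed into the k
eigenvectors of the normalized symmetric Laplacian
I - D^(-1/2) S D^(-1/2) with smallest eigenvalues, scale rows to unit
norm, then run seeded k-means with multiple restarts.  Hierarchical
clustering is agglomerative on the distance 1 - s.

Partitions of a signed DDI network are scored by *edge purity*: restrict
to the classes of interest (default synergy + antagonism), count edges per
cluster-pair block, and report the edge-weighted fraction falling in their
block's majority class.  Purity 1 means a perfectly monochromatic
partition.  Partitions are compared to each other with the adjusted Rand
index and normalized mutual information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.metrics import (
    adjusted_rand_score,
    normalized_mutual_info_score,
    silhouette_score,
)

from .core import Clustering, INTERACTION_CLASSES, SignedDDINetwork, SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "BlockSignProfile",
    "EdgePurityResult",
    "spectral_clustering",
    "hierarchical_clustering",
    "select_k",
    "edge_purity",
    "block_sign_profile",
    "compare_clusterings",
]

DEFAULT_PURITY_CLASSES = frozenset({"synergy", "antagonism"})


@dataclass(frozen=True)
class BlockSignProfile:
    """Per-class edge counts for every cluster-label pair (g, h), g <= h.

    ``majority`` maps each block to the class with the largest count, or
    "tied" when the maximum is shared.
    """

    counts: dict  # (g, h) -> {class: count}
    majority: dict  # (g, h) -> class | "tied"

    def table(self) -> pd.DataFrame:
        """Per-block counts as a tidy table (one row per block)."""
        rows = []
        for (g, h), cnt in sorted(self.counts.items()):
            row = {"cluster_a": g, "cluster_b": h, "majority": self.majority[(g, h)]}
            row.update({cls: cnt.get(cls, 0) for cls in INTERACTION_CLASSES})
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class EdgePurityResult:
    purity: float
    counted_edges: int
    classes_used: frozenset
    profile: BlockSignProfile


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def _check_similarity(similarity: SimilarityMatrix, k: int) -> None:
    n = similarity.n
    if not 2 <= k <= n:
        raise ValueError(f"k={k} out of range [2, {n}]")


def spectral_embedding(similarity: SimilarityMatrix, k: int) -> np.ndarray:
    """Rows of the k smallest eigenvectors of the normalized Laplacian,
    scaled to unit norm."""
    S = similarity.values.copy()
    off = S - np.diag(np.diag(S))
    degree = S.sum(axis=1)
    if np.any(off.sum(axis=1) <= 0):
        isolated = [similarity.ids[i] for i in np.flatnonzero(off.sum(axis=1) <= 0)]
        raise ValueError(
            f"drug(s) {isolated} have zero similarity to all others; "
            "prune isolated drugs before spectral clustering"
        )
    d_inv_sqrt = 1.0 / np.sqrt(degree)
    M = d_inv_sqrt[:, None] * S * d_inv_sqrt[None, :]
    # k smallest eigenvalues of I - M == k largest of M.
    n = similarity.n
    _, vecs = scipy.linalg.eigh(M, subset_by_index=(n - k, n - 1))
    norms = np.linalg.norm(vecs, axis=1)
    norms[norms < 1e-12] = 1.0
    return vecs / norms[:, None]


def laplacian_eigenvalues(similarity: SimilarityMatrix) -> np.ndarray:
    """Ascending eigenvalues of the normalized symmetric Laplacian."""
    S = similarity.values
    degree = S.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(degree)
    L = np.eye(similarity.n) - d_inv_sqrt[:, None] * S * d_inv_sqrt[None, :]
    return scipy.linalg.eigvalsh(L)


def _repair_empty(labels: np.ndarray, embedding: np.ndarray, k: int) -> np.ndarray:
    """Split the largest cluster at its farthest point until k clusters exist."""
    labels = labels.copy()
    while len(np.unique(labels)) < k:
        sizes = {lab: int((labels == lab).sum()) for lab in np.unique(labels)}
        big = max(sizes, key=lambda l: (sizes[l], -l))
        members = np.flatnonzero(labels == big)
        center = embedding[members].mean(axis=0)
        far = members[np.argmax(np.linalg.norm(embedding[members] - center, axis=1))]
        new_label = max(np.unique(labels)) + 1
        labels[far] = new_label
        logger.warning("repaired empty cluster by splitting cluster %s at point %s", big, far)
    return labels


def spectral_clustering(similarity: SimilarityMatrix, k: int, seed: int = 0) -> Clustering:
    """Ng-Jordan-Weiss spectral clustering into exactly k clusters.

    Deterministic for fixed inputs and seed (k-means uses >= 20 restarts).
    """
    _check_similarity(similarity, k)
    embedding = spectral_embedding(similarity, k)
    km = KMeans(n_clusters=k, n_init=20, random_state=int(seed) % (2**31))
    labels = km.fit_predict(embedding)
    labels = _repair_empty(labels, embedding, k)
    return Clustering.from_labels(similarity.ids, labels)


def hierarchical_clustering(
    similarity: SimilarityMatrix, k: int, linkage: str = "average"
) -> Clustering:
    """Agglomerative clustering on distance 1 - s, cut to exactly k clusters.

    Unlike the spectral path, k = 1 is allowed (the forced single cluster).
    """
    if not 1 <= k <= similarity.n:
        raise ValueError(f"k={k} out of range [1, {similarity.n}]")
    if linkage not in ("average", "complete", "single"):
        raise ValueError(f"unknown linkage {linkage!r}")
    D = 1.0 - similarity.values
    np.fill_diagonal(D, 0.0)
    model = AgglomerativeClustering(n_clusters=k, metric="precomputed", linkage=linkage)
    labels = model.fit_predict(D)
    return Clustering.from_labels(similarity.ids, labels)


def select_k(
    similarity: SimilarityMatrix,
    k_min: int = 2,
    k_max: Optional[int] = None,
    seed: int = 0,
) -> tuple:
    """Scan candidate cluster counts and pick the best by mean silhouette.

    Returns ``(k_best, diagnostics)`` where diagnostics is a DataFrame with
    one row per k holding the silhouette (on distance 1 - s, spectral
    labels) and the Laplacian eigengap (eigenvalue k+1 minus eigenvalue k,
    reported as secondary evidence).  Ties go to the smallest k.
    """
    n = similarity.n
    if k_max is None:
        k_max = n - 1
    if not 2 <= k_min <= k_max <= n - 1:
        raise ValueError(f"invalid k range [{k_min}, {k_max}] for n={n}")
    eigvals = laplacian_eigenvalues(similarity)
    D = 1.0 - similarity.values
    np.fill_diagonal(D, 0.0)
    rows = []
    for k in range(k_min, k_max + 1):
        labels = spectral_clustering(similarity, k, seed=seed).labels_for(similarity.ids)
        sil = float(silhouette_score(D, labels, metric="precomputed"))
        gap = float(eigvals[k] - eigvals[k - 1]) if k < n else np.nan
        rows.append({"k": k, "silhouette": sil, "eigengap": gap})
    diag = pd.DataFrame(rows)
    best = diag["silhouette"].max()
    if np.ptp(diag["silhouette"]) < 1e-12:
        logger.warning("silhouette is flat across k; no cluster count is preferred")
    k_best = int(diag.loc[diag["silhouette"] >= best - 1e-12, "k"].min())
    return k_best, diag


# ---------------------------------------------------------------------------
# Evaluation on the signed network
# ---------------------------------------------------------------------------

def block_sign_profile(
    network: SignedDDINetwork,
    clustering: Clustering,
    classes: frozenset = frozenset(INTERACTION_CLASSES),
) -> BlockSignProfile:
    """Count edges per cluster-pair block, restricted to ``classes``."""
    counts: dict = {}
    for (a, b), (cls, _) in network.edges.items():
        if cls not in classes:
            continue
        if a not in clustering.assignment or b not in clustering.assignment:
            missing = [x for x in (a, b) if x not in clustering.assignment]
            raise ValueError(f"clustering does not cover edge endpoint(s) {missing}")
        g, h = sorted((clustering.label_of(a), clustering.label_of(b)))
        block = counts.setdefault((g, h), {})
        block[cls] = block.get(cls, 0) + 1
    majority = {}
    for block, cnt in counts.items():
        top = max(cnt.values())
        winners = [cls for cls, c in cnt.items() if c == top]
        majority[block] = winners[0] if len(winners) == 1 else "tied"
    return BlockSignProfile(counts=counts, majority=majority)


def edge_purity(
    network: SignedDDINetwork,
    clustering: Clustering,
    classes=DEFAULT_PURITY_CLASSES,
    average: str = "micro",
) -> EdgePurityResult:
    """Edge purity of a partition on a signed DDI network.

    For each cluster-pair block (including within-cluster blocks) take the
    largest single-class edge count; purity is the edge-weighted
    micro-average sum(c_max) / sum(total).  ``average="macro"`` instead
    averages per-block purities with equal block weight.  Additive edges
    are excluded by default; pass ``classes`` to change that.
    """
    classes = frozenset(classes)
    if not classes:
        raise ValueError("classes must be non-empty")
    unknown = classes - set(INTERACTION_CLASSES)
    if unknown:
        raise ValueError(f"unknown classes {sorted(unknown)}")
    uncovered = [n for n in {x for p in network.edges for x in p}
                 if n not in clustering.assignment]
    if uncovered:
        raise ValueError(f"clustering does not cover endpoint(s) {sorted(uncovered)}")
    if average not in ("micro", "macro"):
        raise ValueError(f"unknown average {average!r}")
    profile = block_sign_profile(network, clustering, classes)
    totals = {blk: sum(cnt.values()) for blk, cnt in profile.counts.items()}
    maxima = {blk: max(cnt.values()) for blk, cnt in profile.counts.items()}
    counted = sum(totals.values())
    if counted == 0:
        raise ValueError(
            f"no edges with class in {sorted(classes)}; edge purity is undefined"
        )
    if average == "micro":
        purity = sum(maxima.values()) / counted
    else:
        purity = float(np.mean([maxima[b] / totals[b] for b in totals]))
    return EdgePurityResult(
        purity=float(purity),
        counted_edges=counted,
        classes_used=classes,
        profile=profile,
    )


def compare_clusterings(a: Clustering, b: Clustering) -> tuple:
    """Adjusted Rand index, normalized mutual information, and the
    contingency table of two partitions over the same id set."""
    if set(a.assignment) != set(b.assignment):
        diff = sorted(set(a.assignment) ^ set(b.assignment))
        raise ValueError(f"clusterings cover different ids; symmetric difference {diff}")
    ids = sorted(a.assignment)
    la, lb = a.labels_for(ids), b.labels_for(ids)
    ari = float(adjusted_rand_score(la, lb))
    nmi = float(normalized_mutual_info_score(la, lb))
    table = pd.crosstab(
        pd.Series(la, name="a"), pd.Series(lb, name="b")
    )
    return ari, nmi, table
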