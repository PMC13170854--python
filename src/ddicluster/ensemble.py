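"""Clustering-ensemble strategies: evidence accumulation and matrix fusion.

Evidence accumulation averages the same-cluster indicator over a set of
partitions into a *co-association matrix* and re-clusters it (default:
average-linkage agglomerative on 1 - C).  Similarity matrix fusion
combines several drug-similarity matrices into one consensus matrix
before clustering — element-wise mean (default), a weighted average, or
an SNF-style iterative cross-diffusion with K-nearest-neighbor locality.

The leave-one-source-out ablation quantifies how much each information
source contributes to edge purity of the fused clustering.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .clustering_eval import edge_purity, hierarchical_clustering, spectral_clustering
from .core import Clustering, SignedDDINetwork, SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CoAssociationMatrix",
    "co_association",
    "consensus_from_coassociation",
    "fuse_similarities",
    "ablation_study",
]


class CoAssociationMatrix(SimilarityMatrix):
    """Co-association matrix: entry (i, j) is the fraction of input
    partitions that place i and j in the same cluster.  Entries lie on the
    grid {0, 1/m, ..., 1} for m partitions."""

    def __init__(self, ids, values, m: int):
        super().__init__(ids, values, kind="coassociation")
        self.m = int(m)


def co_association(partitions: Sequence[Clustering]) -> CoAssociationMatrix:
    """Build the co-association matrix of >= 1 partitions over one id set."""
    if not partitions:
        raise ValueError("need at least one partition")
    id_set = set(partitions[0].assignment)
    for p in partitions[1:]:
        if set(p.assignment) != id_set:
            diff = sorted(set(p.assignment) ^ id_set)
            raise ValueError(f"partitions cover different ids; symmetric difference {diff}")
    ids = sorted(id_set)
    m = len(partitions)
    acc = np.zeros((len(ids), len(ids)))
    for p in partitions:
        labels = p.labels_for(ids)
        acc += (labels[:, None] == labels[None, :]).astype(float)
    return CoAssociationMatrix(ids, acc / m, m=m)


def consensus_from_coassociation(
    c: CoAssociationMatrix,
    k: int,
    method: str = "hierarchical-average",
    seed: int = 0,
) -> Clustering:
    """Extract a consensus partition from a co-association matrix.

    Default is classic evidence-accumulation practice: average-linkage
    agglomerative clustering on 1 - C cut at k.  The spectral option
    reuses the Ng-Jordan-Weiss pipeline on C.
    """
    if method == "hierarchical-average":
        return hierarchical_clustering(c, k, linkage="average")
    if method == "spectral":
        return spectral_clustering(c, k, seed=seed)
    raise ValueError(f"unknown consensus method {method!r}")


def _minmax_offdiag(values: np.ndarray) -> np.ndarray:
    """Min-max rescale off-diagonal entries to [0, 1]; constant -> 0."""
    out = values.copy()
    mask = ~np.eye(len(values), dtype=bool)
    lo, hi = out[mask].min(), out[mask].max()
    if hi - lo < 1e-15:
        out[mask] = 0.0
    else:
        out[mask] = (out[mask] - lo) / (hi - lo)
    np.fill_diagonal(out, 1.0)
    return out


def _snf_diffusion(
    stack: np.ndarray, n_neighbors: int, n_iter: int
) -> np.ndarray:
    """SNF-style cross-diffusion of v similarity matrices (v x n x n).

    Each view diffuses the average of the other views' global kernels
    through its own K-nearest-neighbor local kernel; symmetry is restored
    after every step.
    """
    v, n, _ = stack.shape
    eye = np.eye(n)

    def global_kernel(W):
        off = W * (1 - eye)
        rows = off.sum(axis=1, keepdims=True)
        rows[rows == 0] = 1.0
        return off / (2 * rows) + eye / 2.0

    def local_kernel(W):
        S = np.zeros_like(W)
        off = W * (1 - eye)
        for i in range(n):
            nn = np.argsort(off[i])[::-1][:n_neighbors]
            S[i, nn] = off[i, nn]
        rows = S.sum(axis=1, keepdims=True)
        rows[rows == 0] = 1.0
        return S / rows

    P = [global_kernel(stack[i]) for i in range(v)]
    S = [local_kernel(stack[i]) for i in range(v)]
    for _ in range(n_iter):
        new = []
        for i in range(v):
            others = [P[j] for j in range(v) if j != i] or [P[i]]
            avg = np.mean(others, axis=0)
            Pi = S[i] @ avg @ S[i].T
            new.append((Pi + Pi.T) / 2.0)
        P = new
    fused = np.mean(P, axis=0)
    fused = (fused + fused.T) / 2.0
    return _minmax_offdiag(fused)


def fuse_similarities(
    matrices: Sequence[SimilarityMatrix],
    method: str = "mean",
    weights: Optional[Sequence[float]] = None,
    normalize: bool = False,
    n_neighbors: int = 5,
    n_iter: int = 20,
) -> SimilarityMatrix:
    """Fuse >= 2 similarity matrices (identical id ordering) into one.

    ``mean``: element-wise average.  ``weighted``: weighted average with
    non-negative weights summing to 1.  ``diffusion``: SNF-style iterative
    cross-diffusion, rescaled to [0, 1] with unit diagonal.  With
    ``normalize=True`` each matrix's off-diagonal is min-max rescaled
    first.
    """
    if len(matrices) < 2:
        raise ValueError("need at least two matrices to fuse")
    ids = matrices[0].ids
    for m in matrices[1:]:
        if m.ids != ids:
            raise ValueError("matrices have mismatched id orderings")
    stack = np.stack([m.values for m in matrices])
    if normalize:
        stack = np.stack([_minmax_offdiag(v) for v in stack])
    if method == "mean":
        fused = stack.mean(axis=0)
    elif method == "weighted":
        if weights is None:
            raise ValueError("weighted fusion requires weights")
        w = np.asarray(weights, dtype=float)
        if len(w) != len(matrices) or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")
        fused = np.tensordot(w, stack, axes=1)
    elif method == "diffusion":
        k_eff = min(n_neighbors, len(ids) - 1)
        fused = _snf_diffusion(stack, n_neighbors=k_eff, n_iter=n_iter)
    else:
        raise ValueError(f"unknown fusion method {method!r}")
    np.fill_diagonal(fused, 1.0)
    return SimilarityMatrix(ids, fused, kind="fused")


def ablation_study(
    sources: dict,
    network: SignedDDINetwork,
    k: int,
    seed: int = 0,
    fuse_method: str = "mean",
    purity_classes=("synergy", "antagonism"),
) -> pd.DataFrame:
    """Leave-one-source-out ablation of fused clustering quality.

    For each named source, fuse the remaining matrices, cluster at k
    (spectral) and evaluate edge purity on the network; the all-sources
    baseline is reported in the row ``left_out="none"``.
    """
    if len(sources) < 3:
        raise ValueError("ablation needs at least 3 sources (leave-one-out degenerates)")
    names = list(sources)
    rows = []

    def run(mats):
        fused = fuse_similarities(mats, method=fuse_method) if len(mats) > 1 else mats[0]
        clustering = spectral_clustering(fused, k, seed=seed)
        res = edge_purity(network, clustering, classes=purity_classes)
        return res.purity, res.counted_edges

    purity, counted = run([sources[n] for n in names])
    rows.append({"left_out": "none", "edge_purity": purity, "counted_edges": counted})
    for name in names:
        rest = [sources[n] for n in names if n != name]
        purity, counted = run(rest)
        rows.append({"left_out": name, "edge_purity": purity, "counted_edges": counted})
    return pd.DataFrame(rows)
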