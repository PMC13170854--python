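"""Drug similarity computed from the signed DDI network itself.

Each drug gets a *signed interaction profile*: a vector over the node
list holding +1 for a synergy edge, -1 for an antagonism edge, a
configurable weight for an additive edge (default 0, "no evidence"), and
0 for no edge.  Two drugs are similar when they interact with the same
partners in the same way, so the default measure is the cosine of the two
profiles — with the coordinates of the pair itself removed, so the direct
u-v edge does not inflate shared context — mapped to [0, 1].  An unsigned
Jaccard variant on neighbor sets ignores the signs.

Association between similarity matrices is measured on their strict upper
triangles (Spearman by default) with a Mantel-style permutation test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.stats

from .core import SignedDDINetwork, SimilarityMatrix
from .ensemble import fuse_similarities

logger = logging.getLogger(__name__)

__all__ = [
    "SignedProfile",
    "signed_profiles",
    "network_based_similarity",
    "matrix_correlation",
    "multi_network_similarity",
]

_SIGN = {"synergy": 1.0, "antagonism": -1.0}


@dataclass(frozen=True)
class SignedProfile:
    """One drug's signed interaction vector over the ordered node list."""

    id: str
    vector: np.ndarray


def signed_profiles(
    network: SignedDDINetwork, additive_weight: float = 0.0
) -> list:
    """Signed interaction profile for every node of the network."""
    if network.n == 0:
        raise ValueError("network is empty")
    if not -1.0 <= additive_weight <= 1.0:
        raise ValueError("additive_weight must lie in [-1, 1]")
    index = {node: i for i, node in enumerate(network.node_ids)}
    mat = np.zeros((network.n, network.n))
    for (a, b), (cls, _) in network.edges.items():
        w = _SIGN.get(cls, additive_weight)
        i, j = index[a], index[b]
        mat[i, j] = mat[j, i] = w
    return [SignedProfile(id=node, vector=mat[i].copy())
            for node, i in index.items()]


def network_based_similarity(
    network: SignedDDINetwork,
    additive_weight: float = 0.0,
    mode: str = "signed-cosine",
) -> SimilarityMatrix:
    """Drug x drug similarity from DDI information.

    ``signed-cosine`` (default): for a pair (u, v) drop coordinates u and
    v from both signed profiles and return (1 + cosine)/2; if either
    truncated profile has zero norm the pair scores 0 (warning logged).
    ``unsigned-jaccard``: |N(u) ∩ N(v)| / |N(u) ∪ N(v)| over neighbor sets
    ignoring signs (0 when the union is empty).
    """
    if network.n == 0:
        raise ValueError("network is empty")
    ids = network.node_ids
    n = network.n
    values = np.eye(n)
    if mode == "signed-cosine":
        profiles = {p.id: p.vector for p in signed_profiles(network, additive_weight)}
        warned = set()
        for i in range(n):
            for j in range(i + 1, n):
                keep = np.ones(n, dtype=bool)
                keep[[i, j]] = False
                x = profiles[ids[i]][keep]
                y = profiles[ids[j]][keep]
                nx_, ny_ = np.linalg.norm(x), np.linalg.norm(y)
                if nx_ < 1e-12 or ny_ < 1e-12:
                    for idx, nrm in ((i, nx_), (j, ny_)):
                        if nrm < 1e-12 and ids[idx] not in warned:
                            warned.add(ids[idx])
                            logger.warning(
                                "drug %s has an empty shared-context profile; "
                                "its pairs score 0", ids[idx],
                            )
                    values[i, j] = values[j, i] = 0.0
                else:
                    cos = float(x @ y / (nx_ * ny_))
                    values[i, j] = values[j, i] = np.clip((1.0 + cos) / 2.0, 0.0, 1.0)
    elif mode == "unsigned-jaccard":
        neigh = {node: network.neighbors(node) for node in ids}
        for i in range(n):
            for j in range(i + 1, n):
                a = neigh[ids[i]] - {ids[j]}
                b = neigh[ids[j]] - {ids[i]}
                union = a | b
                values[i, j] = values[j, i] = (len(a & b) / len(union)) if union else 0.0
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return SimilarityMatrix(ids, values, kind="network")


def matrix_correlation(
    a: SimilarityMatrix,
    b: SimilarityMatrix,
    method: str = "spearman",
    n_perm: int = 999,
    seed: int = 0,
) -> tuple:
    """Correlation of two similarity matrices over their strict upper
    triangles, with a Mantel permutation p-value.

    b is reordered internally to a's id ordering.  The permutation null
    jointly permutes b's rows and columns ``n_perm`` times;
    p = (1 + #{|r_perm| >= |r_obs|}) / (1 + n_perm).  ``n_perm=0`` skips
    the test and returns ``(coefficient, None)``.
    """
    if set(a.ids) != set(b.ids):
        diff = sorted(set(a.ids) ^ set(b.ids))
        raise ValueError(f"matrices cover different ids; symmetric difference {diff}")
    if a.n < 4:
        raise ValueError("need at least 4 drugs for a matrix correlation")
    if n_perm != 0 and n_perm < 99:
        raise ValueError("n_perm must be 0 (no test) or >= 99")
    b = b.reorder(a.ids)
    iu = np.triu_indices(a.n, k=1)
    x = a.values[iu]
    y = b.values[iu]
    if np.ptp(x) < 1e-15 or np.ptp(y) < 1e-15:
        raise ValueError("constant upper triangle; correlation undefined")

    if method == "spearman":
        def corr(u, v):
            return float(np.corrcoef(scipy.stats.rankdata(u), scipy.stats.rankdata(v))[0, 1])
    elif method == "pearson":
        def corr(u, v):
            return float(np.corrcoef(u, v)[0, 1])
    else:
        raise ValueError(f"unknown method {method!r}")

    r_obs = corr(x, y)
    if n_perm == 0:
        return r_obs, None
    rng = np.random.default_rng(seed)
    bvals = b.values
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(a.n)
        y_perm = bvals[np.ix_(perm, perm)][iu]
        if np.ptp(y_perm) < 1e-15:
            continue
        if abs(corr(x, y_perm)) >= abs(r_obs) - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return r_obs, float(p)


def multi_network_similarity(
    networks: dict,
    fuse_method: str = "mean",
    additive_weight: float = 0.0,
    mode: str = "signed-cosine",
) -> SimilarityMatrix:
    """Network-based similarity fused across several strains' DDI networks.

    The networks are restricted to their common drug subset (logged), a
    per-network similarity is computed, and the matrices are fused with
    :func:`ddicluster.ensemble.fuse_similarities`.
    """
    if len(networks) < 2:
        raise ValueError("need at least two networks")
    common = set.intersection(*(set(nw.node_ids) for nw in networks.values()))
    if len(common) < 4:
        raise ValueError(f"common drug subset too small ({len(common)} < 4)")
    ids = sorted(common)
    logger.info("multi-network similarity on %d common drugs", len(ids))
    mats = [
        network_based_similarity(nw.subnetwork(ids), additive_weight, mode)
        for nw in networks.values()
    ]
    fused = fuse_similarities(mats, method=fuse_method)
    return SimilarityMatrix(fused.ids, fused.values, kind="network")
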