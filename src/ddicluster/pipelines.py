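"""End-to-end analysis workflows composed from the library modules.

These are the standard experiment shapes on a synthetic study: cluster
each drug-information view, integrate views (mean fusion by default),
and the hold-out exercise where a few drugs are withheld from
clustering, assigned afterwards, and their interaction classes predicted
from cluster-pair sign profiles.
"""

from __future__ import annotations

from typing import Optional, Sequence

from .clustering_eval import block_sign_profile, spectral_clustering
from .core import Clustering
from .ddi_prediction import evaluate_predictions, predict_new_drug_interactions
from .drug_similarity import compute_all_similarities
from .ensemble import fuse_similarities
from .synthetic_data import SyntheticConfig, SyntheticStudy, generate_study

__all__ = ["multi_view_clustering", "holdout_experiment"]


def multi_view_clustering(
    study: SyntheticStudy,
    k: Optional[int] = None,
    seed: int = 0,
    fuse_method: str = "mean",
) -> tuple:
    """Cluster each feature view and the fused consensus.

    Returns ``(per_view, fused)`` where per_view maps view name to its
    spectral clustering and fused is the clustering of the mean-fused
    matrix (all at k = the study's planted cluster count by default).
    """
    if k is None:
        k = study.truth.k
    sims = compute_all_similarities(study.records)
    per_view = {name: spectral_clustering(m, k, seed=seed) for name, m in sims.items()}
    fused_matrix = fuse_similarities(list(sims.values()), method=fuse_method)
    fused = spectral_clustering(fused_matrix, k, seed=seed)
    return per_view, fused


def holdout_experiment(
    config: SyntheticConfig,
    n_holdout: int = 3,
    seed: Optional[int] = None,
):
    """Hold out one drug from each of ``n_holdout`` clusters, cluster the
    rest from fused similarity, assign the held-out drugs and predict
    their interactions with every clustered drug.

    The study is generated with ``n_holdout`` clusters enlarged by one
    drug so the clustered panel keeps the configured geometry.  Returns
    the :class:`~ddicluster.ddi_prediction.PredictionReport` against the
    study's generated edges.
    """
    if seed is None:
        seed = config.seed
    sizes = tuple(s + 1 if i < n_holdout else s for i, s in enumerate(config.sizes))
    study = generate_study(config.with_(sizes=sizes))
    held = [study.truth.clusters()[g][0] for g in range(1, n_holdout + 1)]
    kept = sorted(i for i in study.truth.assignment if i not in held)

    sims = compute_all_similarities(study.records)
    fused_all = fuse_similarities(list(sims.values()))
    clustering = spectral_clustering(fused_all.reorder(kept), config.k, seed=seed)
    profile = block_sign_profile(study.network.subnetwork(kept), clustering)
    _, predictions = predict_new_drug_interactions(fused_all, clustering, profile, held)
    truth_edges = {
        pair: cls
        for pair, (cls, _) in study.network.edges.items()
        if (pair[0] in held) ^ (pair[1] in held)
    }
    return evaluate_predictions(predictions, truth_edges)
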