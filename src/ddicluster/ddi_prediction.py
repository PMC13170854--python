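"""Predicting interaction classes for new drugs from a clustered network.

A new (unclustered) drug is assigned to the cluster whose members it is
most similar to on average.  The interaction class of a drug pair is then
predicted as the majority class of their cluster-pair block in the
training network's sign profile; empty or tied blocks yield "abstain"
rather than a guess.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .clustering_eval import BlockSignProfile
from .core import Clustering, SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PredictionReport",
    "assign_new_drug",
    "predict_interaction",
    "evaluate_predictions",
    "predict_new_drug_interactions",
]

ABSTAIN = "abstain"


@dataclass(frozen=True)
class PredictionReport:
    predictions: dict  # pair -> class | "abstain"
    truth: Optional[dict]
    accuracy: float
    evaluable: int
    coverage: float  # fraction of predicted pairs with a non-abstain call
    per_class: pd.DataFrame

    def table(self) -> pd.DataFrame:
        rows = []
        for pair, pred in sorted(self.predictions.items()):
            obs = self.truth.get(pair) if self.truth else None
            rows.append({
                "drug_a": pair[0], "drug_b": pair[1], "predicted": pred,
                "observed": obs if obs is not None else "",
                "correct": "" if pred == ABSTAIN or obs is None else pred == obs,
            })
        return pd.DataFrame(rows)


def _norm_pair(a, b):
    if a == b:
        raise ValueError(f"self-pair {a!r}")
    return (a, b) if a < b else (b, a)


def assign_new_drug(similarity_row: Mapping[str, float], clustering: Clustering) -> int:
    """Cluster label maximizing mean similarity to the cluster's members.

    ``similarity_row`` maps every clustered drug id to a similarity in
    [0, 1].  Ties go to the smallest label with a warning.
    """
    missing = [i for i in clustering.assignment if i not in similarity_row]
    if missing:
        raise ValueError(f"similarity row missing clustered id(s) {sorted(missing)}")
    means = {}
    for label, members in clustering.clusters().items():
        means[label] = float(np.mean([similarity_row[m] for m in members]))
    best = max(means.values())
    winners = sorted(l for l, v in means.items() if v >= best - 1e-12)
    if len(winners) > 1:
        logger.warning("tied cluster assignment among %s; choosing %s", winners, winners[0])
    return winners[0]


def predict_interaction(u_label: int, v_label: int, profile: BlockSignProfile) -> str:
    """Majority class of block (min(u,v), max(u,v)); absent or tied
    blocks abstain."""
    block = (min(u_label, v_label), max(u_label, v_label))
    majority = profile.majority.get(block)
    if majority is None or majority == "tied":
        return ABSTAIN
    return majority


def evaluate_predictions(
    predictions: Mapping[tuple, str], truth: Mapping[tuple, str]
) -> PredictionReport:
    """Accuracy over pairs with both a non-abstain prediction and a truth
    class; abstentions and coverage reported separately."""
    predictions = {_norm_pair(*p): c for p, c in predictions.items()}
    truth = {_norm_pair(*p): c for p, c in truth.items()}
    evaluable = [p for p, c in predictions.items() if c != ABSTAIN and p in truth]
    if not evaluable:
        raise ValueError("no evaluable pairs (all abstained or no overlapping truth)")
    correct = sum(predictions[p] == truth[p] for p in evaluable)
    rows = []
    classes = sorted({predictions[p] for p in evaluable} | {truth[p] for p in evaluable})
    for cls in classes:
        pred_n = sum(predictions[p] == cls for p in evaluable)
        true_n = sum(truth[p] == cls for p in evaluable)
        hit_n = sum(predictions[p] == cls and truth[p] == cls for p in evaluable)
        rows.append({"class": cls, "predicted": pred_n, "observed": true_n, "correct": hit_n})
    non_abstain = sum(c != ABSTAIN for c in predictions.values())
    return PredictionReport(
        predictions=dict(predictions),
        truth=dict(truth),
        accuracy=correct / len(evaluable),
        evaluable=len(evaluable),
        coverage=non_abstain / len(predictions) if predictions else 0.0,
        per_class=pd.DataFrame(rows),
    )


def predict_new_drug_interactions(
    similarity: SimilarityMatrix,
    clustering: Clustering,
    profile: BlockSignProfile,
    new_ids: Sequence[str],
) -> tuple:
    """Assign each new drug to a cluster and predict its interactions with
    every clustered drug.

    ``similarity`` must cover clustered and new drugs.  Returns
    ``(assignments, predictions)`` with predictions keyed by normalized
    pair.
    """
    clustered = list(clustering.assignment)
    assignments = {}
    for nid in new_ids:
        if nid in clustering.assignment:
            raise ValueError(f"{nid!r} is already clustered")
        row = {cid: similarity.pair(nid, cid) for cid in clustered}
        assignments[nid] = assign_new_drug(row, clustering)
    predictions = {}
    for nid, label in assignments.items():
        for cid in clustered:
            predictions[_norm_pair(nid, cid)] = predict_interaction(
                label, clustering.label_of(cid), profile
            )
    return assignments, predictions
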