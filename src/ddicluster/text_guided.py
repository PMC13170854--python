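"""Text-guided clustering support: prompt construction, response parsing,
and scoring against algorithmic partitions.

This module never calls a model.  It renders deterministic clustering
prompts from data tables or edge lists, parses the "Python dictionary
format" clustering responses that such prompts request (tolerating code
fences, single quotes, trailing commas and case drift in drug ids), and
scores a parsed partition with the same edge-purity / ARI / NMI metrics
used for algorithmic clusterings.
"""

from __future__ import annotations

import ast
import logging
import re
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .clustering_eval import compare_clusterings, edge_purity
from .core import Clustering, DrugRecord, SignedDDINetwork

logger = logging.getLogger(__name__)

__all__ = [
    "PromptSpec",
    "build_prompt",
    "parse_clustering_response",
    "format_clustering_response",
    "score_response",
    "comparison_table",
]

TASKS = ("single-feature", "multi-feature", "ddi-network")

_OUTPUT_CLAUSE = "Output in abbreviated and Python dictionary format."

_FEATURE_COLUMNS = {
    "smiles": lambda r: r.smiles or "",
    "moa": lambda r: "|".join(sorted(r.moa_terms)),
    "atc": lambda r: "|".join(r.atc_codes),
}


@dataclass(frozen=True)
class PromptSpec:
    task: str
    k: int
    payload: str
    constraints: str

    def render(self) -> str:
        return f"{self.constraints}\n\n{self.payload}\n"


def _feature_payload(records: Sequence[DrugRecord], features: Sequence[str]) -> str:
    rows = []
    for r in records:
        row = {"id": r.id}
        for f in features:
            if f not in _FEATURE_COLUMNS:
                raise ValueError(f"unknown feature column {f!r}")
            row[f] = _FEATURE_COLUMNS[f](r)
        rows.append(row)
    return pd.DataFrame(rows).to_csv(index=False).strip()


def _edge_payload(network: SignedDDINetwork) -> str:
    lines = ["drug_a,drug_b,interaction"]
    lines += [f"{a},{b},{cls}" for (a, b), (cls, _) in sorted(network.edges.items())]
    return "\n".join(lines)


def build_prompt(
    task: str,
    k: int,
    records: Optional[Sequence[DrugRecord]] = None,
    network: Optional[SignedDDINetwork] = None,
    features: Sequence[str] = ("smiles",),
) -> str:
    """Render a deterministic clustering prompt.

    ``single-feature`` / ``multi-feature`` tasks need ``records`` and the
    feature column(s) to include; the ``ddi-network`` task needs the
    edge list and adds the monochromaticity constraint — group-group
    interactions should be predominantly synergy or antagonism.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
    if k < 2:
        raise ValueError("k must be >= 2")
    if task == "ddi-network":
        if network is None or not network.edges:
            raise ValueError("ddi-network task needs a non-empty network")
        constraints = (
            "This is a dataset of antibiotic combinations. The first and second "
            "columns are abbreviations of antibiotics, and the third column is "
            f"the type of antibiotic combination. Please classify the antibiotics "
            f"into {k} groups, and make sure the group-group interactions are "
            f"predominantly either synergy or antagonism effects. {_OUTPUT_CLAUSE}"
        )
        payload = _edge_payload(network)
    else:
        if not records:
            raise ValueError(f"{task} task needs drug records")
        if task == "single-feature" and len(features) != 1:
            raise ValueError("single-feature task takes exactly one feature")
        noun = {"single-feature": "the feature given", "multi-feature": "all features given"}
        constraints = (
            f"There are {len(records)} antibiotics. Dividing these antibiotics "
            f"into {k} groups according to {noun[task]} in the table below. "
            f"{_OUTPUT_CLAUSE}"
        )
        payload = _feature_payload(records, features)
    return PromptSpec(task=task, k=k, payload=payload, constraints=constraints).render()


def format_clustering_response(clustering: Clustering) -> str:
    """Serialize a partition the way the prompts request it — the exact
    inverse of :func:`parse_clustering_response`."""
    groups = clustering.clusters()
    inner = ", ".join(
        f'"G{g}": [' + ", ".join(f'"{m}"' for m in members) + "]"
        for g, members in groups.items()
    )
    return "{" + inner + "}"


def _extract_mapping(text: str) -> dict:
    """Find and evaluate the single mapping literal in a response."""
    text = re.sub(r"```[a-zA-Z]*\n?", "", text)
    start = text.find("{")
    if start == -1:
        raise ValueError("no mapping found in response")
    depth = 0
    end = None
    for i, ch in enumerate(text[start:], start=start):
        if ch == "{":
            depth += 1
        elif ch == "}":
            depth -= 1
            if depth == 0:
                end = i
                break
    if end is None:
        raise ValueError("no mapping found in response (unbalanced braces)")
    literal = text[start : end + 1]
    try:
        mapping = ast.literal_eval(literal)
    except (ValueError, SyntaxError) as exc:
        raise ValueError(f"could not parse mapping literal: {exc}") from None
    if not isinstance(mapping, dict) or not mapping:
        raise ValueError("response mapping is not a non-empty dictionary")
    return mapping


def parse_clustering_response(
    text: str,
    expected_ids: Sequence[str],
    expected_k: Optional[int] = None,
    strict: bool = True,
) -> Clustering:
    """Parse a dictionary-format clustering response into a Clustering.

    Ids are matched case-insensitively against ``expected_ids`` (logged
    when the case differs).  Strict mode errors on missing, extra or
    duplicated ids and on a group-count mismatch with ``expected_k``;
    lenient mode drops extras and logs missing ids.
    """
    mapping = _extract_mapping(text)
    canon = {str(i).lower(): str(i) for i in expected_ids}
    groups: dict = {}
    seen: dict = {}
    for key in sorted(mapping, key=str):
        members = mapping[key]
        if not isinstance(members, (list, tuple)):
            raise ValueError(f"group {key!r} value must be a list of ids")
        resolved = []
        for raw in members:
            raw = str(raw)
            match = canon.get(raw.lower())
            if match is None:
                if strict:
                    raise ValueError(f"unexpected id {raw!r} in response")
                logger.warning("dropping unexpected id %r", raw)
                continue
            if match != raw:
                logger.info("case-normalized response id %r -> %r", raw, match)
            if match in seen:
                raise ValueError(f"id {match!r} appears in groups {seen[match]!r} and {key!r}")
            seen[match] = key
            resolved.append(match)
        if resolved:
            groups[str(key)] = resolved
        elif strict:
            raise ValueError(f"group {key!r} is empty")
    missing = [i for i in expected_ids if str(i) not in seen]
    if missing:
        if strict:
            raise ValueError(f"response is missing id(s) {missing}")
        logger.warning("response is missing id(s) %s", missing)
    if strict and expected_k is not None and len(groups) != expected_k:
        raise ValueError(f"expected {expected_k} groups, response has {len(groups)}")
    if not groups:
        raise ValueError("no recognized ids in response")
    return Clustering.from_groups(groups)


def score_response(
    parsed: Clustering,
    network: SignedDDINetwork,
    reference: Optional[Clustering] = None,
    purity_classes=("synergy", "antagonism"),
) -> dict:
    """Score a parsed partition on the network (edge purity), and against
    a reference partition (ARI / NMI) when one is given."""
    result = edge_purity(network, parsed, classes=purity_classes)
    report = {
        "edge_purity": result.purity,
        "counted_edges": result.counted_edges,
        "k": parsed.k,
    }
    if reference is not None:
        ari, nmi, _ = compare_clusterings(parsed, reference)
        report["ari"] = ari
        report["nmi"] = nmi
    return report


def comparison_table(scored: dict) -> pd.DataFrame:
    """Assemble method -> score reports into one comparison table
    (one row per method, e.g. chemical structure, mechanism of action,
    clustering ensemble, network-based clustering)."""
    rows = []
    for method, report in scored.items():
        row = {"method": method}
        row.update(report)
        rows.append(row)
    return pd.DataFrame(rows)
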