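"""Readers and writers for every external representation the pipeline touches.

Formats: CSV/TSV drug tables and edge lists, CSV feature matrices
(fingerprints, growth curves), CSV similarity matrices, JSON clusterings
(the "dictionary format"), and GraphML / SIF exports for Cytoscape.
All text is UTF-8; delimiter is inferred from the extension
(.csv comma, .tsv tab).  Multi-valued cells (ATC codes, MoA terms) use
"|" as the separator so they stay comma-safe inside CSV.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .core import (
    ATC_PATTERN,
    INTERACTION_CLASSES,
    Clustering,
    DrugRecord,
    SignedDDINetwork,
    SimilarityMatrix,
    validate_records,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "read_drug_table",
    "write_drug_table",
    "read_feature_vectors",
    "write_feature_vectors",
    "attach_features",
    "read_ddi_edges",
    "write_ddi_edges",
    "read_clustering",
    "write_clustering",
    "read_similarity_matrix",
    "write_similarity_matrix",
    "export_cytoscape",
]

MULTIVALUE_SEP = "|"


class FormatError(ValueError):
    """A file violates the expected format or a type invariant."""


def _delimiter(path) -> str:
    return "\t" if str(path).lower().endswith(".tsv") else ","


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    try:
        df = pd.read_csv(path, sep=_delimiter(path), dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"empty file: {path}") from None
    if df.empty:
        raise FormatError(f"no data rows in {path}")
    df.columns = [c.strip().lower() for c in df.columns]
    return df


# ---------------------------------------------------------------------------
# Drug tables
# ---------------------------------------------------------------------------

def read_drug_table(path) -> list:
    """Read a CSV/TSV drug table into validated :class:`DrugRecord` rows.

    Recognized columns (case-insensitive): ``id`` (required), ``name``,
    ``smiles``, ``moa``, ``atc``.  ATC and MoA cells may hold multiple
    values separated by "|".  Missing optional columns yield absent fields.
    """
    df = _read_table(path)
    if "id" not in df.columns:
        raise FormatError(f"{path}: header must name an 'id' column, got {list(df.columns)}")
    records = []
    seen = set()
    for rownum, row in enumerate(df.itertuples(index=False), start=2):
        row = dict(zip(df.columns, row))
        drug_id = row["id"].strip()
        if drug_id in seen:
            raise FormatError(f"{path}: duplicate drug id {drug_id!r}")
        seen.add(drug_id)
        atc_cell = row.get("atc", "").strip()
        atc = tuple(c.strip() for c in atc_cell.split(MULTIVALUE_SEP) if c.strip())
        for code in atc:
            if not ATC_PATTERN.match(code):
                raise FormatError(f"{path} row {rownum}: malformed ATC code {code!r}")
        moa_cell = row.get("moa", "").strip()
        moa = frozenset(t.strip() for t in moa_cell.split(MULTIVALUE_SEP) if t.strip())
        smiles = row.get("smiles", "").strip() or None
        records.append(
            DrugRecord(
                id=drug_id,
                name=row.get("name", "").strip(),
                smiles=smiles,
                moa_terms=moa,
                atc_codes=atc,
            )
        )
    validate_records(records)
    return records


def write_drug_table(records: Sequence[DrugRecord], path) -> None:
    """Write the scalar/multi-value drug fields as CSV/TSV (vector features
    go through :func:`write_feature_vectors`)."""
    validate_records(records)
    df = pd.DataFrame(
        {
            "id": [r.id for r in records],
            "name": [r.name for r in records],
            "smiles": [r.smiles or "" for r in records],
            "moa": [MULTIVALUE_SEP.join(sorted(r.moa_terms)) for r in records],
            "atc": [MULTIVALUE_SEP.join(r.atc_codes) for r in records],
        }
    )
    df.to_csv(path, sep=_delimiter(path), index=False)


def read_feature_vectors(path) -> dict:
    """Read an id x feature CSV (fingerprint bits or growth-curve readings)
    into an id -> float vector mapping, preserving file row order."""
    df = _read_table(path)
    out = {}
    for rownum, row in enumerate(df.itertuples(index=False), start=2):
        drug_id = str(row[0])
        if drug_id in out:
            raise FormatError(f"{path}: duplicate id {drug_id!r}")
        try:
            out[drug_id] = np.array([float(x) for x in row[1:]])
        except ValueError as exc:
            raise FormatError(f"{path} row {rownum}: non-numeric value ({exc})") from None
    lengths = {v.size for v in out.values()}
    if len(lengths) > 1:
        raise FormatError(f"{path}: rows have mismatched lengths {sorted(lengths)}")
    return out


def write_feature_vectors(vectors: dict, path, prefix: str = "f") -> None:
    ids = list(vectors)
    arr = np.vstack([np.asarray(vectors[i], dtype=float) for i in ids])
    cols = [f"{prefix}{j}" for j in range(arr.shape[1])]
    df = pd.DataFrame(arr, columns=cols)
    df.insert(0, "id", ids)
    # Bit vectors round-trip as integers for readability.
    if np.array_equal(arr, arr.astype(int)):
        df[cols] = arr.astype(int)
    df.to_csv(path, sep=_delimiter(path), index=False)


def attach_features(
    records: Sequence[DrugRecord],
    growth_curves: Optional[dict] = None,
    fingerprints: Optional[dict] = None,
) -> list:
    """Attach vector features (by id) to drug records."""
    out = []
    for rec in records:
        if growth_curves is not None and rec.id in growth_curves:
            rec = rec.with_(growth_curve=np.asarray(growth_curves[rec.id], dtype=float))
        if fingerprints is not None and rec.id in fingerprints:
            rec = rec.with_(fingerprint=np.asarray(fingerprints[rec.id]).astype(np.uint8))
        out.append(rec)
    validate_records(out)
    return out


# ---------------------------------------------------------------------------
# Edge lists
# ---------------------------------------------------------------------------

def read_ddi_edges(path, score_thresholds: Optional[tuple] = None) -> SignedDDINetwork:
    """Read a signed DDI edge list.

    The third column holds either a class token in
    {synergy, additive, antagonism} or a numeric interaction score.  A
    numeric score s is classified against user-supplied thresholds
    (low, high), low < high: synergy if s <= low, antagonism if s >= high,
    additive otherwise.  Pair order is normalized lexicographically; a
    duplicate pair with a conflicting class is an error.
    """
    df = _read_table(path)
    if df.shape[1] < 3:
        raise FormatError(f"{path}: edge list needs at least 3 columns")
    if score_thresholds is not None:
        low, high = score_thresholds
        if not low < high:
            raise FormatError(f"score thresholds must satisfy low < high, got {score_thresholds}")
    nodes: list = []
    edges = {}
    for rownum, row in enumerate(df.itertuples(index=False), start=2):
        a, b, third = str(row[0]).strip(), str(row[1]).strip(), str(row[2]).strip()
        if a == b:
            raise FormatError(f"{path} row {rownum}: self-edge on {a!r}")
        score = None
        if third.lower() in INTERACTION_CLASSES:
            cls = third.lower()
        else:
            try:
                score = float(third)
            except ValueError:
                raise FormatError(
                    f"{path} row {rownum}: unknown interaction class {third!r}"
                ) from None
            if score_thresholds is None:
                raise FormatError(
                    f"{path} row {rownum}: numeric score {third} requires score_thresholds"
                )
            low, high = score_thresholds
            cls = "synergy" if score <= low else ("antagonism" if score >= high else "additive")
        pair = (a, b) if a < b else (b, a)
        if pair in edges and edges[pair][0] != cls:
            raise FormatError(
                f"{path} row {rownum}: conflicting classes for pair {pair}: "
                f"{edges[pair][0]} vs {cls}"
            )
        edges[pair] = (cls, score)
        for node in (a, b):
            if node not in nodes:
                nodes.append(node)
    return SignedDDINetwork(nodes, edges)


def write_ddi_edges(network: SignedDDINetwork, path) -> None:
    rows = []
    for (a, b), (cls, score) in sorted(network.edges.items()):
        rows.append({"drug_a": a, "drug_b": b, "class": cls,
                     "score": "" if score is None else score})
    pd.DataFrame(rows, columns=["drug_a", "drug_b", "class", "score"]).to_csv(
        path, sep=_delimiter(path), index=False
    )


# ---------------------------------------------------------------------------
# Clusterings (JSON dictionary format)
# ---------------------------------------------------------------------------

def write_clustering(clustering: Clustering, path) -> None:
    """Serialize a partition as a JSON object: cluster label -> member list.

    Keys are sorted and members sorted for reproducible bytes.
    """
    groups = {str(g): members for g, members in clustering.clusters().items()}
    Path(path).write_text(
        json.dumps(groups, sort_keys=True, indent=2) + "\n", encoding="utf-8"
    )


def read_clustering(path) -> Clustering:
    """Read a JSON clustering; group keys (arbitrary strings) become labels
    1..k in sorted-key order."""
    try:
        groups = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON ({exc})") from None
    if not isinstance(groups, dict) or not groups:
        raise FormatError(f"{path}: expected a non-empty JSON object of groups")
    try:
        return Clustering.from_groups(groups)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from None


# ---------------------------------------------------------------------------
# Similarity matrices
# ---------------------------------------------------------------------------

def write_similarity_matrix(matrix: SimilarityMatrix, path) -> None:
    """CSV with the id list as both header row and first column."""
    df = pd.DataFrame(matrix.values, index=list(matrix.ids), columns=list(matrix.ids))
    df.to_csv(path, sep=_delimiter(path), index=True, index_label="id",
              float_format="%.17g")


def read_similarity_matrix(path, kind: str = "generic") -> SimilarityMatrix:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    try:
        # ids are case-sensitive here; bypass the lowercasing table reader
        df = pd.read_csv(path, sep=_delimiter(path), dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"empty file: {path}") from None
    if df.empty:
        raise FormatError(f"no data rows in {path}")
    ids_rows = [str(x) for x in df.iloc[:, 0]]
    ids_cols = [str(c) for c in df.columns[1:]]
    if ids_rows != ids_cols:
        raise FormatError(f"{path}: header ids and first-column ids differ")
    try:
        values = df.iloc[:, 1:].astype(float).to_numpy()
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric matrix entry ({exc})") from None
    try:
        return SimilarityMatrix(ids_rows, values, kind=kind)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from None


# ---------------------------------------------------------------------------
# Cytoscape export
# ---------------------------------------------------------------------------

def export_cytoscape(
    network: SignedDDINetwork,
    clustering: Optional[Clustering],
    path,
    format: str = "graphml",
) -> None:
    """Export the network (plus optional cluster labels) for Cytoscape.

    ``graphml``: one file; node attribute "cluster", edge attribute
    "interaction" (and "score" where present).  ``sif+attrs``: a .sif edge
    file plus node and edge attribute TSV tables alongside it.
    """
    if clustering is not None:
        missing = [n for n in network.node_ids if n not in clustering.assignment]
        if missing:
            raise FormatError(f"clustering does not cover node(s) {missing}")
    if format == "graphml":
        g = nx.Graph()
        for node in network.node_ids:
            attrs = {"cluster": int(clustering.label_of(node))} if clustering else {}
            g.add_node(node, **attrs)
        for (a, b), (cls, score) in network.edges.items():
            attrs = {"interaction": cls}
            if score is not None:
                attrs["score"] = float(score)
            g.add_edge(a, b, **attrs)
        nx.write_graphml(g, path)
    elif format == "sif+attrs":
        path = Path(path)
        lines = []
        linked = set()
        for (a, b), (cls, _) in sorted(network.edges.items()):
            lines.append(f"{a}\t{cls}\t{b}")
            linked.update((a, b))
        lines.extend(n for n in network.node_ids if n not in linked)
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        if clustering is not None:
            node_rows = [{"id": n, "cluster": clustering.label_of(n)} for n in network.node_ids]
            pd.DataFrame(node_rows).to_csv(
                path.with_suffix(".node_attrs.tsv"), sep="\t", index=False
            )
        edge_rows = [
            {"drug_a": a, "drug_b": b, "interaction": cls,
             "score": "" if score is None else score}
            for (a, b), (cls, score) in sorted(network.edges.items())
        ]
        pd.DataFrame(edge_rows).to_csv(
            path.with_suffix(".edge_attrs.tsv"), sep="\t", index=False
        )
    else:
        raise FormatError(f"unknown export format {format!r} (use 'graphml' or 'sif+attrs')")
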