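"""Core domain types shared across the pipeline.

A drug is described by up to four feature modalities (chemical structure,
mechanism of action, growth phenotype, ATC classification).  Pairwise drug
relations live in two containers: a :class:`SimilarityMatrix` (symmetric,
unit diagonal, values in [0, 1]) and a :class:`SignedDDINetwork`, an
undirected interaction network whose edges carry one of the three
combination classes — synergy, additive, antagonism.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "ATC_PATTERN",
    "INTERACTION_CLASSES",
    "DrugRecord",
    "SimilarityMatrix",
    "SignedDDINetwork",
    "Clustering",
    "validate_records",
]

#: WHO ATC code shape: anatomical letter, 2-digit therapeutic group,
#: pharmacological letter, chemical letter, 2-digit substance.
ATC_PATTERN = re.compile(r"^[A-Za-z]\d{2}[A-Za-z]{2}\d{2}$")

#: The three drug-combination classes of a signed DDI network.
INTERACTION_CLASSES = ("synergy", "additive", "antagonism")

# Tolerances for matrix validation.
_SYM_TOL = 1e-9
_RANGE_TOL = 1e-9


@dataclass(frozen=True)
class DrugRecord:
    """One drug's identifier and feature annotations.

    Any feature may be absent; each similarity measure checks for the
    features it needs and errors with the offending ids otherwise.
    """

    id: str
    name: str = ""
    smiles: Optional[str] = None
    moa_terms: frozenset = field(default_factory=frozenset)
    atc_codes: tuple = ()
    growth_curve: Optional[np.ndarray] = None
    fingerprint: Optional[np.ndarray] = None

    def __post_init__(self):
        if not self.id or not str(self.id).strip():
            raise ValueError("drug id must be a non-empty token")
        object.__setattr__(self, "moa_terms", frozenset(self.moa_terms))
        object.__setattr__(self, "atc_codes", tuple(self.atc_codes))
        for code in self.atc_codes:
            if not ATC_PATTERN.match(code):
                raise ValueError(
                    f"malformed ATC code {code!r} for drug {self.id!r}: "
                    "expected letter, 2 digits, 2 letters, 2 digits"
                )
        if self.growth_curve is not None:
            gc = np.asarray(self.growth_curve, dtype=float)
            if gc.ndim != 1 or gc.size == 0:
                raise ValueError(f"growth curve of {self.id!r} must be a non-empty vector")
            if np.any(gc < 0) or not np.all(np.isfinite(gc)):
                raise ValueError(f"growth curve of {self.id!r} must be finite and non-negative")
            object.__setattr__(self, "growth_curve", gc)
        if self.fingerprint is not None:
            fp = np.asarray(self.fingerprint)
            if not np.isin(fp, (0, 1)).all():
                raise ValueError(f"fingerprint of {self.id!r} must be binary")
            object.__setattr__(self, "fingerprint", fp.astype(np.uint8))

    def with_(self, **kwargs) -> "DrugRecord":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def validate_records(records: Sequence[DrugRecord]) -> None:
    """Check cross-record invariants of a drug table.

    Ids must be unique; growth curves (where present) must share one
    length, as must fingerprints.
    """
    seen = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate drug id {rec.id!r}")
        seen.add(rec.id)
    for attr in ("growth_curve", "fingerprint"):
        lengths = {len(getattr(r, attr)) for r in records if getattr(r, attr) is not None}
        if len(lengths) > 1:
            raise ValueError(f"{attr} vectors have mismatched lengths: {sorted(lengths)}")


class SimilarityMatrix:
    """Symmetric drug x drug similarity with aligned id ordering.

    Invariants enforced at construction: symmetry within 1e-9, diagonal
    exactly 1, entries in [0, 1] (tiny numerical excursions are clipped).
    """

    KINDS = (
        "structural", "pharmacological", "phenotypic", "therapeutic",
        "network", "fused", "coassociation", "generic",
    )

    def __init__(self, ids: Sequence[str], values: np.ndarray, kind: str = "generic"):
        ids = tuple(str(i) for i in ids)
        if len(set(ids)) != len(ids):
            raise ValueError("similarity matrix ids must be unique")
        values = np.asarray(values, dtype=float)
        n = len(ids)
        if values.shape != (n, n):
            raise ValueError(f"matrix shape {values.shape} does not match {n} ids")
        if not np.all(np.isfinite(values)):
            raise ValueError("similarity matrix contains non-finite entries")
        if np.abs(values - values.T).max(initial=0.0) > _SYM_TOL:
            raise ValueError("similarity matrix is asymmetric beyond 1e-9")
        if values.min(initial=1.0) < -_RANGE_TOL or values.max(initial=0.0) > 1 + _RANGE_TOL:
            raise ValueError("similarity values outside [0, 1] beyond 1e-9")
        if n and np.abs(np.diag(values) - 1.0).max() > _RANGE_TOL:
            raise ValueError("similarity diagonal must be 1")
        if kind not in self.KINDS:
            raise ValueError(f"unknown similarity kind {kind!r}")
        values = np.clip((values + values.T) / 2.0, 0.0, 1.0)
        if n:
            np.fill_diagonal(values, 1.0)
        self.ids = ids
        self.values = values
        self.kind = kind

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, drug_id: str) -> int:
        return self.ids.index(drug_id)

    def pair(self, a: str, b: str) -> float:
        return float(self.values[self.index_of(a), self.index_of(b)])

    def reorder(self, ids: Sequence[str]) -> "SimilarityMatrix":
        """Return the matrix restricted/reordered to ``ids``."""
        idx = [self.ids.index(i) for i in ids]
        return SimilarityMatrix(ids, self.values[np.ix_(idx, idx)], self.kind)

    def upper_triangle(self) -> np.ndarray:
        """Strict upper-triangle entries, row-major."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def __eq__(self, other):
        return (
            isinstance(other, SimilarityMatrix)
            and self.ids == other.ids
            and np.array_equal(self.values, other.values)
        )

    def __repr__(self):
        return f"SimilarityMatrix(kind={self.kind!r}, n={self.n})"


def _norm_pair(a: str, b: str) -> tuple:
    """Lexicographically normalized undirected pair key."""
    if a == b:
        raise ValueError(f"self-interaction {a!r}-{b!r} is not allowed")
    return (a, b) if a < b else (b, a)


class SignedDDINetwork:
    """Undirected drug interaction network with per-edge class labels.

    Edges are keyed by the lexicographically ordered id pair and carry a
    class in {synergy, additive, antagonism} plus an optional raw score.
    """

    def __init__(
        self,
        node_ids: Sequence[str],
        edges: Mapping[tuple, tuple] | Iterable[tuple],
    ):
        self.node_ids = tuple(str(i) for i in node_ids)
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValueError("network node ids must be unique")
        node_set = set(self.node_ids)
        norm = {}
        items = edges.items() if isinstance(edges, Mapping) else edges
        for key, val in items:
            a, b = key
            cls, score = (val if isinstance(val, tuple) else (val, None))
            pair = _norm_pair(str(a), str(b))
            if cls not in INTERACTION_CLASSES:
                raise ValueError(f"unknown interaction class {cls!r} on pair {pair}")
            if pair in norm and norm[pair][0] != cls:
                raise ValueError(
                    f"conflicting classes for pair {pair}: {norm[pair][0]} vs {cls}"
                )
            if pair[0] not in node_set or pair[1] not in node_set:
                missing = [x for x in pair if x not in node_set]
                raise ValueError(f"edge endpoint(s) {missing} not in node list")
            norm[pair] = (cls, None if score is None else float(score))
        self.edges = norm

    @property
    def n(self) -> int:
        return len(self.node_ids)

    def edge_class(self, a: str, b: str) -> Optional[str]:
        entry = self.edges.get(_norm_pair(a, b))
        return entry[0] if entry else None

    def neighbors(self, drug_id: str) -> set:
        out = set()
        for (a, b) in self.edges:
            if a == drug_id:
                out.add(b)
            elif b == drug_id:
                out.add(a)
        return out

    def subnetwork(self, ids: Sequence[str]) -> "SignedDDINetwork":
        """Induced subnetwork on ``ids`` (order preserved)."""
        keep = set(ids)
        edges = {p: v for p, v in self.edges.items() if p[0] in keep and p[1] in keep}
        return SignedDDINetwork(ids, edges)

    def class_counts(self) -> dict:
        counts = dict.fromkeys(INTERACTION_CLASSES, 0)
        for cls, _ in self.edges.values():
            counts[cls] += 1
        return counts

    def __eq__(self, other):
        return (
            isinstance(other, SignedDDINetwork)
            and self.node_ids == other.node_ids
            and {p: c for p, (c, _) in self.edges.items()}
            == {p: c for p, (c, _) in other.edges.items()}
        )

    def __repr__(self):
        return f"SignedDDINetwork(n={self.n}, edges={len(self.edges)})"


class Clustering:
    """A partition of drug ids into k labeled groups, labels 1..k.

    Labels form a contiguous range starting at 1; empty clusters are
    forbidden after construction.
    """

    def __init__(self, assignment: Mapping[str, int]):
        if not assignment:
            raise ValueError("clustering must assign at least one id")
        assignment = {str(i): int(l) for i, l in assignment.items()}
        labels = sorted(set(assignment.values()))
        k = len(labels)
        if labels != list(range(1, k + 1)):
            raise ValueError(
                f"cluster labels must be the contiguous range 1..k, got {labels}"
            )
        self.assignment = assignment
        self.k = k

    @classmethod
    def from_labels(cls, ids: Sequence[str], labels: Sequence[int]) -> "Clustering":
        """Build from parallel id/label sequences, relabeling clusters to
        1..k in order of first appearance."""
        if len(ids) != len(labels):
            raise ValueError("ids and labels must have equal length")
        remap = {}
        assignment = {}
        for i, raw in zip(ids, labels):
            if raw not in remap:
                remap[raw] = len(remap) + 1
            assignment[str(i)] = remap[raw]
        return cls(assignment)

    @classmethod
    def from_groups(cls, groups: Mapping[object, Sequence[str]]) -> "Clustering":
        """Build from a group-key -> member-list mapping; keys are mapped to
        labels 1..k in sorted-key order."""
        assignment = {}
        for label, key in enumerate(sorted(groups, key=str), start=1):
            members = groups[key]
            if not isinstance(members, (list, tuple)):
                raise ValueError(f"group {key!r} value must be a list of ids")
            if not members:
                raise ValueError(f"group {key!r} is empty; empty clusters are forbidden")
            for m in members:
                if m in assignment:
                    raise ValueError(f"id {m!r} appears in more than one group")
                assignment[str(m)] = label
        return cls(assignment)

    @property
    def ids(self) -> tuple:
        return tuple(self.assignment)

    def label_of(self, drug_id: str) -> int:
        return self.assignment[drug_id]

    def clusters(self) -> dict:
        """Label -> sorted member list."""
        out = {g: [] for g in range(1, self.k + 1)}
        for i, g in self.assignment.items():
            out[g].append(i)
        return {g: sorted(ms) for g, ms in out.items()}

    def labels_for(self, ids: Sequence[str]) -> np.ndarray:
        return np.array([self.assignment[i] for i in ids], dtype=int)

    def same_partition(self, other: "Clustering") -> bool:
        """Equality up to cluster relabeling."""
        if set(self.assignment) != set(other.assignment):
            return False
        mine = {frozenset(ms) for ms in self.clusters().values()}
        theirs = {frozenset(ms) for ms in other.clusters().values()}
        return mine == theirs

    def __eq__(self, other):
        return isinstance(other, Clustering) and self.assignment == other.assignment

    def __repr__(self):
        return f"Clustering(n={len(self.assignment)}, k={self.k})"
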