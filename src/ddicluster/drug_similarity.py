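"""The four drug-information similarity measures.

structural      Tanimoto coefficient on MACCS substructure fingerprints
                (166 keys) computed from SMILES, or on precomputed binary
                fingerprints where no SMILES exists.
pharmacological Jaccard index over mechanism-of-action term sets.
phenotypic      (Pearson r + 1) / 2 on bacterial growth curves, mapping
                correlation into [0, 1] (cosine variant available).
therapeutic     5-level ATC prefix score: L/5 where L counts consecutive
                matching leading levels; code lists are combined by
                best-match averaging in both directions.

All measures return a validated :class:`SimilarityMatrix` whose row/column
order follows the input record order.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from .core import DrugRecord, SimilarityMatrix, validate_records

logger = logging.getLogger(__name__)

__all__ = [
    "MACCS_N_BITS",
    "fingerprint_from_smiles",
    "tanimoto",
    "structural_similarity",
    "pharmacological_similarity",
    "phenotypic_similarity",
    "therapeutic_similarity",
    "atc_code_score",
    "compute_all_similarities",
]

#: Number of MACCS substructure keys (the chemistry backend pads a 167th
#: never-set bit at index 0, which we drop).
MACCS_N_BITS = 166

# ATC level cut points: prefix lengths after levels 1..5 of the 7-character
# code (anatomical / therapeutic / pharmacological / chemical / substance).
_ATC_PREFIX_LENGTHS = (1, 3, 4, 5, 7)


def fingerprint_from_smiles(smiles: str) -> np.ndarray:
    """Convert a SMILES string into a 166-bit MACCS fingerprint.

    Canonicalization is delegated to RDKit, so two spellings of the same
    molecule yield identical fingerprints.  Raises ``ValueError`` carrying
    the offending string when the SMILES cannot be parsed.
    """
    from rdkit import Chem, RDLogger
    from rdkit.Chem import MACCSkeys

    RDLogger.DisableLog("rdApp.error")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    fp = MACCSkeys.GenMACCSKeys(mol)
    bits = np.zeros(fp.GetNumBits(), dtype=np.uint8)
    bits[list(fp.GetOnBits())] = 1
    return bits[1:]  # drop the padding bit


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto coefficient |A∩B| / |A∪B| over set bits; 0 if both empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        return 0.0
    return int(np.logical_and(a, b).sum()) / union


def _build(ids, values, kind) -> SimilarityMatrix:
    values = np.asarray(values, dtype=float)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(ids, values, kind=kind)


def structural_similarity(records: Sequence[DrugRecord]) -> SimilarityMatrix:
    """Pairwise Tanimoto similarity of MACCS fingerprints.

    Records may carry a precomputed binary fingerprint (preferred when
    present) or a SMILES string; records with neither are reported in one
    error.  A pair of empty fingerprints scores 0 with a warning.
    """
    validate_records(records)
    missing = [r.id for r in records if r.fingerprint is None and r.smiles is None]
    if missing:
        raise ValueError(f"records lack both SMILES and fingerprint: {missing}")
    fps = [
        r.fingerprint if r.fingerprint is not None else fingerprint_from_smiles(r.smiles)
        for r in records
    ]
    if len({len(fp) for fp in fps}) > 1:
        raise ValueError("fingerprints have mismatched lengths")
    n = len(records)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            if not fps[i].any() and not fps[j].any():
                logger.warning(
                    "both fingerprints empty for %s/%s; structural similarity set to 0",
                    records[i].id, records[j].id,
                )
            values[i, j] = values[j, i] = tanimoto(fps[i], fps[j])
    return _build([r.id for r in records], values, "structural")


def pharmacological_similarity(records: Sequence[DrugRecord]) -> SimilarityMatrix:
    """Jaccard index of mechanism-of-action term sets."""
    validate_records(records)
    empty = [r.id for r in records if not r.moa_terms]
    if empty:
        raise ValueError(f"records have empty MoA term sets: {empty}")
    n = len(records)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = records[i].moa_terms, records[j].moa_terms
            values[i, j] = values[j, i] = len(a & b) / len(a | b)
    return _build([r.id for r in records], values, "pharmacological")


def phenotypic_similarity(
    records: Sequence[DrugRecord], method: str = "pearson"
) -> SimilarityMatrix:
    """Growth-curve similarity: (r + 1)/2 with r the Pearson correlation
    (default) or the cosine of the centered curves ("cosine").

    A zero-variance curve has undefined correlation; its pairs score the
    uninformative 0.5 with a warning.
    """
    validate_records(records)
    bad = [r.id for r in records if r.growth_curve is None]
    if bad:
        raise ValueError(f"records lack growth curves: {bad}")
    curves = np.vstack([r.growth_curve for r in records])
    if curves.shape[1] < 3:
        raise ValueError("growth curves must have length >= 3")
    if method not in ("pearson", "cosine"):
        raise ValueError(f"unknown phenotypic method {method!r}")
    centered = curves - curves.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    flat = norms < 1e-12
    if flat.any():
        ids = [records[i].id for i in np.flatnonzero(flat)]
        logger.warning("zero-variance growth curve(s) %s; their pairs score 0.5", ids)
    safe = np.where(flat, 1.0, norms)
    unit = centered / safe[:, None]
    r = unit @ unit.T
    r[flat, :] = 0.0
    r[:, flat] = 0.0
    values = np.clip((r + 1.0) / 2.0, 0.0, 1.0)
    return _build([rec.id for rec in records], values, "phenotypic")


def atc_code_score(code_a: str, code_b: str) -> float:
    """Similarity of two 7-character ATC codes: L/5, where L is the number
    of consecutive matching leading levels."""
    level = 0
    for plen in _ATC_PREFIX_LENGTHS:
        if code_a[:plen].upper() == code_b[:plen].upper():
            level += 1
        else:
            break
    return level / 5.0


def therapeutic_similarity(records: Sequence[DrugRecord]) -> SimilarityMatrix:
    """ATC-code similarity with best-match averaging.

    For each code of drug A, take its best score against B's codes; average
    over A's codes; symmetrize by averaging the two directions.
    """
    validate_records(records)
    empty = [r.id for r in records if not r.atc_codes]
    if empty:
        raise ValueError(f"records have no ATC codes: {empty}")
    n = len(records)
    values = np.eye(n)

    def directed(codes_a, codes_b):
        return float(np.mean([max(atc_code_score(a, b) for b in codes_b) for a in codes_a]))

    for i in range(n):
        for j in range(i + 1, n):
            ab = directed(records[i].atc_codes, records[j].atc_codes)
            ba = directed(records[j].atc_codes, records[i].atc_codes)
            values[i, j] = values[j, i] = (ab + ba) / 2.0
    return _build([r.id for r in records], values, "therapeutic")


def compute_all_similarities(records: Sequence[DrugRecord]) -> dict:
    """Compute every similarity the records' features allow.

    Returns a name -> SimilarityMatrix dict with keys among
    {structural, pharmacological, phenotypic, therapeutic}.
    """
    out = {}
    if all(r.fingerprint is not None or r.smiles is not None for r in records):
        out["structural"] = structural_similarity(records)
    if all(r.moa_terms for r in records):
        out["pharmacological"] = pharmacological_similarity(records)
    if all(r.growth_curve is not None for r in records):
        out["phenotypic"] = phenotypic_similarity(records)
    if all(r.atc_codes for r in records):
        out["therapeutic"] = therapeutic_similarity(records)
    return out
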