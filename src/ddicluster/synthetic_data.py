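"""Synthetic studies: planted-cluster drugs with correlated features and a
monochromatic signed DDI network.

The generator emulates the structure of antibiotic combination screens:
a small panel of drugs falling into mechanistic classes whose class-class
interactions are predominantly one sign.  Default geometry is 6 clusters
of 3 drugs (an 18-drug panel).  Every unordered drug pair becomes an edge
with probability ``density``; an edge is additive with probability
``additive_fraction`` and otherwise takes its cluster-pair block's
planted sign, flipped (synergy <-> antagonism) with probability
``epsilon``.  Within-cluster blocks are biased toward synergy; the
remaining blocks get a balanced random sign assignment.

Four feature modalities are generated per cluster and inherited by
members with independent noise:

* a random 166-bit prototype fingerprint, copied with per-bit flips
  (``fp_flip``) — fingerprints are emitted directly as bit vectors, and
  the structural similarity accepts them as-is, so no synthetic SMILES
  is fabricated;
* a cluster mechanism-of-action term set (``moa_mislabel`` swaps a
  member's set for another cluster's);
* a cluster logistic growth curve with cluster-specific midpoint and
  rate, plus per-member Gaussian noise (``curve_sigma``);
* a cluster ATC 5-character prefix (all within the antibacterial "J01"
  stem, like a real antibiotic panel) with member-specific final digits
  (``atc_scramble`` replaces the whole code with a random J01 code).

Generation is a pure function of the config (seed included).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import io_formats
from .core import Clustering, DrugRecord, SignedDDINetwork

__all__ = [
    "SyntheticConfig",
    "SyntheticStudy",
    "generate_network",
    "generate_features",
    "generate_study",
    "write_study",
    "read_study",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the generator; defaults mirror the 18-antibiotic /
    6-cluster panel with mild noise."""

    k: int = 6
    sizes: tuple = (3, 3, 3, 3, 3, 3)
    density: float = 1.0
    epsilon: float = 0.05
    additive_fraction: float = 0.0
    block_signs: Optional[dict] = None  # (g, h) g<=h -> class
    within_synergy_bias: float = 0.8
    fp_flip: float = 0.05
    moa_mislabel: float = 0.05
    curve_sigma: float = 0.05
    atc_scramble: float = 0.05
    fp_length: int = 166
    fp_density: float = 0.3
    n_timepoints: int = 12
    seed: int = 0

    def __post_init__(self):
        if self.k != len(self.sizes):
            raise ValueError(f"k={self.k} but {len(self.sizes)} cluster sizes given")
        if any(s <= 0 for s in self.sizes):
            raise ValueError("cluster sizes must be positive")
        for name in ("density", "epsilon", "additive_fraction", "fp_flip",
                     "moa_mislabel", "atc_scramble", "within_synergy_bias",
                     "fp_density"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.curve_sigma < 0:
            raise ValueError("curve_sigma must be non-negative")
        object.__setattr__(self, "sizes", tuple(int(s) for s in self.sizes))

    @property
    def n(self) -> int:
        return sum(self.sizes)

    def with_(self, **kwargs) -> "SyntheticConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SyntheticStudy:
    records: list
    network: SignedDDINetwork
    truth: Clustering
    block_signs: dict
    config: SyntheticConfig


def _ids_and_truth(config: SyntheticConfig) -> tuple:
    ids = [f"D{i + 1:02d}" for i in range(config.n)]
    assignment = {}
    pos = 0
    for g, size in enumerate(config.sizes, start=1):
        for _ in range(size):
            assignment[ids[pos]] = g
            pos += 1
    return ids, Clustering(assignment)


def _default_block_signs(config: SyntheticConfig, rng: np.random.Generator) -> dict:
    """Within-cluster blocks biased to synergy; off-diagonal blocks get a
    balanced random half/half assignment."""
    signs = {}
    for g in range(1, config.k + 1):
        signs[(g, g)] = (
            "synergy" if rng.random() < config.within_synergy_bias else "antagonism"
        )
    off = [(g, h) for g in range(1, config.k + 1) for h in range(g + 1, config.k + 1)]
    half = len(off) // 2
    labels = ["synergy"] * half + ["antagonism"] * (len(off) - half)
    rng.shuffle(labels)
    for blk, lab in zip(off, labels):
        signs[blk] = lab
    return signs


def generate_network(config: SyntheticConfig) -> tuple:
    """Sample the signed network; returns (network, truth, block_signs)."""
    rng = np.random.default_rng([int(config.seed) % (2**31), 101])
    ids, truth = _ids_and_truth(config)
    if config.block_signs is not None:
        block_signs = {tuple(sorted(b)): c for b, c in config.block_signs.items()}
        for g in range(1, config.k + 1):
            for h in range(g, config.k + 1):
                if (g, h) not in block_signs:
                    raise ValueError(f"block_signs missing block {(g, h)}")
    else:
        block_signs = _default_block_signs(config, rng)
    flip = {"synergy": "antagonism", "antagonism": "synergy"}
    edges = {}
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if rng.random() >= config.density:
                continue
            a, b = ids[i], ids[j]
            if rng.random() < config.additive_fraction:
                cls = "additive"
            else:
                g, h = sorted((truth.label_of(a), truth.label_of(b)))
                cls = block_signs[(g, h)]
                if rng.random() < config.epsilon:
                    cls = flip[cls]
            edges[(a, b)] = (cls, None)
    return SignedDDINetwork(ids, edges), truth, block_signs


#: All synthetic drugs live in the antibacterial ATC class, like a real
#: antibiotic panel; clusters differ at the pharmacological/chemical levels.
_ATC_STEM = "J01"


def _random_atc(rng: np.random.Generator) -> str:
    letters = list(string.ascii_uppercase)
    return (
        _ATC_STEM
        + str(rng.choice(letters))
        + str(rng.choice(letters))
        + f"{rng.integers(0, 100):02d}"
    )


def generate_features(truth: Clustering, config: SyntheticConfig) -> tuple:
    """Generate per-drug feature records from the planted partition.

    Returns ``(records, prototypes)`` where prototypes holds the
    per-cluster fingerprint, MoA set, curve parameters and ATC prefix.
    """
    rng = np.random.default_rng([int(config.seed) % (2**31), 202])
    clusters = truth.clusters()
    k = truth.k
    prototypes = {}
    letters = list(string.ascii_uppercase)
    # Distinct ATC prefixes per cluster so the planted signal is the prefix.
    prefixes = set()
    for g in range(1, k + 1):
        while True:
            prefix = _ATC_STEM + str(rng.choice(letters)) + str(rng.choice(letters))
            if prefix not in prefixes:
                prefixes.add(prefix)
                break
        prototypes[g] = {
            "fingerprint": (rng.random(config.fp_length) < config.fp_density).astype(np.uint8),
            "moa": frozenset({f"target_c{g}", f"process_c{g}", "antibacterial"}),
            "midpoint": float(rng.uniform(0.15, 0.85)),
            "rate": float(rng.uniform(5.0, 20.0)),
            "atc_prefix": prefix,
        }
    t = np.linspace(0.0, 1.0, config.n_timepoints)
    records = []
    member_index = {}
    for drug_id, g in truth.assignment.items():
        proto = prototypes[g]
        fp = proto["fingerprint"].copy()
        flips = rng.random(config.fp_length) < config.fp_flip
        fp[flips] = 1 - fp[flips]
        moa = proto["moa"]
        if rng.random() < config.moa_mislabel and k > 1:
            others = [h for h in range(1, k + 1) if h != g]
            moa = prototypes[int(rng.choice(others))]["moa"]
        curve = 1.0 / (1.0 + np.exp(-proto["rate"] * (t - proto["midpoint"])))
        curve = np.clip(curve + rng.normal(0.0, config.curve_sigma, size=t.size), 0.0, None)
        member_index[g] = member_index.get(g, 0) + 1
        if rng.random() < config.atc_scramble:
            atc = _random_atc(rng)
        else:
            atc = proto["atc_prefix"] + f"{member_index[g]:02d}"
        records.append(
            DrugRecord(
                id=drug_id,
                name=f"synthetic drug {drug_id}",
                moa_terms=moa,
                atc_codes=(atc,),
                growth_curve=curve,
                fingerprint=fp,
            )
        )
    records.sort(key=lambda r: r.id)
    return records, prototypes


def generate_study(config: SyntheticConfig = SyntheticConfig()) -> SyntheticStudy:
    """Compose network and features under one seed into a full study."""
    network, truth, block_signs = generate_network(config)
    records, _ = generate_features(truth, config)
    return SyntheticStudy(
        records=records,
        network=network,
        truth=truth,
        block_signs=block_signs,
        config=config,
    )


def write_study(study: SyntheticStudy, directory) -> dict:
    """Write the study as plain-text fixture files.

    Emits drug-table CSV, fingerprint CSV, growth-curve CSV, edge-list CSV
    and truth JSON; returns the name -> path mapping.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "drugs": directory / "drugs.csv",
        "fingerprints": directory / "fingerprints.csv",
        "growth_curves": directory / "growth_curves.csv",
        "edges": directory / "edges.csv",
        "truth": directory / "truth.json",
    }
    io_formats.write_drug_table(study.records, paths["drugs"])
    io_formats.write_feature_vectors(
        {r.id: r.fingerprint for r in study.records}, paths["fingerprints"], prefix="bit"
    )
    io_formats.write_feature_vectors(
        {r.id: r.growth_curve for r in study.records}, paths["growth_curves"], prefix="t"
    )
    io_formats.write_ddi_edges(study.network, paths["edges"])
    io_formats.write_clustering(study.truth, paths["truth"])
    return paths


def read_study(directory) -> tuple:
    """Read back the fixture files written by :func:`write_study`.

    Returns ``(records, network, truth)``; the config is not serialized.
    """
    directory = Path(directory)
    records = io_formats.read_drug_table(directory / "drugs.csv")
    records = io_formats.attach_features(
        records,
        growth_curves=io_formats.read_feature_vectors(directory / "growth_curves.csv"),
        fingerprints=io_formats.read_feature_vectors(directory / "fingerprints.csv"),
    )
    network = io_formats.read_ddi_edges(directory / "edges.csv")
    truth = io_formats.read_clustering(directory / "truth.json")
    return records, network, truth
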