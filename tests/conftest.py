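import numpy as np
import pytest

from ddicluster.core import Clustering, DrugRecord, SignedDDINetwork, SimilarityMatrix


@pytest.fixture
def small_records():
    """Four drugs with all four feature modalities."""
    curve = np.array([0.1, 0.3, 0.7, 0.9, 1.0])
    return [
        DrugRecord(
            id="AMP", name="ampicillin", smiles="CC1(C)SC2C(NC(=O)Cc3ccccc3)C(=O)N2C1C(=O)O",
            moa_terms={"cell wall", "pbp"}, atc_codes=("J01CA01",),
            growth_curve=curve,
        ),
        DrugRecord(
            id="KAN", name="kanamycin", smiles="NCC1OC(OC2C(N)CC(N)C(O)C2O)C(N)CC1O",
            moa_terms={"30S ribosome"}, atc_codes=("J01GB04",),
            growth_curve=curve[::-1].copy(),
        ),
        DrugRecord(
            id="CIP", name="ciprofloxacin", smiles="OC(=O)c1cn(C2CC2)c2cc(N3CCNCC3)c(F)cc2c1=O",
            moa_terms={"gyrase"}, atc_codes=("J01MA02",),
            growth_curve=np.array([0.2, 0.2, 0.5, 0.8, 0.8]),
        ),
        DrugRecord(
            id="TET", name="tetracycline", smiles="CN(C)C1C(O)=C(C(N)=O)C(=O)C2(O)C(O)=C3C(=O)c4c(O)cccc4C(C)(O)C3CC12",
            moa_terms={"30S ribosome", "tetracycline pocket"}, atc_codes=("J01AA07",),
            growth_curve=np.array([0.9, 0.7, 0.4, 0.2, 0.1]),
        ),
    ]


@pytest.fixture
def toy_network():
    """Two 2-drug clusters: {a, b} synergy inside, {c, d} antagonism inside."""
    return SignedDDINetwork(
        ["a", "b", "c", "d"],
        {
            ("a", "b"): ("synergy", None),
            ("a", "c"): ("synergy", None),
            ("a", "d"): ("antagonism", None),
            ("b", "c"): ("synergy", None),
            ("c", "d"): ("antagonism", None),
        },
    )


@pytest.fixture
def toy_clustering():
    return Clustering({"a": 1, "b": 1, "c": 2, "d": 2})


def block_similarity(sizes, within=1.0, between=0.0, rng=None, jitter=0.0):
    """Planted-block similarity matrix over clusters of the given sizes."""
    n = sum(sizes)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    values = np.where(labels[:, None] == labels[None, :], within, between).astype(float)
    if rng is not None and jitter > 0:
        noise = rng.uniform(-jitter, jitter, size=(n, n))
        noise = (noise + noise.T) / 2
        values = np.clip(values + noise, 0.0, 1.0)
    np.fill_diagonal(values, 1.0)
    ids = [f"d{i:02d}" for i in range(n)]
    return SimilarityMatrix(ids, values), labels


@pytest.fixture
def blocks_2x4():
    sim, labels = block_similarity([4, 4])
    return sim, labels
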