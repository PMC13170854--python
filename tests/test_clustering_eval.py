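import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ddicluster.clustering_eval import (
    compare_clusterings,
    edge_purity,
    hierarchical_clustering,
    select_k,
    spectral_clustering,
)
from ddicluster.core import Clustering, SignedDDINetwork, SimilarityMatrix
from conftest import block_similarity


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def best_two_partition(sim: SimilarityMatrix):
    """Exhaustive search over all 2-partitions maximizing the within-cluster
    similarity sum."""
    n = sim.n
    best, best_labels = -np.inf, None
    for bits in range(1, 2 ** (n - 1)):
        labels = [(bits >> i) & 1 for i in range(n)]
        if len(set(labels)) < 2:
            continue
        score = sum(
            sim.values[i, j]
            for i, j in itertools.combinations(range(n), 2)
            if labels[i] == labels[j]
        )
        if score > best:
            best, best_labels = score, labels
    return Clustering.from_labels(sim.ids, best_labels)


def purity_oracle(network, clustering, classes):
    """Brute-force edge purity: enumerate all node pairs per cluster-pair
    block and count classes directly."""
    labels = sorted(set(clustering.assignment.values()))
    num = den = 0
    nodes = list(clustering.assignment)
    for g in labels:
        for h in labels:
            if g > h:
                continue
            counts = {}
            for a, b in itertools.combinations(nodes, 2):
                la, lb = sorted((clustering.label_of(a), clustering.label_of(b)))
                if (la, lb) != (g, h):
                    continue
                cls = network.edge_class(a, b)
                if cls in classes:
                    counts[cls] = counts.get(cls, 0) + 1
            if counts:
                num += max(counts.values())
                den += sum(counts.values())
    if den == 0:
        raise ValueError("undefined")
    return num / den


def random_case(seed, max_n=12):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, max_n + 1))
    ids = [f"n{i}" for i in range(n)]
    k = int(rng.integers(2, min(n, 5) + 1))
    labels = rng.integers(1, k + 1, n)
    labels[:k] = np.arange(1, k + 1)  # no empty cluster
    clustering = Clustering.from_labels(ids, labels)
    edges = {}
    classes = ("synergy", "additive", "antagonism")
    for i, j in itertools.combinations(range(n), 2):
        if rng.random() < 0.6:
            edges[(ids[i], ids[j])] = (classes[rng.integers(0, 3)], None)
    return SignedDDINetwork(ids, edges), clustering


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

class TestSpectral:
    def test_recovers_two_perfect_blocks_matching_exhaustive_search(self, blocks_2x4):
        sim, labels = blocks_2x4
        got = spectral_clustering(sim, 2, seed=0)
        oracle = best_two_partition(sim)
        assert got.same_partition(oracle)
        assert compare_clusterings(got, Clustering.from_labels(sim.ids, labels))[0] == 1.0

    def test_deterministic_given_seed(self, blocks_2x4):
        sim, _ = blocks_2x4
        a = spectral_clustering(sim, 2, seed=42)
        b = spectral_clustering(sim, 2, seed=42)
        assert a == b

    def test_permuting_rows_permutes_assignment(self):
        rng = np.random.default_rng(3)
        sim, _ = block_similarity([3, 3, 2], within=0.9, between=0.1, rng=rng, jitter=0.05)
        base = spectral_clustering(sim, 3, seed=0)
        perm = list(rng.permutation(sim.n))
        sim_p = sim.reorder([sim.ids[i] for i in perm])
        got = spectral_clustering(sim_p, 3, seed=0)
        assert got.same_partition(base)

    def test_k_out_of_range(self, blocks_2x4):
        sim, _ = blocks_2x4
        with pytest.raises(ValueError, match="out of range"):
            spectral_clustering(sim, 1, seed=0)
        with pytest.raises(ValueError, match="out of range"):
            spectral_clustering(sim, sim.n + 1, seed=0)

    def test_isolated_drug_advises_pruning(self):
        values = np.eye(3)
        values[0, 1] = values[1, 0] = 0.8
        sim = SimilarityMatrix(["a", "b", "c"], values)
        with pytest.raises(ValueError, match="prune isolated"):
            spectral_clustering(sim, 2, seed=0)


class TestHierarchical:
    @pytest.mark.parametrize("linkage", ["average", "complete", "single"])
    def test_recovers_two_perfect_blocks(self, blocks_2x4, linkage):
        sim, labels = blocks_2x4
        got = hierarchical_clustering(sim, 2, linkage=linkage)
        assert got.same_partition(best_two_partition(sim))

    def test_forced_extremes(self, blocks_2x4):
        sim, _ = blocks_2x4
        assert hierarchical_clustering(sim, sim.n).k == sim.n  # all singletons
        assert hierarchical_clustering(sim, 1).k == 1  # single cluster

    def test_k_out_of_range(self, blocks_2x4):
        sim, _ = blocks_2x4
        with pytest.raises(ValueError, match="out of range"):
            hierarchical_clustering(sim, 0)


class TestSelectK:
    def test_three_perfect_blocks_pick_three(self):
        sim, _ = block_similarity([3, 3, 3], within=0.95, between=0.05)
        k_best, diag = select_k(sim, 2, 6, seed=0)
        assert k_best == 3
        assert set(diag.columns) >= {"k", "silhouette", "eigengap"}

    def test_eigengap_maximal_at_two_blocks(self):
        sim, _ = block_similarity([4, 4], within=0.95, between=0.05)
        _, diag = select_k(sim, 2, 5, seed=0)
        gaps = diag.set_index("k")["eigengap"]
        assert gaps.idxmax() == 2

    def test_flat_similarity_warns(self, caplog):
        values = np.full((5, 5), 0.5)
        np.fill_diagonal(values, 1.0)
        sim = SimilarityMatrix(list("abcde"), values)
        with caplog.at_level("WARNING"):
            select_k(sim, 2, 4, seed=0)
        assert "no cluster count is preferred" in caplog.text

    def test_invalid_range(self, blocks_2x4):
        sim, _ = blocks_2x4
        with pytest.raises(ValueError, match="invalid k range"):
            select_k(sim, 5, 3, seed=0)


# ---------------------------------------------------------------------------
# Edge purity
# ---------------------------------------------------------------------------

class TestEdgePurity:
    def test_hand_enumerated_example(self, toy_network, toy_clustering):
        # blocks: (1,1) 1/1 syn; (1,2) max(2 syn, 1 ant)=2 of 3; (2,2) 1/1 ant
        res = edge_purity(toy_network, toy_clustering)
        assert res.purity == pytest.approx(4 / 5)
        assert res.counted_edges == 5
        assert res.profile.majority[(1, 1)] == "synergy"
        assert res.profile.majority[(2, 2)] == "antagonism"

    def test_single_class_network_is_pure(self):
        net = SignedDDINetwork(
            ["a", "b", "c"],
            {("a", "b"): ("synergy", None), ("b", "c"): ("synergy", None)},
        )
        c = Clustering({"a": 1, "b": 1, "c": 2})
        assert edge_purity(net, c).purity == 1.0

    def test_invariant_under_relabeling(self, toy_network, toy_clustering):
        swapped = Clustering({i: 3 - g for i, g in toy_clustering.assignment.items()})
        assert edge_purity(toy_network, swapped).purity == pytest.approx(
            edge_purity(toy_network, toy_clustering).purity
        )

    def test_matches_bruteforce_oracle_on_random_cases(self):
        classes = frozenset({"synergy", "antagonism"})
        checked = 0
        for seed in range(60):
            net, clustering = random_case(seed)
            try:
                expected = purity_oracle(net, clustering, classes)
            except ValueError:
                with pytest.raises(ValueError):
                    edge_purity(net, clustering, classes=classes)
                continue
            got = edge_purity(net, clustering, classes=classes)
            assert got.purity == pytest.approx(expected)
            assert got.purity >= 1 / len(classes)
            checked += 1
        assert checked > 30

    def test_additive_included_when_requested(self, toy_clustering):
        net = SignedDDINetwork(
            ["a", "b", "c", "d"],
            {("a", "b"): ("additive", None), ("c", "d"): ("additive", None)},
        )
        with pytest.raises(ValueError, match="undefined"):
            edge_purity(net, toy_clustering)
        res = edge_purity(net, toy_clustering, classes=("synergy", "additive", "antagonism"))
        assert res.purity == 1.0

    def test_macro_average_weights_blocks_equally(self, toy_network, toy_clustering):
        res = edge_purity(toy_network, toy_clustering, average="macro")
        assert res.purity == pytest.approx((1.0 + 2 / 3 + 1.0) / 3)

    def test_uncovered_endpoint_is_error(self, toy_network):
        partial = Clustering({"a": 1, "b": 2, "c": 2})
        with pytest.raises(ValueError, match="d"):
            edge_purity(toy_network, partial)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.integers(0, 2**30 - 1))
    def test_purity_invariant_under_node_reordering(self, seed):
        net, clustering = random_case(seed, max_n=8)
        try:
            base = edge_purity(net, clustering).purity
        except ValueError:
            return
        rng = np.random.default_rng(seed + 1)
        order = [net.node_ids[i] for i in rng.permutation(net.n)]
        reordered = SignedDDINetwork(order, net.edges)
        assert edge_purity(reordered, clustering).purity == pytest.approx(base)


class TestCompareClusterings:
    def test_identity_and_label_permutation(self, toy_clustering):
        ari, nmi, _ = compare_clusterings(toy_clustering, toy_clustering)
        assert ari == 1.0 and nmi == 1.0
        swapped = Clustering({i: 3 - g for i, g in toy_clustering.assignment.items()})
        assert compare_clusterings(toy_clustering, swapped)[0] == 1.0

    def test_crossed_partition_gives_minus_half(self):
        a = Clustering({"a": 1, "b": 1, "c": 2, "d": 2})
        b = Clustering({"a": 1, "b": 2, "c": 1, "d": 2})
        ari, _, table = compare_clusterings(a, b)
        assert ari == pytest.approx(-0.5)
        assert table.values.tolist() == [[1, 1], [1, 1]]

    def test_id_mismatch_lists_difference(self):
        a = Clustering({"a": 1, "b": 2})
        b = Clustering({"a": 1, "c": 2})
        with pytest.raises(ValueError, match="'b', 'c'"):
            compare_clusterings(a, b)
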