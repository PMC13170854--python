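import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ddicluster.core import Clustering, SimilarityMatrix
from ddicluster.ensemble import (
    ablation_study,
    co_association,
    consensus_from_coassociation,
    fuse_similarities,
)
from ddicluster.synthetic_data import SyntheticConfig, generate_study
from ddicluster.drug_similarity import compute_all_similarities
from conftest import block_similarity


class TestCoAssociation:
    def test_identical_partitions_give_indicator(self):
        p = Clustering({"a": 1, "b": 1, "c": 2, "d": 2})
        c = co_association([p, p])
        labels = p.labels_for(c.ids)
        expected = (labels[:, None] == labels[None, :]).astype(float)
        assert np.array_equal(c.values, expected)

    def test_hand_counted_two_partition_example(self):
        p1 = Clustering({"a": 1, "b": 1, "c": 2, "d": 2})
        p2 = Clustering({"a": 1, "b": 2, "c": 1, "d": 2})
        c = co_association([p1, p2])
        assert c.pair("a", "b") == 0.5
        assert c.pair("c", "d") == 0.5
        assert c.pair("a", "c") == 0.5
        assert c.pair("b", "d") == 0.5
        assert c.pair("a", "d") == 0.0
        assert c.pair("b", "c") == 0.0

    def test_single_partition_is_its_indicator(self):
        p = Clustering({"a": 1, "b": 2, "c": 1})
        c = co_association([p])
        assert c.pair("a", "c") == 1.0 and c.pair("a", "b") == 0.0

    def test_id_mismatch_is_error(self):
        with pytest.raises(ValueError, match="different ids"):
            co_association([Clustering({"a": 1, "b": 2}), Clustering({"a": 1, "c": 2})])

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.integers(0, 2**30 - 1), st.integers(1, 5))
    def test_entries_on_grid_and_label_permutation_invariant(self, seed, m):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        ids = [f"x{i}" for i in range(n)]
        parts = []
        for _ in range(m):
            k = int(rng.integers(2, n + 1))
            labels = np.concatenate([np.arange(1, k + 1), rng.integers(1, k + 1, n - k)])
            parts.append(Clustering.from_labels(ids, labels))
        c = co_association(parts)
        grid = np.round(c.values * m)
        assert np.allclose(c.values * m, grid)
        # relabeling any input partition leaves the matrix unchanged
        p0 = parts[0]
        relabeled = Clustering({i: p0.k + 1 - g for i, g in p0.assignment.items()})
        c2 = co_association([relabeled] + parts[1:])
        assert np.array_equal(c.values, c2.values)


class TestConsensus:
    def test_recovers_partition_from_indicator(self):
        p = Clustering({"a": 1, "b": 1, "c": 2, "d": 2, "e": 3, "f": 3})
        c = co_association([p, p])
        got = consensus_from_coassociation(c, 3)
        assert got.same_partition(p)

    def test_all_ones_matrix_single_cluster(self):
        c = co_association([Clustering({"a": 1, "b": 1, "c": 1})])
        assert consensus_from_coassociation(c, 1).k == 1

    def test_spectral_option_deterministic(self):
        p1 = Clustering({"a": 1, "b": 1, "c": 2, "d": 2})
        p2 = Clustering({"a": 1, "b": 1, "c": 2, "d": 2})
        c = co_association([p1, p2])
        a = consensus_from_coassociation(c, 2, method="spectral", seed=5)
        b = consensus_from_coassociation(c, 2, method="spectral", seed=5)
        assert a == b


class TestFusion:
    def test_mean_is_idempotent(self, blocks_2x4):
        s, _ = blocks_2x4
        fused = fuse_similarities([s, s], method="mean")
        assert np.allclose(fused.values, s.values)
        assert fused.kind == "fused"

    def test_mean_of_extremes_is_midpoint(self):
        n = 4
        ones = np.ones((n, n))
        zeros = np.eye(n)
        ids = list("abcd")
        fused = fuse_similarities(
            [SimilarityMatrix(ids, ones), SimilarityMatrix(ids, zeros)], method="mean"
        )
        off = ~np.eye(n, dtype=bool)
        assert np.allclose(fused.values[off], 0.5)

    def test_degenerate_weight_returns_first_matrix(self, blocks_2x4):
        s, _ = blocks_2x4
        rng = np.random.default_rng(0)
        other, _ = block_similarity([4, 4], within=0.7, between=0.2, rng=rng, jitter=0.1)
        other = SimilarityMatrix(s.ids, other.values)
        fused = fuse_similarities([s, other], method="weighted", weights=(1.0, 0.0))
        assert np.allclose(fused.values, s.values)

    def test_bad_weights_rejected(self, blocks_2x4):
        s, _ = blocks_2x4
        with pytest.raises(ValueError, match="weights"):
            fuse_similarities([s, s], method="weighted", weights=(0.7, 0.7))

    def test_id_mismatch_rejected(self, blocks_2x4):
        s, _ = blocks_2x4
        other, _ = block_similarity([2, 2])
        with pytest.raises(ValueError, match="id"):
            fuse_similarities([s, other])

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 2**30 - 1))
    def test_mean_bounded_by_elementwise_extremes(self, seed):
        rng = np.random.default_rng(seed)
        ids = [f"x{i}" for i in range(5)]
        mats = []
        for _ in range(3):
            v = rng.uniform(0, 1, (5, 5))
            v = (v + v.T) / 2
            np.fill_diagonal(v, 1.0)
            mats.append(SimilarityMatrix(ids, v))
        fused = fuse_similarities(mats, method="mean")
        stack = np.stack([m.values for m in mats])
        assert np.all(fused.values <= stack.max(axis=0) + 1e-12)
        assert np.all(fused.values >= stack.min(axis=0) - 1e-12)

    def test_diffusion_preserves_structure_and_invariants(self):
        rng = np.random.default_rng(4)
        a, labels = block_similarity([3, 3], within=0.9, between=0.1, rng=rng, jitter=0.05)
        b, _ = block_similarity([3, 3], within=0.8, between=0.2, rng=rng, jitter=0.05)
        b = SimilarityMatrix(a.ids, b.values)
        fused = fuse_similarities([a, b], method="diffusion", n_neighbors=3, n_iter=10)
        assert np.allclose(fused.values, fused.values.T)
        assert np.allclose(np.diag(fused.values), 1.0)
        assert fused.values.min() >= 0 and fused.values.max() <= 1
        # block structure survives diffusion
        same = labels[:, None] == labels[None, :]
        off = ~np.eye(6, dtype=bool)
        assert fused.values[same & off].mean() > fused.values[~same].mean()


class TestAblation:
    def test_table_has_row_per_source_plus_baseline(self):
        study = generate_study(SyntheticConfig(seed=0))
        sources = compute_all_similarities(study.records)
        table = ablation_study(sources, study.network, k=6, seed=0)
        assert len(table) == len(sources) + 1
        assert set(table["left_out"]) == set(sources) | {"none"}

    def test_fewer_than_three_sources_rejected(self, blocks_2x4, toy_network):
        s, _ = blocks_2x4
        with pytest.raises(ValueError, match="at least 3"):
            ablation_study({"a": s, "b": s}, toy_network, k=2)

    def test_dropping_a_noise_source_usually_helps_most(self):
        wins = 0
        trials = 15
        for seed in range(trials):
            study = generate_study(SyntheticConfig(
                seed=seed, epsilon=0.0,
                fp_flip=0.02, moa_mislabel=0.02, curve_sigma=0.02, atc_scramble=0.02,
            ))
            sources = compute_all_similarities(study.records)
            # replace one source by pure noise: permute ids against values
            rng = np.random.default_rng(seed)
            noisy = sources["structural"]
            perm = rng.permutation(noisy.n)
            sources["structural"] = SimilarityMatrix(
                noisy.ids, noisy.values[np.ix_(perm, perm)], kind="structural"
            )
            table = ablation_study(sources, study.network, k=6, seed=seed)
            rows = table[table["left_out"] != "none"]
            best = rows.loc[rows["edge_purity"].idxmax(), "left_out"]
            wins += best == "structural"
        assert wins > trials / 2
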