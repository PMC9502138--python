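"""Distances, embeddings, clustering, ARI and cluster summaries."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from litsim.analysis import (
    Partition,
    adjusted_rand_index,
    cluster_hierarchical,
    cluster_kmeans,
    distance_matrix,
    reduce_dimensions,
    suggest_k,
    top_terms_per_cluster,
)
from litsim.data_model import BinaryTermMatrix
from litsim.errors import ValidationError


def brute_force_ari(labels_a, labels_b) -> float:
    """Independent oracle: explicit enumeration of entity pairs classified
    as together/apart in each partition."""
    n = len(labels_a)
    n11 = n10 = n01 = n00 = 0
    for i, j in itertools.combinations(range(n), 2):
        same_a = labels_a[i] == labels_a[j]
        same_b = labels_b[i] == labels_b[j]
        if same_a and same_b:
            n11 += 1
        elif same_a:
            n10 += 1
        elif same_b:
            n01 += 1
        else:
            n00 += 1
    denom = (n11 + n10) * (n10 + n00) + (n11 + n01) * (n01 + n00)
    if denom == 0:
        return 1.0
    return 2.0 * (n11 * n00 - n10 * n01) / denom


def block_matrix():
    """Two blocks of identical rows: within-block distance 0, between 1."""
    rows = [[1, 1, 0, 0]] * 3 + [[0, 0, 1, 1]] * 3
    return BinaryTermMatrix([f"e{i}" for i in range(6)], list("abcd"), rows)


class TestDistanceMatrix:
    def test_jaccard_hand_computed(self):
        m = BinaryTermMatrix(["A", "B"], ["t1", "t2", "t3"], [[1, 1, 0], [0, 1, 1]])
        d = distance_matrix(m, "jaccard")
        assert d[0, 1] == pytest.approx(1 - 1 / 3)
        assert d[0, 0] == d[1, 1] == 0

    def test_identical_rows_distance_zero(self):
        m = BinaryTermMatrix(["A", "B"], ["t"], [[1], [1]])
        assert distance_matrix(m, "jaccard")[0, 1] == 0

    def test_disjoint_rows_distance_one(self):
        m = BinaryTermMatrix(["A", "B"], ["t1", "t2"], [[1, 0], [0, 1]])
        assert distance_matrix(m, "jaccard")[0, 1] == 1

    def test_all_zero_rows_defined_as_zero(self):
        m = BinaryTermMatrix(["A", "B", "C"], ["t"], [[0], [0], [1]])
        d = distance_matrix(m, "jaccard")
        assert d[0, 1] == 0

    def test_single_entity_rejected(self):
        m = BinaryTermMatrix(["A"], ["t"], [[1]])
        with pytest.raises(ValidationError):
            distance_matrix(m)


class TestReduceDimensions:
    def test_shape_contract(self):
        rng = np.random.default_rng(0)
        vals = (rng.random((10, 40)) < 0.3).astype(int)
        vals[:, vals.sum(axis=0) == 0] = 1
        m = BinaryTermMatrix([f"e{i}" for i in range(10)],
                             [f"t{i:02d}" for i in range(40)], vals)
        emb = reduce_dimensions(m, "pca", d=2)
        assert emb.coordinates.shape == (10, 2)

    def test_duplicate_rows_get_identical_pca_coordinates(self):
        m = block_matrix()
        emb = reduce_dimensions(m, "pca", d=2)
        np.testing.assert_allclose(emb.coordinates[0], emb.coordinates[1], atol=1e-12)

    def test_pca_scores_exact_on_two_point_case(self):
        m = BinaryTermMatrix(["A", "B"], ["t1", "t2"], [[1, 0], [0, 1]])
        emb = reduce_dimensions(m, "pca", d=1)
        scores = sorted(emb.coordinates[:, 0])
        assert scores == pytest.approx([-np.sqrt(0.5), np.sqrt(0.5)])

    def test_tsne_perplexity_validation(self):
        m = block_matrix()
        with pytest.raises(ValidationError, match="perplexity"):
            reduce_dimensions(m, "tsne", seed=0, perplexity=10)

    @pytest.mark.parametrize("method", ["tsne", "umap"])
    def test_stochastic_methods_reproducible_given_seed(self, method):
        m = block_matrix()
        a = reduce_dimensions(m, method, d=2, seed=3)
        b = reduce_dimensions(m, method, d=2, seed=3)
        np.testing.assert_array_equal(a.coordinates, b.coordinates)


class TestHierarchical:
    @pytest.mark.parametrize("linkage", ["ward", "average", "complete"])
    def test_two_ideal_blocks_recovered(self, linkage):
        m = block_matrix()
        d = distance_matrix(m)
        p = cluster_hierarchical(d, m.entity_ids, linkage=linkage, k=2)
        labels = p.relabelled()
        assert (labels[:3] == labels[0]).all()
        assert (labels[3:] == labels[3]).all()
        assert labels[0] != labels[3]

    def test_k_extremes(self):
        m = block_matrix()
        d = distance_matrix(m)
        assert len(set(cluster_hierarchical(d, m.entity_ids, k=1).labels)) == 1
        assert len(set(cluster_hierarchical(d, m.entity_ids, k=6).labels)) == 6

    def test_k_out_of_range(self):
        m = block_matrix()
        d = distance_matrix(m)
        with pytest.raises(ValidationError):
            cluster_hierarchical(d, m.entity_ids, k=0)

    def test_cuts_are_nested_refinements(self):
        rng = np.random.default_rng(7)
        vals = (rng.random((12, 30)) < 0.3).astype(int)
        vals[:, vals.sum(axis=0) == 0] = 1
        m = BinaryTermMatrix([f"e{i}" for i in range(12)],
                             [f"t{i:02d}" for i in range(30)], vals)
        d = distance_matrix(m)
        for k in range(2, 12):
            coarse = cluster_hierarchical(d, m.entity_ids, k=k - 1).labels
            fine = cluster_hierarchical(d, m.entity_ids, k=k).labels
            # every fine cluster maps into exactly one coarse cluster
            mapping = {}
            for f, c in zip(fine, coarse):
                assert mapping.setdefault(f, c) == c


class TestKMeans:
    def test_two_far_clouds_recovered(self):
        coords = np.array([[0.0, 0.0], [0.1, 0.0], [0.0, 0.1],
                           [10.0, 10.0], [10.1, 10.0], [10.0, 10.1]])
        from litsim.analysis import Embedding
        emb = Embedding([f"e{i}" for i in range(6)], coords, "pca")
        p = cluster_kmeans(emb, 2, seed=0)
        labels = p.relabelled()
        assert (labels[:3] == labels[0]).all() and (labels[3:] == labels[3]).all()
        assert labels[0] != labels[3]

    def test_k_equals_n_gives_singletons(self):
        from litsim.analysis import Embedding
        coords = np.arange(8, dtype=float).reshape(4, 2)
        emb = Embedding(list("abcd"), coords, "pca")
        p = cluster_kmeans(emb, 4, seed=0)
        assert len(set(p.labels)) == 4

    def test_same_seed_identical_labels(self):
        from litsim.analysis import Embedding
        rng = np.random.default_rng(5)
        emb = Embedding([f"e{i}" for i in range(20)], rng.random((20, 2)), "pca")
        assert cluster_kmeans(emb, 3, seed=9).labels == \
            cluster_kmeans(emb, 3, seed=9).labels


class TestAdjustedRandIndex:
    def ids(self, n):
        return [f"e{i}" for i in range(n)]

    def ari(self, a, b):
        n = len(a)
        return adjusted_rand_index(Partition(self.ids(n), list(a)),
                                   Partition(self.ids(n), list(b)))

    def test_label_permutation_invariance(self):
        assert self.ari([1, 1, 2, 2], [2, 2, 1, 1]) == 1.0

    def test_worked_example_exact(self):
        assert self.ari([1, 1, 2, 2], [1, 2, 1, 2]) == -0.5

    def test_identity(self):
        assert self.ari([1, 1, 2, 2], [1, 1, 2, 2]) == 1.0

    def test_degenerate_conventions(self):
        assert self.ari([1, 2, 3], [4, 5, 6]) == 1.0  # both all-singletons
        assert self.ari([1, 1, 1], [2, 2, 2]) == 1.0  # both one-cluster
        assert self.ari([1, 2, 3], [1, 1, 1]) == 0.0  # singletons vs one cluster

    def test_mismatched_entities_rejected(self):
        with pytest.raises(ValidationError):
            adjusted_rand_index(Partition(["a", "b"], [1, 2]),
                                Partition(["b", "a"], [1, 2]))

    def test_matches_brute_force_and_sklearn_on_random_pairs(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = int(rng.integers(2, 13))
            a = rng.integers(1, 5, size=n).tolist()
            b = rng.integers(1, 5, size=n).tolist()
            ours = self.ari(a, b)
            assert ours == pytest.approx(brute_force_ari(a, b), abs=1e-12)
            if len(set(a)) > 1 or len(set(b)) > 1:
                assert ours == pytest.approx(adjusted_rand_score(a, b), abs=1e-10)

    def test_chance_calibration_near_zero(self):
        rng = np.random.default_rng(2)
        fixed = [i % 5 for i in range(50)]
        ids = self.ids(50)
        p = Partition(ids, fixed)
        values = []
        for _ in range(1000):
            shuffled = list(fixed)
            rng.shuffle(shuffled)
            values.append(adjusted_rand_index(p, Partition(ids, shuffled)))
        assert -0.05 < np.mean(values) < 0.05


class TestTopTermsPerCluster:
    def test_within_cluster_presence_ranking(self):
        m = BinaryTermMatrix(["x", "y"], ["a", "b", "c"], [[1, 1, 0], [1, 0, 1]])
        p = Partition(["x", "y"], [0, 0])
        assert top_terms_per_cluster(m, p, n=1) == {0: ["a"]}

    def test_n_zero_gives_empty_lists(self):
        m = BinaryTermMatrix(["x", "y"], ["a"], [[1], [1]])
        p = Partition(["x", "y"], [0, 1])
        assert top_terms_per_cluster(m, p, n=0) == {0: [], 1: []}

    def test_singleton_cluster_lists_its_terms_lexicographically(self):
        m = BinaryTermMatrix(["x", "y"], ["b", "a", "c"], [[1, 1, 0], [0, 1, 1]])
        p = Partition(["x", "y"], [0, 1])
        assert top_terms_per_cluster(m, p, n=5)[0] == ["a", "b"]


class TestSuggestK:
    def test_two_ideal_blocks(self):
        d = distance_matrix(block_matrix())
        assert suggest_k(d, range(2, 5)) == 2

    def test_single_candidate(self):
        m = BinaryTermMatrix(["a", "b", "c"], ["t1", "t2", "t3"],
                             [[1, 0, 0], [0, 1, 0], [1, 1, 1]])
        d = distance_matrix(m)
        assert suggest_k(d, [2]) == 2

    def test_three_ideal_blocks(self):
        rows = [[1, 1, 0, 0, 0, 0]] * 3 + [[0, 0, 1, 1, 0, 0]] * 3 + \
               [[0, 0, 0, 0, 1, 1]] * 3
        m = BinaryTermMatrix([f"e{i}" for i in range(9)], list("abcdef"), rows)
        d = distance_matrix(m)
        assert suggest_k(d, range(2, 6)) == 3

    def test_empty_range_rejected(self):
        d = distance_matrix(block_matrix())
        with pytest.raises(ValidationError):
            suggest_k(d, [])
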