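import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from conftest import grid_clusters, two_blobs
from rscukit.cluster import (
    ClusterAssignment,
    agglomerative_cluster,
    consensus_k,
    dbscan_cluster,
    evaluate_clustering,
    heuristic_scan,
    kmeans_cluster,
    linkage_to_newick,
    select_best_method,
    spectral_cluster,
)


def _three_blobs(n_per=20, seed=0):
    rng = np.random.default_rng(seed)
    centers = np.array([[0.0, 0.0], [10.0, 0.0], [5.0, 10.0 * np.sqrt(3) / 2]])
    X = np.vstack(
        [rng.normal(0, 1, (n_per, 2)) + c for c in centers]
    )
    labels = np.repeat(np.arange(3), n_per)
    return X, labels


class TestHeuristics:
    def test_two_separated_clouds_all_agree(self):
        X, _ = two_blobs()
        report = heuristic_scan(X, seed=0)
        assert report.best_k["silhouette"] == 2
        assert report.best_k["calinski_harabasz"] == 2
        assert report.best_k["davies_bouldin"] == 2
        assert report.best_k["inertia_knee"] == 2
        assert report.consensus == 2

    def test_three_clouds_consensus(self):
        X, _ = _three_blobs()
        assert heuristic_scan(X, seed=0).consensus == 3

    def test_minimal_sample_count(self, rng):
        X = rng.normal(size=(3, 2))
        report = heuristic_scan(X, seed=0)
        assert report.k_range == (2,)
        assert report.consensus == 2

    def test_bad_k_range(self, rng):
        with pytest.raises(ValueError):
            heuristic_scan(rng.normal(size=(5, 2)), k_range=range(2, 10))


def _consensus_oracle(votes):
    """Independent restatement of the consensus rule for 4-tuples."""
    from collections import Counter

    counts = Counter(votes)
    top = counts.most_common(1)[0][1]
    if top >= 2:
        return min(v for v, c in counts.items() if c == top)
    return sorted(votes)[1]  # lower median of four values


class TestConsensusK:
    @pytest.mark.parametrize(
        "votes,expected",
        [((3, 3, 5, 2), 3), ((2, 3, 4, 6), 3), ((4, 4, 4, 4), 4), ((2, 2, 5, 5), 2)],
    )
    def test_examples(self, votes, expected):
        names = ["silhouette", "calinski_harabasz", "inertia_knee", "davies_bouldin"]
        assert consensus_k(dict(zip(names, votes))) == expected

    def test_matches_rule_oracle_on_all_tuples(self):
        """All 1,296 vote tuples over {2..6} agree with a brute-force oracle."""
        names = ["a", "b", "c", "d"]
        for votes in itertools.product(range(2, 7), repeat=4):
            assert consensus_k(dict(zip(names, votes))) == _consensus_oracle(votes)

    def test_failed_heuristic_abstains(self):
        assert consensus_k({"a": 2, "b": 2, "c": None, "d": 5}) == 2

    def test_all_failed_rejected(self):
        with pytest.raises(ValueError):
            consensus_k({"a": None})


class TestKMeans:
    def test_recovers_planted_clusters(self):
        X, truth = two_blobs()
        labels = kmeans_cluster(X, 2, seed=0).labels
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_deterministic_under_seed(self):
        X, _ = two_blobs(seed=3)
        a = kmeans_cluster(X, 2, seed=42).labels
        b = kmeans_cluster(X, 2, seed=42).labels
        pd.testing.assert_series_equal(a, b)

    def test_k_one_single_label(self):
        X, _ = two_blobs(n_per=5)
        assert kmeans_cluster(X, 1, seed=0).labels.nunique() == 1

    def test_small_subsample_falls_back(self, rng, caplog):
        X = rng.normal(size=(10, 2))  # 30% subsample = 3 < k = 4
        with caplog.at_level("WARNING"):
            assignment = kmeans_cluster(X, 4, seed=0)
        assert assignment.parameters["subsample"] == 10


class TestSpectral:
    def test_recovers_planted_clusters(self):
        X, truth = two_blobs()
        labels = spectral_cluster(X, 2, seed=0).labels
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_neighbor_floor_rule(self):
        X, _ = two_blobs(n_per=8)  # n = 16
        assert spectral_cluster(X, 2, seed=0).parameters["n_neighbors"] == 4

    def test_affinity_reported(self):
        X, _ = two_blobs()
        assert spectral_cluster(X, 2, seed=0).parameters["affinity"] in (
            "rbf",
            "nearest_neighbors",
        )

    def test_nonconvex_structure_recovered(self):
        """Two opposing arcs (non-convex, elongated clusters); the angular
        structure survives the method's internal row normalization."""
        rng = np.random.default_rng(0)
        arc = np.deg2rad(120)
        t1 = rng.uniform(0, arc, 60)
        t2 = rng.uniform(np.pi, np.pi + arc, 60)
        X = np.vstack(
            [np.c_[np.cos(t), np.sin(t)] * 5 for t in (t1, t2)]
        ) + rng.normal(0, 0.15, (120, 2))
        truth = np.r_[np.zeros(60), np.ones(60)]
        labels = spectral_cluster(X, 2, seed=0).labels
        assert adjusted_rand_score(truth, labels) >= 0.9


class TestDBSCAN:
    def test_min_samples_rule(self):
        X, _ = two_blobs()
        assert dbscan_cluster(X, dims=2).parameters["min_samples"] == 4

    def test_recovers_dense_clusters_and_flags_outliers(self):
        X, truth = grid_clusters()
        assignment = dbscan_cluster(X, dims=2)
        assert adjusted_rand_score(truth, assignment.labels) == 1.0
        noise = assignment.labels.to_numpy() == -1
        assert noise.sum() == 4 and (truth[noise] == -1).all()

    def test_all_noise_flagged_degenerate(self):
        X, _ = two_blobs()
        assignment = dbscan_cluster(X, dims=2, eps=1e-6)
        assert assignment.degenerate

    def test_too_few_samples(self, rng):
        with pytest.raises(ValueError):
            dbscan_cluster(rng.normal(size=(4, 2)), dims=2)


class TestAgglomerative:
    def test_recovers_planted_clusters(self):
        X, truth = two_blobs()
        labels = agglomerative_cluster(X, 2).labels
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_k_equals_n(self, rng):
        X = rng.normal(size=(6, 2))
        assert agglomerative_cluster(X, 6).labels.nunique() == 6

    def test_ward_merge_heights_monotone(self, rng):
        X = rng.normal(size=(20, 3))
        tree = agglomerative_cluster(X, 2).linkage_tree
        assert np.all(np.diff(tree[:, 2]) >= -1e-12)

    def test_newick_export(self, rng):
        X = rng.normal(size=(5, 2))
        tree = agglomerative_cluster(X, 2).linkage_tree
        nwk = linkage_to_newick(tree, [f"s{i}" for i in range(5)])
        assert nwk.endswith(";") and nwk.count("(") == 4
        for name in ("s0", "s4"):
            assert name in nwk


def _assignment(labels, method="kmeans"):
    return ClusterAssignment(
        method=method, parameters={}, labels=pd.Series(labels)
    )


class TestEvaluation:
    def test_perfect_agreement(self):
        ref = pd.Series([0, 0, 1, 1])
        ev = evaluate_clustering(_assignment([1, 1, 0, 0]), ref)
        for value in ev.as_dict().values():
            assert value == pytest.approx(1.0)

    def test_single_cluster_vs_balanced_reference(self):
        ref = pd.Series([0, 0, 1, 1])
        ev = evaluate_clustering(_assignment([0, 0, 0, 0]), ref)
        assert ev.homogeneity == pytest.approx(0.0)
        assert ev.completeness == pytest.approx(1.0)

    def test_random_labels_chance_corrected(self, rng):
        """Mean ARI of random labelings is ~0 (chance correction)."""
        ref = pd.Series(rng.integers(0, 3, 60))
        aris = [
            evaluate_clustering(
                _assignment(rng.permutation(ref.to_numpy())), ref
            ).ari
            for _ in range(100)
        ]
        assert abs(np.mean(aris)) <= 0.05

    def test_mismatched_samples_rejected(self):
        ref = pd.Series([0, 1], index=["a", "b"])
        with pytest.raises(ValueError):
            evaluate_clustering(_assignment([0, 1, 0]), ref)


class TestBestMethod:
    @staticmethod
    def _evals(scores):
        from rscukit.cluster import ClusterEvaluation

        return {
            method: {
                ref: ClusterEvaluation(method, ref, s, s, s, s, s)
                for ref, s in zip(("tissue_state", "stage"), pair)
            }
            for method, pair in scores.items()
        }

    def test_clear_winner(self):
        evals = self._evals(
            {"kmeans": (1.0, 1.0), "dbscan": (0.1, 0.1), "spectral": (0.2, 0.0)}
        )
        assert select_best_method(evals) == "kmeans"

    def test_tie_breaks_by_fixed_order(self):
        evals = self._evals({m: (0.5, 0.5) for m in ("dbscan", "kmeans", "agglomerative")})
        assert select_best_method(evals) == "agglomerative"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_best_method({})
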