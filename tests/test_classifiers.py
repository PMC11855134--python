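"""PNN / KNN / SVC against closed forms and independent brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from ploidyml.classifiers import (
    cosine_distance,
    knn_fit,
    knn_predict,
    pnn_fit,
    pnn_kernel,
    pnn_posterior,
    pnn_predict,
    select_k,
    select_sigma,
    svc_fit,
    svc_predict,
)
from ploidyml.classifiers.svm import rbf_kernel
from ploidyml.errors import DomainError
from ploidyml.preprocess import PloidyDataset


def _dataset(X, labels, classes=("diploid", "mixoploid", "tetraploid")):
    return PloidyDataset(np.asarray(X, float), np.asarray(labels, dtype=object),
                         classes=tuple(classes))


class TestPNNKernel:
    def test_zero_distance_is_one(self):
        assert pnn_kernel([1.0, 2.0], [1.0, 2.0], sigma=0.3) == 1.0

    def test_unit_distance_closed_form(self):
        val = pnn_kernel([0.0, 0.0], [1.0, 0.0], sigma=1.0)
        assert val == pytest.approx(math.exp(-0.5), abs=1e-12)

    def test_large_sigma_limit(self):
        assert pnn_kernel([0.0, 0.0], [5.0, 5.0], sigma=1e6) == pytest.approx(1.0)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(DomainError):
            pnn_kernel([0.0], [1.0], sigma=0.0)


class TestPNNPosterior:
    def test_six_point_fixture_matches_hand_summed_ratios(self):
        X = [[0.0, 0.0], [0.3, -0.2], [1.0, 1.0], [2.0, 2.0], [2.5, 1.5], [1.8, 2.2]]
        y = ["diploid"] * 3 + ["tetraploid"] * 3
        m = pnn_fit(_dataset(X, y, ("diploid", "tetraploid")), sigma=1.0)
        q = np.array([1.2, 0.7])
        # independent brute-force summation of the pattern layer
        sums = {"diploid": 0.0, "tetraploid": 0.0}
        for xi, label in zip(X, y):
            d2 = (q[0] - xi[0]) ** 2 + (q[1] - xi[1]) ** 2
            sums[label] += math.exp(-d2 / 2.0)
        expected = np.array(
            [sums["diploid"], sums["tetraploid"]]
        ) / (sums["diploid"] + sums["tetraploid"])
        assert pnn_posterior(m, q) == pytest.approx(expected, abs=1e-12)

    @settings(
        derandomize=True,
        max_examples=100,
        suppress_health_check=[HealthCheck.function_scoped_fixture],
    )
    @given(qx=st.floats(-5, 5), qy=st.floats(-5, 5), sigma=st.floats(0.05, 5))
    def test_posterior_is_a_simplex(self, three_cluster_dataset, qx, qy, sigma):
        m = pnn_fit(three_cluster_dataset, sigma=sigma)
        p = pnn_posterior(m, [qx, qy])
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(p >= 0)

    def test_small_sigma_converges_to_1nn(self):
        rng = np.random.default_rng(42)
        X = rng.standard_normal((30, 2))
        y = rng.choice(["diploid", "mixoploid", "tetraploid"], size=30)
        train = _dataset(X, y)
        m = pnn_fit(train, sigma=1e-3)
        queries = rng.standard_normal((50, 2))
        for q in queries:
            nearest = np.argmin(np.sum((X - q) ** 2, axis=1))
            assert pnn_predict(m, q) == y[nearest]

    def test_prediction_invariant_to_duplicated_training_set(self, three_cluster_dataset):
        d = three_cluster_dataset
        doubled = _dataset(np.vstack([d.X, d.X]), np.concatenate([d.y, d.y]))
        m1 = pnn_fit(d, sigma=0.7)
        m2 = pnn_fit(doubled, sigma=0.7)
        q = np.array([[5.0, 3.0], [12.0, 9.0], [-1.0, 2.0]])
        assert np.array_equal(pnn_predict(m1, q), pnn_predict(m2, q))
        assert pnn_posterior(m1, q) == pytest.approx(pnn_posterior(m2, q), abs=1e-12)

    def test_unweighted_sums_equal_classic_pnn_on_balanced_data(self, three_cluster_dataset):
        # with equal class counts the argmax of Sj equals the argmax of Sj/Nj
        d = three_cluster_dataset
        m = pnn_fit(d, sigma=0.9)
        rng = np.random.default_rng(0)
        for q in rng.uniform(-5, 25, size=(100, 2)):
            post = pnn_posterior(m, q)
            counts = np.array([np.sum(d.y == c) for c in d.classes])
            classic = post / counts
            assert d.classes[int(np.argmax(post))] == d.classes[int(np.argmax(classic))]

    def test_empty_class_rejected_at_fit(self):
        d = _dataset([[0, 0], [1, 1]], ["diploid", "diploid"])
        with pytest.raises(Exception):
            pnn_fit(d, sigma=1.0)


class TestSigmaSelection:
    def test_single_candidate_returned(self, three_cluster_dataset):
        assert select_sigma(three_cluster_dataset, [0.4]) == 0.4

    def test_separated_clusters_reach_perfect_loo(self, three_cluster_dataset):
        from ploidyml.classifiers.pnn import loo_accuracy_pnn

        sigma = select_sigma(three_cluster_dataset, [0.1, 0.5, 1.0])
        assert loo_accuracy_pnn(three_cluster_dataset, sigma) == 1.0

    def test_ties_break_toward_larger_sigma(self, three_cluster_dataset):
        # both candidates give LOO accuracy 1.0 on separated clusters
        assert select_sigma(three_cluster_dataset, [0.2, 0.4]) == 0.4

    def test_empty_grid_rejected(self, three_cluster_dataset):
        with pytest.raises(DomainError):
            select_sigma(three_cluster_dataset, [])


class TestCosineDistance:
    def test_identical_direction_is_zero(self):
        assert cosine_distance([2.0, 1.0], [4.0, 2.0]) == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_is_one(self):
        assert cosine_distance([1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.0)

    def test_45_degree_closed_form(self):
        assert cosine_distance([1.0, 1.0], [1.0, 0.0]) == pytest.approx(
            1.0 - 1.0 / math.sqrt(2), abs=1e-12
        )

    def test_zero_norm_rejected(self):
        with pytest.raises(DomainError):
            cosine_distance([0.0, 0.0], [1.0, 0.0])


class TestKNN:
    def test_k1_exact_training_point(self, three_cluster_dataset):
        d = three_cluster_dataset
        shifted = _dataset(d.X + 30.0, d.y)  # positive orthant for cosine
        m = knn_fit(shifted, k=1)
        for i in range(0, shifted.n, 5):
            assert knn_predict(m, shifted.X[i]) == shifted.y[i]

    def test_matches_brute_force_oracle_on_200_queries(self):
        rng = np.random.default_rng(99)
        X = rng.uniform(1, 10, size=(30, 2))
        y = rng.choice(["diploid", "mixoploid", "tetraploid"], size=30)
        m = knn_fit(_dataset(X, y), k=5)
        for q in rng.uniform(1, 10, size=(200, 2)):
            # independent full-sort oracle
            dists = [
                1 - (q @ xi) / (math.hypot(*q) * math.hypot(*xi)) for xi in X
            ]
            order = sorted(range(30), key=lambda i: dists[i])[:5]
            votes = {}
            for i in order:
                votes[y[i]] = votes.get(y[i], 0) + 1
            best = max(votes.values())
            tied = [c for c in ("diploid", "mixoploid", "tetraploid")
                    if votes.get(c, 0) == best]
            expected = tied[0] if len(tied) == 1 else y[order[0]]
            assert knn_predict(m, q) == expected

    def test_full_vote_tie_resolves_to_nearest_neighbor(self):
        X = [[1.0, 1.0], [2.0, 1.0], [1.0, 2.0], [3.0, 1.0], [1.0, 3.0], [2.0, 3.0]]
        y = ["diploid", "diploid", "mixoploid", "mixoploid", "tetraploid", "tetraploid"]
        d = _dataset(X, y)
        m = knn_fit(d, k=6)  # k = n_train on a balanced set: guaranteed vote tie
        q = np.array([2.0, 1.05])
        dists = [cosine_distance(q, xi) for xi in X]
        assert knn_predict(m, q) == y[int(np.argmin(dists))]


class TestKSelection:
    def test_single_candidate(self, three_cluster_dataset):
        d = three_cluster_dataset
        shifted = _dataset(d.X + 30.0, d.y)
        assert select_k(shifted, [3]) == 3

    def test_separated_clusters_pick_smallest_k(self, three_cluster_dataset):
        d = three_cluster_dataset
        shifted = _dataset(d.X + 30.0, d.y)
        # every small odd k gives LOO accuracy 1.0; the tie rule picks k = 1
        assert select_k(shifted, [1, 3, 5]) == 1

    def test_empty_candidates_rejected(self, three_cluster_dataset):
        with pytest.raises(DomainError):
            select_k(three_cluster_dataset, [])


class TestSVC:
    def test_separable_clusters_training_accuracy_one(self):
        rng = np.random.default_rng(3)
        X = np.vstack([
            rng.normal([-5, 0], 0.3, (10, 2)),
            rng.normal([5, 0], 0.3, (10, 2)),
        ])
        y = ["diploid"] * 10 + ["tetraploid"] * 10
        d = _dataset(X, y, ("diploid", "tetraploid"))
        m = svc_fit(d, C=1.0, gamma=0.5)
        assert np.all(svc_predict(m, X) == np.asarray(y, dtype=object))

    def test_dual_equality_constraint(self, three_cluster_dataset):
        m = svc_fit(three_cluster_dataset, C=1.0, gamma=0.5)
        for p in m.subproblems:
            assert abs(np.sum(p.alpha * p.y)) <= 1e-3
            assert np.all(p.alpha >= -1e-12) and np.all(p.alpha <= 1.0 + 1e-12)

    def test_decision_values_match_sklearn_oracle(self):
        sklearn_svm = pytest.importorskip("sklearn.svm")
        rng = np.random.default_rng(17)
        X = np.vstack([
            rng.normal([0, 0], 1.0, (12, 2)),
            rng.normal([2.5, 2.0], 1.0, (12, 2)),
        ])
        y = ["diploid"] * 12 + ["tetraploid"] * 12
        d = _dataset(X, y, ("diploid", "tetraploid"))
        C, gamma = 1.0, 0.5
        m = svc_fit(d, C=C, gamma=gamma)
        ours = m.subproblems[0].decision(X)
        ref = sklearn_svm.SVC(C=C, gamma=gamma, kernel="rbf").fit(
            X, [0 if v == "diploid" else 1 for v in y]
        )
        theirs = -ref.decision_function(X)  # their positive class is label 1
        assert np.max(np.abs(ours - theirs)) < 5e-2

    def test_multiclass_vote_covers_all_pairs(self, three_cluster_dataset):
        m = svc_fit(three_cluster_dataset, C=1.0, gamma=0.5)
        assert len(m.subproblems) == 3
        pred = svc_predict(m, three_cluster_dataset.X)
        assert np.all(pred == three_cluster_dataset.y)

    def test_invalid_hyperparameters_rejected(self, three_cluster_dataset):
        with pytest.raises(DomainError):
            svc_fit(three_cluster_dataset, C=-1.0)
        with pytest.raises(DomainError):
            svc_fit(three_cluster_dataset, C=1.0, gamma=0.0)


def test_all_classifiers_perfect_on_separated_clusters(three_cluster_dataset):
    d = three_cluster_dataset
    y = d.y
    pnn = pnn_fit(d, sigma=0.5)
    assert np.all(pnn_predict(pnn, d.X) == y)
    shifted = _dataset(d.X + 30.0, y)
    knn = knn_fit(shifted, k=3)
    assert np.all(knn_predict(knn, shifted.X) == y)
    svc = svc_fit(d, C=1.0, gamma=0.5)
    assert np.all(svc_predict(svc, d.X) == y)
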