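"""Normalization contracts, SVM behavior, RFE-CBR ranking, LOOCV structure."""

from __future__ import annotations

import numpy as np
import pytest
from sklearn.svm import SVC

from tractsvm import (
    loocv_classify,
    loocv_matrix,
    normalize_apply,
    normalize_fit,
    rfe_cbr,
    train_svm,
)
from tractsvm.classify import _fit_dual, default_gamma, rfe_delta_j_oracle

from conftest import make_blobs


class TestNormalization:
    def test_train_transform_is_zscore(self):
        rng = np.random.default_rng(0)
        X = rng.normal(3.0, 2.0, size=(20, 7))
        params = normalize_fit(X)
        Xn = normalize_apply(params, X)
        np.testing.assert_allclose(Xn.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(Xn.std(axis=0, ddof=1), 1.0, atol=1e-9)

    def test_two_row_hand_computation(self):
        # per-feature values {0, 2}: mean 1, sample SD sqrt(2)
        params = normalize_fit(np.array([[0.0, 0.0], [2.0, 2.0]]))
        np.testing.assert_allclose(params.means, [1.0, 1.0])
        np.testing.assert_allclose(params.sds, [np.sqrt(2.0)] * 2)

    def test_test_rows_use_training_statistics_only(self):
        train = np.array([[0.0], [2.0]])
        params = normalize_fit(train)
        test = np.array([[5.0]])
        np.testing.assert_allclose(
            normalize_apply(params, test), (5.0 - 1.0) / np.sqrt(2.0)
        )

    def test_roundtrip_inverse(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 4))
        params = normalize_fit(X)
        np.testing.assert_allclose(params.inverse(normalize_apply(params, X)), X, atol=1e-9)

    def test_not_idempotent_unless_already_standard(self):
        rng = np.random.default_rng(2)
        X = rng.normal(5.0, 3.0, size=(15, 3))
        params = normalize_fit(X)
        once = normalize_apply(params, X)
        twice = normalize_apply(params, once)
        assert not np.allclose(once, twice)

    def test_constant_feature_error_names_feature(self):
        X = np.ones((5, 3))
        X[:, 0] = np.arange(5)
        X[:, 2] = np.arange(5)
        with pytest.raises(ValueError, match="node-7"):
            normalize_fit(X, feature_names=["node-6", "node-7", "node-8"])

    def test_feature_mismatch_error(self):
        params = normalize_fit(np.random.default_rng(3).normal(size=(5, 3)))
        with pytest.raises(ValueError, match="feature mismatch"):
            normalize_apply(params, np.zeros((2, 4)))


class TestSvm:
    def test_separable_blobs_perfect_training_accuracy(self):
        X, y = make_blobs(40, d=6.0, seed=0)
        model = train_svm(X, y)
        assert (model.predict(X) == y).mean() == 1.0

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(ValueError, match="both classes"):
            train_svm(X, np.zeros(10, dtype=int))

    def test_duplicate_row_leaves_separable_boundary_unchanged(self):
        X, y = make_blobs(40, d=6.0, seed=1)
        gamma = default_gamma(X)
        m1 = train_svm(X, y, gamma=gamma)
        X2 = np.vstack([X, X[:1]])
        y2 = np.concatenate([y, y[:1]])
        m2 = train_svm(X2, y2, gamma=gamma)
        grid = np.random.default_rng(2).normal(size=(50, X.shape[1]))
        np.testing.assert_allclose(
            m1.decision_function(grid), m2.decision_function(grid), atol=1e-6
        )

    def test_permuted_labels_give_chance_level_loocv(self):
        # separable blobs with shuffled labels carry no class information:
        # mean LOOCV accuracy over permutations stays at or below chance
        # (leave-one-out is pessimistically biased under the null, since the
        # held-out label always opposes the training majority) and never
        # approaches the ~1.0 accuracy of the true labels
        rng = np.random.default_rng(5)
        X, y = make_blobs(30, d=6.0, seed=5)
        subjects = [f"s{i}" for i in range(30)]
        accs = []
        for _ in range(20):
            yp = rng.permutation(y)
            groups = np.where(yp == 1, "C", "NC").astype(object)
            res = loocv_matrix(X, groups, subjects, list(range(X.shape[1])), target_k=3)
            accs.append(res.accuracy)
        assert 0.2 <= np.mean(accs) <= 0.6

    def test_fast_dual_solver_matches_svc(self):
        """The low-level libsvm path must reproduce SVC's dual solution
        (up to overall sign, which the quadratic forms ignore)."""
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = int(rng.integers(12, 50))
            X = rng.normal(size=(n, 5))
            y = (rng.random(n) < 0.5).astype(int)
            if min(y.sum(), n - y.sum()) < 2:
                continue
            gamma = float(rng.uniform(0.01, 1.0))
            K = np.exp(-gamma * ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
            svc = SVC(C=1.0, kernel="precomputed").fit(K, y)
            a_ref = np.zeros(n)
            a_ref[svc.support_] = svc.dual_coef_[0]
            a_fast = _fit_dual(K, y, 1.0)
            assert np.allclose(np.abs(a_fast), np.abs(a_ref), atol=1e-6)
            assert np.isclose(a_fast @ K @ a_fast, a_ref @ K @ a_ref, atol=1e-6)


class TestRfe:
    def test_no_elimination_when_under_target(self):
        X, y = make_blobs(20, d=1.0, n_features=6, seed=0)
        res = rfe_cbr(X, y, target_k=10)
        assert res.selected == list(range(6))
        assert res.elimination_order == []

    def test_result_is_duplicate_free_subset_of_correct_size(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 25))
        y = (rng.random(30) < 0.5).astype(int)
        res = rfe_cbr(X, y, target_k=10)
        assert len(res.selected) == 10
        assert len(set(res.selected)) == 10
        assert set(res.selected) <= set(range(25))
        assert sorted(res.elimination_order + res.selected) == list(range(25))

    def test_signal_features_survive_elimination(self):
        """Two d=2 signal features among 10 noise features are retained in
        the selected 10 in at least 95 percent of cohorts."""
        hits = 0
        reps = 100
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(60, 12))
            y = np.zeros(60, dtype=int)
            y[:30] = 1
            X[y == 1, :2] += 2.0
            Xn = (X - X.mean(0)) / X.std(0, ddof=1)
            res = rfe_cbr(Xn, y, target_k=10)
            hits += {0, 1} <= set(res.selected)
        assert hits / reps >= 0.95

    def test_single_step_matches_exhaustive_oracle(self):
        """First eliminated feature equals the argmin of independently
        recomputed single-feature-removal dJ scores."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            X = rng.normal(size=(30, 6))
            y = np.zeros(30, dtype=int)
            y[:15] = 1
            X[y == 1, 0] += rng.uniform(0.5, 1.5)
            Xn = (X - X.mean(0)) / X.std(0, ddof=1)
            gamma = default_gamma(Xn)
            res = rfe_cbr(Xn, y, target_k=5, gamma=gamma, use_cbr=False)
            scores = rfe_delta_j_oracle(Xn, y, gamma=gamma)
            ties = np.nonzero(scores == scores.min())[0]
            assert res.elimination_order[0] == ties.max()

    def test_cbr_retains_correlated_signal_pair(self):
        """A duplicated strong-signal pair (|r| > 0.9) survives group-aware
        scoring; plain RFE would underrate each member separately."""
        kept = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            n = 60
            y = np.zeros(n, dtype=int)
            y[:30] = 1
            signal = rng.normal(size=n) + 2.0 * y
            near_dup = signal + rng.normal(0, 0.1, n)
            noise = rng.normal(size=(n, 6))
            X = np.column_stack([signal, near_dup, noise])
            Xn = (X - X.mean(0)) / X.std(0, ddof=1)
            res = rfe_cbr(Xn, y, target_k=2, corr_threshold=0.9, use_cbr=True)
            kept += set(res.selected) == {0, 1}
        assert kept >= 16


class TestLoocv:
    def test_each_subject_left_out_exactly_once(self, small_effect_cohort):
        res = loocv_classify(small_effect_cohort, "left_ilf", "MD", target_k=4)
        assert res.n == small_effect_cohort.n_subjects
        assert sorted(fr.left_out_subject for fr in res.fold_records) == sorted(
            small_effect_cohort.subjects
        )
        for fr in res.fold_records:
            assert len(fr.selected_nodes) == 4

    def test_deterministic_rerun(self, small_effect_cohort):
        r1 = loocv_classify(small_effect_cohort, "left_ilf", "MD", target_k=4)
        r2 = loocv_classify(small_effect_cohort, "left_ilf", "MD", target_k=4)
        assert [fr.predicted_label for fr in r1.fold_records] == [
            fr.predicted_label for fr in r2.fold_records
        ]
        assert [fr.selected_nodes for fr in r1.fold_records] == [
            fr.selected_nodes for fr in r2.fold_records
        ]
        np.testing.assert_array_equal(
            [fr.decision_score for fr in r1.fold_records],
            [fr.decision_score for fr in r2.fold_records],
        )

    def test_held_out_subject_cannot_influence_training_artifacts(self, small_effect_cohort):
        """Perturbing the held-out subject's profile must leave that fold's
        node selection unchanged (no leakage into normalization or RFE)."""
        import copy

        cohort_a = small_effect_cohort
        cohort_b = copy.deepcopy(cohort_a)
        j = 3
        cohort_b.data[("left_ilf", "MD")][j] += 0.5  # drastic perturbation
        ra = loocv_classify(cohort_a, "left_ilf", "MD", target_k=4)
        rb = loocv_classify(cohort_b, "left_ilf", "MD", target_k=4)
        assert ra.fold_records[j].selected_nodes == rb.fold_records[j].selected_nodes

    def test_strong_localized_effect_detected(self, small_effect_cohort):
        res = loocv_classify(small_effect_cohort, "left_ilf", "MD", target_k=4)
        assert res.accuracy >= 0.7
        assert res.auc >= 0.75
        # selected nodes concentrate on the implanted region (nodes 4-6)
        from tractsvm import selection_histogram

        hist = selection_histogram(res, small_effect_cohort.n_nodes)
        top4 = hist.top_nodes(4)
        assert len(set(top4) & {3, 4, 5, 6, 7}) >= 2

    def test_class_with_single_member_rejected(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(5, 6))
        groups = np.array(["C", "NC", "NC", "NC", "NC"], dtype=object)
        with pytest.raises(ValueError, match="2 subjects per class"):
            loocv_matrix(X, groups, [f"s{i}" for i in range(5)], list(range(6)))
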