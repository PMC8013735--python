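"""Elastic-net path, nested CV classification, feature grouping."""

import warnings

import numpy as np
import pytest

from dfcstates import (
    ClassificationDataset,
    build_state_dataset,
    enr_path,
    group_difference_test,
    group_top_features,
    nested_cv_classify,
)
from dfcstates.clustering import StateSequence
from dfcstates.windows import DFCSeries


def make_dataset(rng, n_per=30, p=21, effect=0.0, state_id=1):
    """Two-group Gaussian dataset with an optional planted mean shift on the
    first feature."""
    x_hc = rng.standard_normal((n_per, p))
    x_sz = rng.standard_normal((n_per, p))
    x_sz[:, 0] += effect
    x = np.vstack([x_hc, x_sz])
    y = np.repeat([0, 1], n_per)
    ids = [f"s{i:03d}" for i in range(2 * n_per)]
    return ClassificationDataset(state_id, x, y, ids, "subject-median",
                                 [f"C{i+1}" for i in range(p)])


class TestENRPath:
    def test_full_shrinkage_at_largest_lambda(self, rng):
        x = rng.standard_normal((60, 21))
        y = rng.integers(0, 2, 60)
        path = enr_path(x, y)
        assert len(path.lambda_grid) == 100
        assert path.lambda_grid[0] == pytest.approx(1e-5)
        assert path.lambda_grid[-1] == pytest.approx(1e5)
        assert np.all(path.coefficients[-1] == 0.0)
        assert not path.retained[-1].any()

    def test_ridge_keeps_all_coefficients_nonzero(self, rng):
        x = rng.standard_normal((80, 10))
        beta = rng.standard_normal(10)
        y = (x @ beta + 0.5 * rng.standard_normal(80) > 0).astype(int)
        path = enr_path(x, y, alpha=0.0)
        mid = np.searchsorted(path.lambda_grid, 1e-2)
        assert np.all(path.coefficients[mid] != 0.0)

    def test_matches_sklearn_saga(self, rng):
        """Independent cross-check of the coordinate-descent path against
        scikit-learn's saga elastic-net logistic regression."""
        from sklearn.linear_model import LogisticRegression
        n, p = 60, 8
        x = rng.standard_normal((n, p))
        x = (x - x.mean(0)) / x.std(0)
        beta = np.zeros(p)
        beta[:2] = [1.5, -1.0]
        y = (rng.random(n) < 1 / (1 + np.exp(-(x @ beta)))).astype(int)
        path = enr_path(x, y, alpha=0.5)
        for li in [45, 55, 60, 70]:
            lam = path.lambda_grid[li]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clf = LogisticRegression(
                    penalty="elasticnet", solver="saga", l1_ratio=0.5,
                    C=1.0 / (n * lam), max_iter=200_000, tol=1e-10)
                clf.fit(x, y)
            np.testing.assert_allclose(path.coefficients[li], clf.coef_[0],
                                       atol=2e-3)

    @pytest.mark.parametrize("seed", range(20))
    def test_signal_feature_retained_above_noise(self, seed):
        """One strongly separating feature out-retains every noise feature
        across the full regularization sweep."""
        rng = np.random.default_rng(seed)
        n = 400
        x = rng.standard_normal((n, 21))
        y = rng.integers(0, 2, n)
        x[:, 0] += 2.0 * (2 * y - 1)  # strong class separation on feature 0
        x = (x - x.mean(0)) / x.std(0)
        path = enr_path(x, y)
        retention = path.retained.mean(axis=0)
        assert np.all(retention[0] > retention[1:])


class TestBuildStateDataset:
    def _toy(self, n_windows=6):
        rng = np.random.default_rng(0)
        dfc, seqs, labels = [], [], {}
        for i in range(6):
            sid = f"s{i}"
            feats = rng.standard_normal((n_windows, 3))
            dfc.append(DFCSeries(sid, feats, [("a", "b"), ("a", "c"), ("b", "c")]))
            labels[sid] = "SZ" if i % 2 else "HC"
        return dfc, labels

    def test_subject_median_row(self):
        dfc, labels = self._toy(3)
        dfc[0].features[:, 0] = [1.0, 2.0, 9.0]
        seqs = [StateSequence(d.subject_id, np.ones(3, dtype=int)) for d in dfc]
        ds = build_state_dataset(dfc, seqs, 1, labels)
        assert ds.X[0, 0] == 2.0  # median of {1, 2, 9}

    def test_subject_without_state_excluded_and_listed(self):
        dfc, labels = self._toy(4)
        seqs = [StateSequence(d.subject_id, np.ones(4, dtype=int)) for d in dfc]
        seqs[2] = StateSequence(dfc[2].subject_id, np.full(4, 2, dtype=int))
        ds = build_state_dataset(dfc, seqs, 1, labels)
        assert dfc[2].subject_id in ds.excluded_subjects
        assert len(ds.X) == 5

    def test_window_mode_row_count_matches_recount(self):
        dfc, labels = self._toy(8)
        rng = np.random.default_rng(5)
        seqs = [StateSequence(d.subject_id, rng.integers(1, 4, 8)) for d in dfc]
        ds = build_state_dataset(dfc, seqs, 2, labels, sample_unit="window")
        expected = sum(int(np.sum(s.states == 2)) for s in seqs)
        assert len(ds.X) == expected

    def test_absent_class_rejected(self):
        dfc, labels = self._toy(4)
        labels = {k: "HC" for k in labels}
        seqs = [StateSequence(d.subject_id, np.ones(4, dtype=int)) for d in dfc]
        with pytest.raises(ValueError, match="class is absent"):
            build_state_dataset(dfc, seqs, 1, labels)


class TestNestedCV:
    def test_separable_contrast_has_high_auc(self):
        rng = np.random.default_rng(0)
        ds = make_dataset(rng, n_per=40, effect=4.0)
        rep = nested_cv_classify(ds, seed=0)
        assert rep.auc >= 0.95
        assert len(rep.lambda_selected) == 10

    def test_null_labels_give_chance_auc(self):
        aucs = []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            ds = make_dataset(rng, n_per=30, effect=0.0)
            aucs.append(nested_cv_classify(ds, seed=seed).auc)
        assert abs(np.mean(aucs) - 0.5) < 0.15

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(7)
        ds = make_dataset(rng, n_per=25, effect=1.0)
        a = nested_cv_classify(ds, seed=3)
        b = nested_cv_classify(ds, seed=3)
        assert a.auc == b.auc
        np.testing.assert_array_equal(a.importance_per_fold, b.importance_per_fold)

    def test_window_mode_groups_subjects(self):
        """With repeated subject ids, no subject appears in both the train
        and test side of any fold (asserted inside the CV loop)."""
        rng = np.random.default_rng(11)
        n_subj, win_per = 24, 5
        x = np.repeat(rng.standard_normal((n_subj, 4)), win_per, axis=0)
        x = x + 0.1 * rng.standard_normal(x.shape)
        y = np.repeat(rng.permutation(np.repeat([0, 1], n_subj // 2)), win_per)
        ids = [f"s{i}" for i in range(n_subj) for _ in range(win_per)]
        ds = ClassificationDataset(1, x, y, ids, "window",
                                   [f"C{i+1}" for i in range(4)])
        rep = nested_cv_classify(ds, seed=1)
        assert 0.0 <= rep.auc <= 1.0

    def test_too_small_class_rejected(self):
        rng = np.random.default_rng(2)
        ds = make_dataset(rng, n_per=5)
        with pytest.raises(ValueError, match="10"):
            nested_cv_classify(ds, seed=0)

    def test_retention_importance_in_unit_interval(self):
        rng = np.random.default_rng(8)
        ds = make_dataset(rng, n_per=20, effect=1.5)
        rep = nested_cv_classify(ds, seed=5)
        assert np.all((rep.importance >= 0) & (rep.importance <= 1))


class TestGroupTopFeatures:
    def test_identical_retention_returns_all(self):
        imp = np.full((5, 21), 0.4)
        with pytest.warns(UserWarning, match="zero variance"):
            top = group_top_features(imp)
        assert top == list(range(21))

    def test_single_dominant_feature(self):
        imp = np.zeros((6, 21))
        imp[:, 7] = 1.0
        assert group_top_features(imp) == [7]

    @pytest.mark.parametrize("seed", range(20))
    def test_planted_two_tier_structure(self, seed):
        """An upper tier of features separated from the rest by far more
        than fold noise is returned exactly."""
        rng = np.random.default_rng(seed)
        folds, p = 10, 21
        upper = [2, 5, 11]
        imp = 0.2 + 0.01 * rng.standard_normal((folds, p))
        imp[:, upper] = 0.9 + 0.01 * rng.standard_normal((folds, len(upper)))
        assert group_top_features(imp) == upper


class TestGroupDifference:
    def test_single_feature_q_equals_p(self, rng):
        ds = make_dataset(rng, n_per=20, effect=1.0)
        out = group_difference_test(ds, [0])
        assert out["q"].iloc[0] == out["p"].iloc[0]

    def test_planted_elevation_detected_with_direction(self):
        rng = np.random.default_rng(0)
        ds = make_dataset(rng, n_per=150, effect=0.6)
        out = group_difference_test(ds, [0, 1, 2])
        row = out[out["feature_idx"] == 0].iloc[0]
        assert row["direction"] < 0  # SZ > HC
        assert row["q"] < 0.05

    def test_null_type_one_error_controlled(self):
        """Fraction of null replicates with any q < 0.05 stays within the
        binomial envelope of the nominal BH level."""
        rng = np.random.default_rng(42)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            ds = make_dataset(rng, n_per=25, effect=0.0)
            out = group_difference_test(ds, list(range(21)))
            hits += (out["q"] < 0.05).any()
        # one-sided 95% binomial bound for a true rate of 0.05 at n=200
        assert hits <= 16

    def test_constant_feature_p_one(self, rng):
        ds = make_dataset(rng, n_per=15)
        ds.X[:, 3] = 2.0
        out = group_difference_test(ds, [3])
        assert out["p"].iloc[0] == 1.0
        assert "constant" in out["note"].iloc[0]
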