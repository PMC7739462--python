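"""Scaling, the RBF-SVM estimator, the AdaBoost baseline, metrics and
the cross-validation harness."""

import math

import numpy as np
import pytest
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

import oxisleep as ox
from oxisleep.classify import (
    ConfusionCounts,
    apply_scaler,
    compute_metrics,
    cross_validate,
    cv_splits,
    fit_scaler,
)
from oxisleep.errors import FormatError, StateError, TrainingError


class TestScaler:
    def test_column_maps_to_unit_interval(self):
        X = np.array([[2.0], [4.0], [6.0]])
        params = fit_scaler(X)
        np.testing.assert_allclose(apply_scaler(params, X)[:, 0], [0, 0.5, 1])

    def test_constant_column_maps_to_zero(self):
        X = np.array([[5.0], [5.0], [5.0]])
        out = apply_scaler(fit_scaler(X), X)
        np.testing.assert_array_equal(out, np.zeros((3, 1)))

    def test_out_of_range_test_value_not_clipped(self):
        params = fit_scaler(np.array([[2.0], [6.0]]))
        assert apply_scaler(params, np.array([[8.0]]))[0, 0] == pytest.approx(1.5)

    def test_unfitted_scaler_is_a_state_error(self):
        with pytest.raises(StateError):
            apply_scaler(None, np.zeros((2, 3)))

    def test_matches_sklearn_minmax_on_training_data(self, rng):
        X = rng.normal(size=(40, 6))
        X[:, 3] = 7.0  # constant column
        ours = apply_scaler(fit_scaler(X), X)
        theirs = MinMaxScaler().fit_transform(X)
        np.testing.assert_allclose(ours, theirs, atol=1e-12)


class TestSVMEstimator:
    def test_separable_pair_is_classified_correctly(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        y = np.array([ox.LABEL_APNEA, ox.LABEL_NORMAL])
        model = ox.SpO2SVMClassifier().fit(X, y)
        np.testing.assert_array_equal(model.predict(X), y)

    def test_xor_pattern_needs_and_gets_nonlinear_separation(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        y = np.array([1, 1, -1, -1])
        model = ox.SpO2SVMClassifier().fit(X, y)
        np.testing.assert_array_equal(model.predict(X), y)

    def test_training_is_deterministic(self, default_dataset):
        X, y = default_dataset
        h1 = ox.SpO2SVMClassifier().fit(X, y).decision_function(X)
        h2 = ox.SpO2SVMClassifier().fit(X, y).decision_function(X)
        np.testing.assert_allclose(h1, h2, atol=1e-9)

    def test_single_class_input_rejected(self):
        X = np.zeros((5, 10))
        with pytest.raises(TrainingError):
            ox.SpO2SVMClassifier().fit(X, np.ones(5))

    def test_decision_function_matches_sklearn_svc(self, rng):
        # independent route: scale by hand, fit sklearn's SVC directly
        X = rng.normal(size=(80, 10))
        y = np.where(X[:, 0] + 0.3 * rng.normal(size=80) > 0, 1, -1)
        if len(np.unique(y)) < 2:
            pytest.skip("degenerate draw")
        model = ox.SpO2SVMClassifier(C=1000, sigma=5).fit(X, y)
        Xs = apply_scaler(fit_scaler(X), X)
        ref = SVC(C=1000, kernel="rbf", gamma=1 / 50).fit(Xs, y)
        np.testing.assert_allclose(
            model.decision_function(X), ref.decision_function(Xs), atol=1e-10
        )

    def test_tie_at_zero_predicts_normal(self):
        # hand-built model with h(x) = 1*k(sv, x) - 1, so h(sv) = 0 exactly
        model = ox.SpO2SVMClassifier.from_dict(
            {
                "C": 1000.0,
                "sigma": 5.0,
                "classes": [ox.LABEL_APNEA, ox.LABEL_NORMAL],
                "scaler": {"data_min": [0.0, 0.0], "data_max": [1.0, 1.0]},
                "support_vectors": [[0.5, 0.5]],
                "dual_coef": [1.0],
                "intercept": -1.0,
            }
        )
        x = np.array([[0.5, 0.5]])
        assert model.decision_function(x)[0] == 0.0
        assert model.predict(x)[0] == ox.LABEL_NORMAL

    def test_wrong_column_count_is_a_shape_error(self, small_model):
        with pytest.raises(FormatError):
            small_model.predict(np.zeros((3, 7)))

    def test_predict_is_pure(self, small_model, default_dataset):
        X, _ = default_dataset
        np.testing.assert_array_equal(
            small_model.predict(X[:50]), small_model.predict(X[:50])
        )

    def test_sklearn_params_protocol(self):
        est = ox.SpO2SVMClassifier(C=10, sigma=2)
        assert est.get_params() == {"C": 10, "sigma": 2}
        est.set_params(C=500)
        assert est.C == 500


class TestMetrics:
    def test_direct_ratios(self):
        sens, spec, acc = compute_metrics(ConfusionCounts(tp=5, fn=5, tn=0, fp=0))
        assert sens == 0.5

    def test_hand_computed_table(self):
        sens, spec, acc = compute_metrics(ConfusionCounts(tp=10, fn=0, tn=9, fp=1))
        assert (sens, spec, acc) == (1.0, 0.9, 0.95)

    def test_zero_denominator_yields_nan_marker(self):
        sens, spec, acc = compute_metrics(ConfusionCounts(tp=0, fn=0, tn=3, fp=1))
        assert math.isnan(sens) and spec == 0.75

    def test_counts_from_labels_apnea_positive(self):
        y_true = [ox.LABEL_APNEA, ox.LABEL_APNEA, ox.LABEL_NORMAL, ox.LABEL_NORMAL]
        y_pred = [ox.LABEL_APNEA, ox.LABEL_NORMAL, ox.LABEL_NORMAL, ox.LABEL_APNEA]
        c = ConfusionCounts.from_labels(y_true, y_pred)
        assert (c.tp, c.fn, c.tn, c.fp) == (1, 1, 1, 1)
        assert c.p == 2 and c.n == 2


class TestCrossValidation:
    def test_folds_partition_the_data(self, default_dataset):
        X, y = default_dataset
        splits = cv_splits(y, folds=10, seed=0)
        tested = np.concatenate([test for _, test in splits])
        assert sorted(tested.tolist()) == list(range(len(y)))

    def test_same_seed_identical_report(self, default_dataset):
        X, y = default_dataset
        r1 = cross_validate(X[:200], y[:200], folds=5, seed=3)
        r2 = cross_validate(X[:200], y[:200], folds=5, seed=3)
        assert r1.to_dict() == r2.to_dict()

    def test_pooled_counts_sum_fold_counts(self, default_dataset):
        X, y = default_dataset
        rep = cross_validate(X[:300], y[:300], folds=5, seed=1)
        total = sum(rep.fold_counts, ConfusionCounts())
        assert rep.pooled.to_dict() == total.to_dict()
        assert rep.pooled.p + rep.pooled.n == 300

    def test_class_smaller_than_folds_suggests_fewer_folds(self):
        X = np.zeros((12, 10))
        y = np.array([1] * 9 + [-1] * 3)
        with pytest.raises(TrainingError, match="fewer folds"):
            cross_validate(X, y, folds=5, seed=0)

    def test_grouped_folds_keep_records_together(self, default_dataset):
        X, y = default_dataset
        groups = np.arange(len(y)) // 50  # 20 pseudo-records
        _, splits, _ = cross_validate(
            X, y, folds=5, seed=0, groups=groups, return_models=True
        )
        for train_idx, test_idx in splits:
            assert not set(groups[train_idx]) & set(groups[test_idx])

    def test_shuffled_labels_stay_near_chance(self, default_dataset):
        # no memorisation of 10-feature noise at n=1000: accuracy on
        # label-shuffled data stays near the majority-class rate
        X, y = default_dataset
        rng = np.random.default_rng(0)
        rep = cross_validate(X, rng.permutation(y), folds=10, seed=0)
        assert 0.45 <= rep.accuracy <= 0.65

    def test_accuracy_identity_on_report(self, default_dataset):
        X, y = default_dataset
        rep = cross_validate(X[:300], y[:300], folds=5, seed=2)
        c = rep.pooled
        assert rep.accuracy == pytest.approx(
            (rep.sensitivity * c.p + rep.specificity * c.n) / (c.p + c.n), abs=1e-12
        )


class TestAdaBoostBaseline:
    def test_single_stump_solves_threshold_problem(self):
        X = np.linspace(0, 1, 20).reshape(-1, 1)
        y = np.where(X[:, 0] > 0.5, 1, -1)
        model = ox.AdaBoostBaseline(n_estimators=1, random_state=0).fit(X, y)
        np.testing.assert_array_equal(model.predict(X), y)

    def test_report_schema_matches_svm_report(self, default_dataset):
        X, y = default_dataset
        svm_rep = cross_validate(X[:200], y[:200], folds=5, seed=0)
        ada_rep = cross_validate(
            X[:200], y[:200], ox.AdaBoostBaseline(random_state=0), folds=5, seed=0
        )
        assert set(svm_rep.to_dict()) == set(ada_rep.to_dict())
        assert ada_rep.classifier == "AdaBoostBaseline"

    def test_fixed_seed_reproducible(self, default_dataset):
        X, y = default_dataset
        r1 = cross_validate(X[:200], y[:200], ox.AdaBoostBaseline(random_state=5),
                            folds=5, seed=5)
        r2 = cross_validate(X[:200], y[:200], ox.AdaBoostBaseline(random_state=5),
                            folds=5, seed=5)
        assert r1.to_dict() == r2.to_dict()
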