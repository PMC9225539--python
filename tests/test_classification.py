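"""Normalization, kernels, classifiers, CV protocol and confusion metrics."""

import math

import numpy as np
import pytest

from bladderwall.classification import (
    ClassifierConfig,
    Dataset,
    confusion_metrics,
    cross_validate,
    gwo_svm,
    normalize_apply,
    normalize_fit,
    normalize_fit_apply,
    predict,
    rbf_kernel,
    train_classifier,
    train_test_protocol,
)
from bladderwall.gwo import GWOConfig


def blobs(n=40, sep=4.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, size=(n // 2, 2))
    b = rng.normal(sep, 1, size=(n // 2, 2))
    X = np.vstack([a, b])
    y = np.array([-1] * (n // 2) + [1] * (n // 2))
    return Dataset(X, y)


class TestNormalization:
    def test_minmax_mapping(self):
        model = normalize_fit(np.array([[10.0], [30.0]]))
        out = normalize_apply(model, np.array([[10.0], [30.0], [20.0]]))
        np.testing.assert_allclose(out.ravel(), [-1.0, 1.0, 0.0])

    def test_constant_feature_maps_to_zero(self):
        model = normalize_fit(np.array([[5.0, 1.0], [5.0, 3.0]]))
        out = normalize_apply(model, np.array([[5.0, 2.0], [7.0, 1.0]]))
        assert out[0, 0] == 0.0 and out[1, 0] == 0.0

    def test_test_values_not_clipped(self):
        _, _, test = normalize_fit_apply(np.array([[10.0], [30.0]]), np.array([[35.0]]))
        assert test[0, 0] == pytest.approx(1.5)


class TestRbfKernel:
    def test_zero_distance(self):
        assert rbf_kernel([1.0, 2.0], [1.0, 2.0], 0.5) == 1.0

    def test_characteristic_distance(self):
        gamma = 0.7
        xj = [math.sqrt(2) * gamma, 0.0]
        assert rbf_kernel([0.0, 0.0], xj, gamma) == pytest.approx(math.exp(-1))

    def test_matches_direct_formula(self, rng):
        gamma = 0.5
        for _ in range(5):
            xi, xj = rng.normal(size=4), rng.normal(size=4)
            direct = math.exp(-float(np.sum((xi - xj) ** 2)) / (2 * gamma**2))
            assert rbf_kernel(xi, xj, gamma) == pytest.approx(direct, abs=1e-12)

    def test_invalid_gamma(self):
        with pytest.raises(ValueError):
            rbf_kernel([0.0], [1.0], 0.0)


class TestClassifiers:
    def test_linear_kernel_separates_blobs(self):
        data = blobs()
        model = train_classifier(data, ClassifierConfig(kind="svm", kernel="linear"))
        assert np.array_equal(predict(model, data.X), data.y)

    def test_random_forest_separates_blobs(self):
        train = blobs(seed=0)
        test = blobs(seed=1)
        model = train_classifier(train, ClassifierConfig(kind="rf", n_trees=50, seed=0))
        assert np.array_equal(predict(model, test.X), test.y)

    def test_xor_needs_nonlinear_kernel(self):
        rng = np.random.default_rng(2)
        centers = np.array([[0, 0], [4, 4], [0, 4], [4, 0]])
        X = np.vstack([c + rng.normal(0, 0.3, size=(10, 2)) for c in centers])
        y = np.array([1] * 20 + [-1] * 20)
        data = Dataset(X, y)
        linear = train_classifier(data, ClassifierConfig(kind="svm", kernel="linear"))
        assert (predict(linear, X) == y).mean() < 1.0
        rbf = train_classifier(data, ClassifierConfig(kind="svm", kernel="rbf",
                                                      C=10.0, gamma=1.0))
        assert np.array_equal(predict(rbf, X), y)

    def test_single_class_training_error(self):
        with pytest.raises(ValueError):
            Dataset(np.zeros((4, 2)), np.ones(4))


class TestCrossValidate:
    def test_separable_cohort_perfect_accuracy(self):
        metrics = cross_validate(blobs(n=50), ClassifierConfig(kind="svm", kernel="rbf",
                                                               C=10.0, gamma=1.0), k=5, seed=0)
        assert metrics.accuracy == 1.0

    def test_same_seed_same_metrics(self):
        data = blobs(n=60, sep=2.0, seed=3)
        cfg = ClassifierConfig(kind="svm", kernel="rbf", C=1.0, gamma=1.0)
        m1 = cross_validate(data, cfg, k=5, seed=7)
        m2 = cross_validate(data, cfg, k=5, seed=7)
        assert m1 == m2

    def test_class_smaller_than_k_errors(self):
        X = np.vstack([np.zeros((3, 2)), np.ones((10, 2))])
        y = np.array([1] * 3 + [-1] * 10)
        with pytest.raises(ValueError, match="5-fold"):
            cross_validate(Dataset(X, y), ClassifierConfig(), k=5)


class TestConfusionMetrics:
    def test_perfect_prediction(self):
        y = np.array([1, -1, 1, -1])
        m = confusion_metrics(y, y)
        assert (m.accuracy, m.sensitivity, m.specificity, m.precision) == (1, 1, 1, 1)

    def test_reported_quadruple_from_confusion_counts(self):
        """TP=18, FN=1, TN=16, FP=1 yields accuracy 0.9444, sensitivity
        0.9474, specificity 0.9412, precision 0.9474 (4 decimals)."""
        y_true = np.array([1] * 19 + [-1] * 17)
        y_pred = np.array([1] * 18 + [-1] + [-1] * 16 + [1])
        m = confusion_metrics(y_true, y_pred)
        assert round(m.accuracy, 4) == 0.9444
        assert round(m.sensitivity, 4) == 0.9474
        assert round(m.specificity, 4) == 0.9412
        assert round(m.precision, 4) == 0.9474

    def test_all_positive_predictions(self):
        y_true = np.array([1, 1, -1, -1])
        y_pred = np.ones(4, dtype=int)
        m = confusion_metrics(y_true, y_pred)
        assert m.specificity == 0.0

    def test_undefined_metric_is_nan_not_zero(self):
        y_true = np.array([-1, -1])
        y_pred = np.array([-1, -1])
        m = confusion_metrics(y_true, y_pred)
        assert math.isnan(m.sensitivity)   # no positives at all
        assert math.isnan(m.precision)
        assert m.accuracy == 1.0


class TestGwoSvm:
    def test_separable_cohort_perfect_cv(self):
        data = blobs(n=40, sep=5.0)
        cfg = GWOConfig(pack_size=6, iterations=8, seed=0)
        result = gwo_svm(data, cfg, k=5, cv_seed=0)
        assert result.cv_metrics.accuracy == 1.0
        assert np.all(np.diff(result.trace) >= -1e-15)

    def test_deterministic_hyperparameters(self):
        data = blobs(n=40, sep=2.5, seed=5)
        cfg = GWOConfig(pack_size=5, iterations=6, seed=4)
        r1 = gwo_svm(data, cfg, k=5, cv_seed=4)
        r2 = gwo_svm(data, cfg, k=5, cv_seed=4)
        assert (r1.C, r1.gamma) == (r2.C, r2.gamma)


def test_train_test_protocol_split_and_normalization():
    data = blobs(n=60, sep=5.0)
    held, cv = train_test_protocol(data, ClassifierConfig(kind="svm", kernel="rbf",
                                                          C=10.0, gamma=1.0), seed=0)
    assert held.accuracy == 1.0
    assert cv.accuracy == 1.0
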