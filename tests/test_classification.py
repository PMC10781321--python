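"""Classifier benchmark: metrics, splits, specs, and the composed decision rule."""

import numpy as np
import pytest
from sklearn.metrics import precision_recall_fscore_support

from fogbci.autoencoder import build_encoder
from fogbci.classification import (
    ClassifierSpec,
    FeatureMatrix,
    classify_signal,
    compute_metrics,
    default_specs,
    double_miss_probability,
    flatten_latent,
    stratified_split,
    train_classifier,
    unflatten_latent,
)
from fogbci.errors import (
    DegenerateLabelsError,
    ShapeError,
    StratificationError,
    ValidationError,
)
from fogbci.records import EEGRecord


def synthetic_features(rng, n=80, informative_pixel=None):
    """Random features; optionally class = sign pattern of one pixel."""
    X = rng.standard_normal((n, 336))
    if informative_pixel is None:
        y = rng.integers(0, 4, size=n)
    else:
        values = X[:, informative_pixel]
        y = np.digitize(values, np.quantile(values, [0.25, 0.5, 0.75]))
    return FeatureMatrix(X, y)


class TestFlattening:
    def test_row_major_order(self):
        image = np.arange(336).reshape(16, 21)
        vec = flatten_latent(image)
        assert vec[21] == image[1, 0]  # second row starts at index 21

    def test_round_trip(self, rng):
        vec = rng.standard_normal(336)
        np.testing.assert_array_equal(flatten_latent(unflatten_latent(vec)), vec)

    def test_wrong_sizes_rejected(self, rng):
        with pytest.raises(ShapeError):
            flatten_latent(rng.standard_normal((8, 21)))
        with pytest.raises(ShapeError):
            unflatten_latent(rng.standard_normal(335))


class TestComputeMetrics:
    def test_worked_example(self):
        """Class 0 with TP=49, FP=1, FN=2: precision 0.98, recall 49/51."""
        y_true = np.array([0] * 49 + [0, 0] + [1] * 49)
        y_pred = np.array([0] * 49 + [1, 1] + [1] * 48 + [0])
        report = compute_metrics(y_true, y_pred)
        assert report.precision[0] == pytest.approx(0.98)
        assert report.recall[0] == pytest.approx(49 / 51)

    def test_perfect_prediction(self):
        y = np.array([0, 1, 2, 3] * 5)
        report = compute_metrics(y, y)
        assert report.accuracy == 1.0
        np.testing.assert_allclose(report.precision, 1.0)
        np.testing.assert_allclose(report.recall, 1.0)
        np.testing.assert_allclose(report.f1, 1.0)

    def test_all_wrong(self):
        y_true = np.array([0, 1, 2, 3] * 5)
        y_pred = (y_true + 1) % 4
        report = compute_metrics(y_true, y_pred)
        assert report.accuracy == 0.0
        np.testing.assert_allclose(report.precision, 0.0)
        np.testing.assert_allclose(report.recall, 0.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_reference_implementation(self, seed):
        """Cross-check formulas against scikit-learn on random label vectors."""
        rng = np.random.default_rng(seed)
        y_true = rng.integers(0, 4, size=200)
        y_pred = rng.integers(0, 4, size=200)
        report = compute_metrics(y_true, y_pred)
        p, r, f, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=[0, 1, 2, 3], zero_division=0
        )
        np.testing.assert_allclose(report.precision, p, atol=1e-12)
        np.testing.assert_allclose(report.recall, r, atol=1e-12)
        np.testing.assert_allclose(report.f1, f, atol=1e-12)

    def test_confusion_consistency_brute_force(self, rng):
        """Every metric is recomputable from pair counts within 1e-12."""
        y_true = rng.integers(0, 4, size=150)
        y_pred = rng.integers(0, 4, size=150)
        report = compute_metrics(y_true, y_pred)
        for c in range(4):
            tp = sum((t == c) and (p == c) for t, p in zip(y_true, y_pred))
            fp = sum((t != c) and (p == c) for t, p in zip(y_true, y_pred))
            fn = sum((t == c) and (p != c) for t, p in zip(y_true, y_pred))
            expected_p = tp / (tp + fp) if tp + fp else 0.0
            expected_r = tp / (tp + fn) if tp + fn else 0.0
            assert report.precision[c] == pytest.approx(expected_p, abs=1e-12)
            assert report.recall[c] == pytest.approx(expected_r, abs=1e-12)
        assert report.accuracy == pytest.approx(
            np.mean(y_true == y_pred), abs=1e-12
        )
        assert report.confusion.sum() == 150
        np.testing.assert_array_equal(
            report.confusion.sum(axis=1), np.bincount(y_true, minlength=4)
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            compute_metrics(np.array([0, 1]), np.array([0]))


class TestMetricProperties:
    """Property checks over arbitrary label vectors."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        st.lists(
            st.tuples(st.integers(0, 3), st.integers(0, 3)), min_size=1, max_size=60
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_metrics_bounded_and_consistent(self, pairs):
        y_true = np.array([t for t, _ in pairs])
        y_pred = np.array([p for _, p in pairs])
        report = compute_metrics(y_true, y_pred)
        for values in (report.precision, report.recall, report.f1):
            assert np.all((values >= 0) & (values <= 1))
        assert 0 <= report.accuracy <= 1
        assert report.confusion.sum() == len(pairs)
        # accuracy is the trace over the total, by definition
        assert report.accuracy == pytest.approx(
            np.trace(report.confusion) / len(pairs), abs=1e-12
        )

    @given(st.lists(st.floats(-100, 100), min_size=336, max_size=336))
    @settings(max_examples=25, deadline=None)
    def test_flatten_round_trip_any_values(self, values):
        vec = np.array(values)
        np.testing.assert_array_equal(flatten_latent(unflatten_latent(vec)), vec)


class TestDoubleMiss:
    def test_benchmark_value(self):
        assert double_miss_probability(0.96) == pytest.approx(0.04 * 0.04)

    @pytest.mark.parametrize("acc,expected", [(1.0, 0.0), (0.5, 0.25), (0.0, 1.0)])
    def test_direct_values(self, acc, expected):
        assert double_miss_probability(acc) == pytest.approx(expected)

    @pytest.mark.parametrize("bad", [-0.1, 1.5])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValidationError):
            double_miss_probability(bad)


class TestClassifierSpecs:
    def test_rf_has_250_trees(self, rng):
        features = synthetic_features(rng)
        model = train_classifier(ClassifierSpec("RF", seed=0), features)
        assert model.n_estimators == 250
        assert len(model.estimators_) == 250

    def test_gb_and_dt_and_svm_settings(self):
        specs = {s.algorithm: s.build() for s in default_specs()}
        assert specs["GB"].n_estimators == 159
        assert specs["GB"].max_depth == 4
        assert specs["DT"].criterion == "gini"
        assert specs["DT"].max_depth is None
        assert specs["SVM"].C == 1.0 and specs["SVM"].kernel == "rbf"

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValidationError):
            ClassifierSpec("MLP")

    def test_single_pixel_rule_learned_perfectly(self, rng):
        """A decision tree nails labels defined by thresholds on one pixel."""
        features = synthetic_features(rng, n=120, informative_pixel=42)
        model = train_classifier(ClassifierSpec("DT", seed=0), features)
        assert model.score(features.X, features.y) == 1.0

    def test_deterministic_predictions(self, rng):
        features = synthetic_features(rng, n=60, informative_pixel=10)
        probe = rng.standard_normal((20, 336))
        a = train_classifier(ClassifierSpec("RF", seed=4), features).predict(probe)
        b = train_classifier(ClassifierSpec("RF", seed=4), features).predict(probe)
        np.testing.assert_array_equal(a, b)

    def test_single_class_rejected(self, rng):
        features = FeatureMatrix(rng.standard_normal((10, 336)), np.zeros(10))
        with pytest.raises(DegenerateLabelsError):
            train_classifier(ClassifierSpec("RF"), features)


class TestSplit:
    def test_80_20_arithmetic(self, rng):
        features = synthetic_features(rng, n=200)
        features.y = np.tile([0, 1, 2, 3], 50)
        train, test = stratified_split(features, split_seed=0)
        assert len(train) == 160
        assert len(test) == 40

    def test_stratification_within_one_record(self, rng):
        features = synthetic_features(rng, n=200)
        features.y = np.tile([0, 1, 2, 3], 50)
        _, test = stratified_split(features, split_seed=1)
        counts = np.bincount(test.y, minlength=4)
        np.testing.assert_array_less(np.abs(counts - 10), 2)

    def test_too_few_records_rejected(self, rng):
        features = FeatureMatrix(
            rng.standard_normal((8, 336)), np.array([0, 1, 2, 3] * 2)
        )
        with pytest.raises(StratificationError):
            stratified_split(features, split_seed=0)


class TestClassifySignal:
    def test_composed_rule_returns_valid_code(self, rng, small_dataset):
        from fogbci.preprocessing import preprocess_dataset
        from fogbci.autoencoder import encode_dataset

        encoder = build_encoder(seed=0)
        processed = preprocess_dataset(small_dataset)
        images = encode_dataset(encoder, processed)
        features = FeatureMatrix.from_images(images, processed.labels())
        model = train_classifier(ClassifierSpec("RF", seed=0), features)
        code = classify_signal(small_dataset.records[0], encoder, model)
        assert code in (0, 1, 2, 3)

    def test_training_record_maps_to_its_label(self, rng, small_dataset):
        """A record whose latent matches a training row predicts that row's label."""
        from fogbci.preprocessing import preprocess_dataset
        from fogbci.autoencoder import encode_dataset

        encoder = build_encoder(seed=0)
        processed = preprocess_dataset(small_dataset)
        images = encode_dataset(encoder, processed)
        features = FeatureMatrix.from_images(images, processed.labels())
        model = train_classifier(ClassifierSpec("DT", seed=0), features)
        # DT fits the training set (near-)perfectly; the composed map must
        # reproduce the prediction for the identical latent input.
        pred_direct = model.predict(features.X[:4])
        codes = [
            classify_signal(rec, encoder, model)
            for rec in small_dataset.records[:4]
        ]
        np.testing.assert_array_equal(codes, pred_direct)

    def test_feature_count_mismatch_rejected(self, rng):
        class Fake:
            n_features_in_ = 100

        encoder = build_encoder(seed=0)
        rec = EEGRecord(data=rng.standard_normal((4, 160)), sampling_rate=256.0)
        with pytest.raises(ShapeError):
            classify_signal(rec, encoder, Fake())
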