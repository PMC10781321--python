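"""Command classification of latent images and the four-classifier benchmark.

The deployed decision rule is ``C = RF(f_enc(x))``: a random forest with 250
trees over the 336 pixels of the latent image (flattened row-major). For
model selection the same features are benchmarked against three reference
classifiers — an RBF-kernel support vector machine (C = 1.0), a Gini
decision tree, and gradient boosting (159 estimators, per-tree depth 4) —
on a single stratified 80/20 split shared by all algorithms, reporting
per-class precision, recall and F1 plus overall accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .autoencoder import LATENT_SHAPE, N_LATENT_FEATURES, EncoderModel, encode_dataset
from .errors import (
    DegenerateLabelsError,
    ShapeError,
    StratificationError,
    ValidationError,
)
from .preprocessing import FilterConfig, preprocess_record
from .records import CLASS_NAMES, N_CLASSES, Dataset, EEGRecord

logger = logging.getLogger(__name__)

ALGORITHMS = ("RF", "SVM", "DT", "GB")


def flatten_latent(image: np.ndarray) -> np.ndarray:
    """Flatten a 16 x 21 latent image to 336 features, row-major."""
    image = np.asarray(image)
    if image.shape[-2:] != LATENT_SHAPE:
        raise ShapeError(f"latent image must be {LATENT_SHAPE}, got {image.shape}")
    return image.reshape(*image.shape[:-2], N_LATENT_FEATURES)


def unflatten_latent(vector: np.ndarray) -> np.ndarray:
    """Inverse of :func:`flatten_latent`: 336 features -> 16 x 21 image."""
    vector = np.asarray(vector)
    if vector.shape[-1] != N_LATENT_FEATURES:
        raise ShapeError(
            f"feature vector must have {N_LATENT_FEATURES} entries, "
            f"got {vector.shape[-1]}"
        )
    return vector.reshape(*vector.shape[:-1], *LATENT_SHAPE)


@dataclass
class FeatureMatrix:
    """Flattened latent images paired with integer class labels."""

    X: np.ndarray  # (n_samples, 336)
    y: np.ndarray  # (n_samples,)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.X.ndim != 2 or self.X.shape[1] != N_LATENT_FEATURES:
            raise ShapeError(
                f"feature matrix must have {N_LATENT_FEATURES} columns, "
                f"got shape {self.X.shape}"
            )
        if len(self.y) != len(self.X):
            raise ValidationError("labels not aligned with feature rows")

    @classmethod
    def from_images(cls, images: np.ndarray, labels: np.ndarray) -> "FeatureMatrix":
        return cls(X=flatten_latent(images), y=labels)

    def __len__(self) -> int:
        return len(self.X)


@dataclass
class ClassifierSpec:
    """Algorithm choice plus its benchmark hyperparameters.

    Unlisted hyperparameters stay at scikit-learn's documented defaults.
    """

    algorithm: str = "RF"
    seed: int = 0
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValidationError(
                f"algorithm must be one of {ALGORITHMS}, got {self.algorithm!r}"
            )

    def build(self):
        """Instantiate the scikit-learn estimator for this spec."""
        hp = self.hyperparameters
        if self.algorithm == "RF":
            return RandomForestClassifier(
                n_estimators=hp.get("n_estimators", 250), random_state=self.seed
            )
        if self.algorithm == "SVM":
            return SVC(C=hp.get("C", 1.0), kernel=hp.get("kernel", "rbf"))
        if self.algorithm == "DT":
            # Depth unlimited by default (library default).
            return DecisionTreeClassifier(
                criterion=hp.get("criterion", "gini"),
                max_depth=hp.get("max_depth"),
                random_state=self.seed,
            )
        return GradientBoostingClassifier(
            n_estimators=hp.get("n_estimators", 159),
            max_depth=hp.get("max_depth", 4),
            random_state=self.seed,
        )


def default_specs(seed: int = 0) -> list[ClassifierSpec]:
    """The four benchmark classifier specs with their reference settings."""
    return [ClassifierSpec(algorithm=a, seed=seed) for a in ALGORITHMS]


@dataclass
class ClassifierReport:
    """Per-class precision/recall/F1, overall accuracy and confusion counts.

    ``confusion[i, j]`` counts test samples of true class ``i`` predicted as
    class ``j``; row sums are the per-class test counts.
    """

    precision: np.ndarray  # (4,)
    recall: np.ndarray  # (4,)
    f1: np.ndarray  # (4,)
    accuracy: float
    confusion: np.ndarray  # (4, 4) counts
    assignment_proportions: np.ndarray | None = None  # rows: true class

    def to_frame(self) -> pd.DataFrame:
        """Benchmark-table layout: one row per class plus overall accuracy."""
        df = pd.DataFrame(
            {
                "precision": self.precision,
                "recall": self.recall,
                "f1_score": self.f1,
                "support": self.confusion.sum(axis=1),
            },
            index=list(CLASS_NAMES),
        )
        df.attrs["accuracy"] = self.accuracy
        return df

    def to_dict(self) -> dict:
        return {
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "f1": self.f1.tolist(),
            "accuracy": self.accuracy,
            "confusion": self.confusion.tolist(),
            "classes": list(CLASS_NAMES),
        }


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> ClassifierReport:
    """Precision, recall, F1 per class and accuracy from label vectors.

    Zero-denominator metrics are reported as 0 with a logged warning.
    """
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or len(y_true) < 1:
        raise ValidationError(
            f"label vectors must be equal-length 1-D, got {y_true.shape} "
            f"and {y_pred.shape}"
        )
    confusion = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    np.add.at(confusion, (y_true, y_pred), 1)
    tp = np.diag(confusion).astype(float)
    fp = confusion.sum(axis=0) - tp
    fn = confusion.sum(axis=1) - tp

    def safe_div(num: np.ndarray, den: np.ndarray, name: str) -> np.ndarray:
        out = np.zeros_like(num)
        zero = den == 0
        if np.any(zero):
            logger.warning(
                "%s undefined for class(es) %s; reporting 0",
                name,
                [CLASS_NAMES[i] for i in np.flatnonzero(zero)],
            )
        out[~zero] = num[~zero] / den[~zero]
        return out

    precision = safe_div(tp, tp + fp, "precision")
    recall = safe_div(tp, tp + fn, "recall")
    f1 = safe_div(2 * precision * recall, precision + recall, "f1")
    accuracy = float(tp.sum() / confusion.sum())
    return ClassifierReport(
        precision=precision,
        recall=recall,
        f1=f1,
        accuracy=accuracy,
        confusion=confusion,
    )


def train_classifier(spec: ClassifierSpec, features: FeatureMatrix):
    """Fit the specified classifier on flattened latent images."""
    if len(np.unique(features.y)) < 2:
        raise DegenerateLabelsError(
            "training set contains fewer than two classes"
        )
    model = spec.build()
    model.fit(features.X, features.y)
    return model


def classify_signal(
    record: EEGRecord,
    encoder: EncoderModel,
    model,
    filter_config: FilterConfig | None = None,
    filter_signal: bool = True,
) -> int:
    """The deployed decision rule: preprocess, encode, classify.

    Returns the integer class code (0=LF, 1=LH, 2=RX, 3=MA).
    """
    expected = getattr(model, "n_features_in_", N_LATENT_FEATURES)
    if expected != N_LATENT_FEATURES:
        raise ShapeError(
            f"classifier expects {expected} features, "
            f"encoder produces {N_LATENT_FEATURES}"
        )
    processed = preprocess_record(record, filter_config, filter_signal)
    image = encoder.encode(processed)
    return int(model.predict(flatten_latent(image)[None, :])[0])


def stratified_split(
    features: FeatureMatrix, split_seed: int, test_fraction: float = 0.2
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """One stratified train/test split; every class must reach both folds."""
    counts = np.bincount(features.y, minlength=N_CLASSES)
    if np.any(counts == 0):
        missing = [CLASS_NAMES[i] for i in np.flatnonzero(counts == 0)]
        raise StratificationError(f"class(es) {missing} absent from dataset")
    try:
        X_tr, X_te, y_tr, y_te = train_test_split(
            features.X,
            features.y,
            test_size=test_fraction,
            stratify=features.y,
            random_state=split_seed,
        )
    except ValueError as exc:
        raise StratificationError(str(exc)) from exc
    if len(np.unique(y_tr)) < N_CLASSES or len(np.unique(y_te)) < N_CLASSES:
        raise StratificationError("a class is absent from the train or test fold")
    return FeatureMatrix(X_tr, y_tr), FeatureMatrix(X_te, y_te)


def evaluate_suite(
    dataset: Dataset,
    encoder: EncoderModel,
    specs: list[ClassifierSpec] | None = None,
    split_seed: int = 0,
) -> dict[str, ClassifierReport]:
    """Benchmark all classifiers on one shared stratified 80/20 split.

    ``dataset`` must already be preprocessed. Each report also carries the
    per-true-class assignment proportions (rows of the row-normalized
    confusion matrix) behind per-class bar charts.
    """
    if len(dataset) < 20:
        raise ValidationError("benchmark requires at least 20 labeled records")
    specs = specs if specs is not None else default_specs()
    images = encode_dataset(encoder, dataset)
    features = FeatureMatrix.from_images(images, dataset.labels())
    train, test = stratified_split(features, split_seed)
    reports: dict[str, ClassifierReport] = {}
    for spec in specs:
        model = train_classifier(spec, train)
        report = compute_metrics(test.y, model.predict(test.X))
        row_sums = report.confusion.sum(axis=1, keepdims=True).astype(float)
        report.assignment_proportions = np.divide(
            report.confusion,
            row_sums,
            out=np.zeros_like(report.confusion, dtype=float),
            where=row_sums > 0,
        )
        reports[spec.algorithm] = report
    return reports


def reports_to_table(reports: dict[str, ClassifierReport]) -> pd.DataFrame:
    """Wide benchmark table: one row per algorithm, per-class metric columns."""
    rows = {}
    for algo, rep in reports.items():
        row: dict[str, float] = {}
        for metric, values in (
            ("precision", rep.precision),
            ("recall", rep.recall),
            ("f1", rep.f1),
        ):
            for cls, v in zip(CLASS_NAMES, values):
                row[f"{metric}_{cls}"] = v
        row["accuracy"] = rep.accuracy
        rows[algo] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def double_miss_probability(accuracy: float) -> float:
    """Chance that two consecutive independent commands are both missed.

    With accuracy ``a`` the per-command miss probability is ``1 - a``, so
    two independent misses occur with probability ``(1 - a)^2`` — e.g.
    0.04 x 0.04 at 96 % accuracy.
    """
    if not (0.0 <= accuracy <= 1.0):
        raise ValidationError(f"accuracy must be in [0, 1], got {accuracy}")
    return (1.0 - accuracy) ** 2
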