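"""Leave-one-subject-out (LOSO) evaluation with a multiclass linear SVM.

Every subject is held out in turn; all fitted quantities — channel
standardization statistics, the DBN (when the feature set uses one), and the
classifier's feature scaler — are computed from the remaining subjects only,
so the protocol measures cross-subject generalization under per-subject
distribution shift.  The classifier is a one-vs-rest linear SVM on z-scored
features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from . import dbn, preprocessing

__all__ = [
    "EvalResult",
    "accuracy",
    "train_linear_classifier",
    "loso_evaluate",
    "statistical_feature_fn",
    "dbn_feature_fn",
    "combined_feature_fn",
]

#: A feature function maps (train windows, test windows) to the pair of
#: feature matrices; everything it fits must come from the training windows.
FeatureFn = Callable[[list, list], tuple[np.ndarray, np.ndarray]]


@dataclass
class EvalResult:
    """Per-subject LOSO accuracies for one feature set."""

    feature_set: str
    subject_accuracy: dict[str, float]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(list(self.subject_accuracy.values())))


def accuracy(predictions: np.ndarray, labels: np.ndarray) -> float:
    """Fraction of exact matches."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have equal length")
    if predictions.size == 0:
        raise ValueError("empty input")
    return float(np.mean(predictions == labels))


def train_linear_classifier(features: np.ndarray, labels: np.ndarray, C: float = 1.0):
    """One-vs-rest linear SVM on z-scored features.

    The scaler is fitted on the training features and stored inside the
    returned pipeline, so transform-time statistics never leak from test
    data.  Raises on a single-class training set.
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("degenerate training set: fewer than 2 classes")
    if C <= 0:
        raise ValueError("C must be positive")
    clf = Pipeline(
        [
            ("scale", StandardScaler()),
            ("svm", LinearSVC(C=C)),
        ]
    )
    clf.fit(np.asarray(features, dtype=float), labels)
    return clf


class _ConstantClassifier:
    """Fallback predictor for degenerate folds whose training set has one class."""

    def __init__(self, label):
        self.label = label

    def predict(self, X):
        return np.full(np.atleast_2d(X).shape[0], self.label)


def loso_evaluate(
    windows: list,
    feature_fn: FeatureFn,
    C: float = 1.0,
    feature_set: str = "",
) -> EvalResult:
    """Hold out each subject in turn, fit features and classifier on the rest.

    ``feature_fn(train_windows, test_windows)`` must fit all of its internal
    statistics (standardization, DBN training, ...) on the training windows
    only and return the two feature matrices.
    """
    subjects = sorted({w.subject_id for w in windows})
    if len(subjects) < 2:
        raise ValueError("LOSO requires at least 2 subjects")
    per_subject: dict[str, float] = {}
    for subject in subjects:
        test = [w for w in windows if w.subject_id == subject]
        train = [w for w in windows if w.subject_id != subject]
        if not test:
            warnings.warn(f"subject {subject} has no instances; skipped")
            continue
        X_train, X_test = feature_fn(train, test)
        y_train = preprocessing.window_labels(train)
        y_test = preprocessing.window_labels(test)
        if np.unique(y_train).size < 2:
            clf = _ConstantClassifier(y_train[0])
        else:
            clf = train_linear_classifier(X_train, y_train, C)
        per_subject[subject] = accuracy(clf.predict(X_test), y_test)
    return EvalResult(feature_set, per_subject)


def statistical_feature_fn(extras: bool = False) -> FeatureFn:
    """Per-channel window means (the statistical baseline)."""

    def fn(train, test):
        return (
            preprocessing.statistical_feature_matrix(train, extras),
            preprocessing.statistical_feature_matrix(test, extras),
        )

    return fn


def dbn_feature_fn(config: dbn.TrainConfig) -> FeatureFn:
    """DBN readout features; the network and the channel statistics are
    fitted on the training windows of each fold."""

    def fn(train, test):
        train_std, stats = preprocessing.standardize(train)
        test_std, _ = preprocessing.standardize(test, stats)
        X_train = preprocessing.flatten_windows(train_std)
        X_test = preprocessing.flatten_windows(test_std)
        model = dbn.init_model(config, X_train.shape[1])
        dbn.train_layerwise(model, X_train, config)
        return dbn.extract_features(model, X_train), dbn.extract_features(model, X_test)

    return fn


def combined_feature_fn(config: dbn.TrainConfig, extras: bool = False) -> FeatureFn:
    """Statistical baseline columns followed by the DBN readout columns."""
    stat_fn = statistical_feature_fn(extras)
    net_fn = dbn_feature_fn(config)

    def fn(train, test):
        s_tr, s_te = stat_fn(train, test)
        d_tr, d_te = net_fn(train, test)
        return (
            preprocessing.concat_features(s_tr, d_tr),
            preprocessing.concat_features(s_te, d_te),
        )

    return fn
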