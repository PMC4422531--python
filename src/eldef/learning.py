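"""Multi-class relation classification over boolean feature vectors.

The default learner is a linear-kernel support vector machine with
complexity ``C = 1.0``, the configuration that consistently performed best
for this task; logistic regression, multinomial naive Bayes and random
forests are available behind the same interface.  Evaluation is stratified
k-fold cross-validation (10 folds by default) with per-class
precision/recall/F1 and the macro-averaged F-measure — the unweighted mean
of per-class F1 — computed over the pooled out-of-fold predictions.

Conventions (documented because the choice is genuinely open):

* F1 of a class with zero true positives and zero predicted positives is 0.
* Per-class scores are pooled over folds (micro within class), not averaged
  per fold.
* Fold assignment is a pure function of the seed; identical seed and input
  yield an identical report.
"""

from __future__ import annotations

import json
import pickle
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import sparse
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import MultinomialNB
from sklearn.svm import SVC

from .features import to_sparse_matrix

__all__ = [
    "LearnerConfig",
    "TrainedModel",
    "CVReport",
    "TrainingError",
    "train",
    "predict",
    "cross_validate",
    "save_model",
    "load_model",
]

ALGORITHMS = ("linear_svm", "logistic_regression", "naive_bayes", "random_forest")

_MODEL_FORMAT_VERSION = 1


class TrainingError(ValueError):
    """Training preconditions violated (single class, empty vocabulary...)."""


@dataclass(frozen=True)
class LearnerConfig:
    """Learner choice and hyperparameters.

    ``complexity`` is the SVM C parameter (also reused as inverse
    regularisation for logistic regression).  ``epsilon`` is the numeric
    round-off parameter of the reference SMO configuration; it is carried
    for fidelity of the recorded configuration (libsvm exposes no direct
    equivalent) and does not affect the fit.
    """

    algorithm: str = "linear_svm"
    complexity: float = 1.0
    epsilon: float = 1.0e-12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        if self.complexity <= 0 or self.epsilon <= 0:
            raise ValueError("complexity and epsilon must be positive")


def _make_estimator(config: LearnerConfig):
    if config.algorithm == "linear_svm":
        return SVC(kernel="linear", C=config.complexity, random_state=config.seed)
    if config.algorithm == "logistic_regression":
        return LogisticRegression(
            C=config.complexity, max_iter=2000, random_state=config.seed
        )
    if config.algorithm == "naive_bayes":
        return MultinomialNB()
    return RandomForestClassifier(n_estimators=100, random_state=config.seed)


@dataclass
class TrainedModel:
    """A fitted classifier plus the vocabulary and class list it speaks.

    Prediction projects incoming feature sets onto the training vocabulary;
    unseen feature names are silently ignored.
    """

    config: LearnerConfig
    vocabulary: list[str]
    classes: list[str]
    estimator: object


def train(
    vectors: Sequence[frozenset[str]],
    labels: Sequence[str],
    config: LearnerConfig = LearnerConfig(),
    vocabulary: Sequence[str] | None = None,
) -> TrainedModel:
    """Fit a multi-class relation classifier on presence-set vectors."""
    if len(vectors) != len(labels):
        raise ValueError("vectors and labels must have equal length")
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise TrainingError(f"need at least 2 classes, got {classes}")
    if vocabulary is None:
        vocabulary = sorted(set().union(*vectors)) if vectors else []
    vocabulary = list(vocabulary)
    if not vocabulary:
        raise TrainingError("empty feature vocabulary")
    X = to_sparse_matrix(vectors, vocabulary)
    est = _make_estimator(config)
    est.fit(X, np.asarray(labels))
    return TrainedModel(config=config, vocabulary=vocabulary,
                        classes=classes, estimator=est)


def predict(model: TrainedModel, vectors: Sequence[frozenset[str]]) -> list[str]:
    """One deterministic label per vector; unseen features ignored."""
    if not vectors:
        return []
    X = to_sparse_matrix(vectors, model.vocabulary)
    return [str(y) for y in model.estimator.predict(X)]


@dataclass
class CVReport:
    """Cross-validation results: per-class P/R/F1, macro-F, confusion matrix.

    ``confusion[i][j]`` counts instances of true class ``classes[i]``
    predicted as ``classes[j]``, pooled over all folds.
    """

    per_class: dict[str, tuple[float, float, float]]
    macro_f: float
    confusion: list[list[int]]
    classes: list[str]
    folds: int
    seed: int

    def to_json(self) -> str:
        obj = {
            "per_class": {
                c: {"precision": p, "recall": r, "f1": f}
                for c, (p, r, f) in sorted(self.per_class.items())
            },
            "macro_f": self.macro_f,
            "classes": self.classes,
            "confusion": self.confusion,
            "folds": self.folds,
            "seed": self.seed,
        }
        return json.dumps(obj, indent=2, sort_keys=True)


def _prf_from_confusion(confusion: np.ndarray) -> list[tuple[float, float, float]]:
    out = []
    for i in range(confusion.shape[0]):
        tp = confusion[i, i]
        fp = confusion[:, i].sum() - tp
        fn = confusion[i, :].sum() - tp
        precision = tp / (tp + fp) if tp + fp > 0 else 0.0
        recall = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
        out.append((float(precision), float(recall), float(f1)))
    return out


def cross_validate(
    vectors: Sequence[frozenset[str]],
    labels: Sequence[str],
    config: LearnerConfig = LearnerConfig(),
    folds: int = 10,
) -> CVReport:
    """Stratified k-fold cross-validation with pooled per-class scoring.

    If the rarest class has fewer instances than ``folds`` the fold count
    is reduced to that support (with a warning); fewer than 2 usable folds
    is an error.
    """
    labels = list(labels)
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise TrainingError(f"need at least 2 classes, got {classes}")
    min_support = min(labels.count(c) for c in classes)
    if min_support < folds:
        warnings.warn(
            f"reducing folds from {folds} to {min_support} "
            "(smallest class support)", stacklevel=2
        )
        folds = min_support
    if folds < 2:
        raise TrainingError("need at least 2 instances in every class for CV")

    vocabulary = sorted(set().union(*vectors)) if vectors else []
    if not vocabulary:
        raise TrainingError("empty feature vocabulary")
    X = to_sparse_matrix(vectors, vocabulary)
    y = np.asarray(labels)
    cls_index = {c: i for i, c in enumerate(classes)}

    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=config.seed)
    for train_idx, test_idx in skf.split(X, y):
        est = _make_estimator(config)
        est.fit(X[train_idx], y[train_idx])
        for true, pred in zip(y[test_idx], est.predict(X[test_idx])):
            confusion[cls_index[true], cls_index[str(pred)]] += 1

    prf = _prf_from_confusion(confusion)
    per_class = {c: prf[i] for i, c in enumerate(classes)}
    macro_f = float(np.mean([f for _, _, f in prf]))
    return CVReport(
        per_class=per_class,
        macro_f=macro_f,
        confusion=confusion.tolist(),
        classes=classes,
        folds=folds,
        seed=config.seed,
    )


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist a model in a versioned pickle container."""
    payload = {
        "format_version": _MODEL_FORMAT_VERSION,
        "config": asdict(model.config),
        "vocabulary": model.vocabulary,
        "classes": model.classes,
        "estimator": model.estimator,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_model(path: str | Path) -> TrainedModel:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("format_version") != _MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format: {payload.get('format_version')}")
    return TrainedModel(
        config=LearnerConfig(**payload["config"]),
        vocabulary=payload["vocabulary"],
        classes=payload["classes"],
        estimator=payload["estimator"],
    )
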