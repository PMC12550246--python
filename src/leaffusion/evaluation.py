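"""Classifier suite, soft voting, stratified evaluation and metrics.

Classifier internals are delegated to scikit-learn; this module owns
their configuration, the soft-voting combination, the stratified
splitting/cross-validation procedure and all confusion-matrix metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.ensemble import AdaBoostClassifier, GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .balancing import FeatureMatrix, smote_resample, standardize

logger = logging.getLogger(__name__)

CLASSIFIER_NAMES = (
    "AdaBoost",
    "DecisionTree",
    "GradientBoost",
    "KNN",
    "LogisticRegression",
    "NaiveBayes",
    "SVM",
    "RandomForest",
    "SoftVote",
)

#: Default soft-voting ensemble membership.
DEFAULT_ENSEMBLE = ("SVM", "RandomForest", "GradientBoost")


@dataclass
class ClassifierSpec:
    name: str
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    seed: int = 42
    members: tuple[str, ...] = DEFAULT_ENSEMBLE  # SoftVote only

    def __post_init__(self) -> None:
        if self.name not in CLASSIFIER_NAMES:
            raise ValueError(f"unknown classifier {self.name!r}; valid names: {', '.join(CLASSIFIER_NAMES)}")


class SoftVotingClassifier:
    """Averages member class probabilities; prediction is the argmax."""

    def __init__(self, members: list[tuple[str, Any]], weights: list[float] | None = None):
        if len(members) < 2:
            raise ValueError("soft voting needs at least 2 members")
        self.members = members
        self.weights = weights

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SoftVotingClassifier":
        for _, m in self.members:
            m.fit(X, y)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        blocks = [m.predict_proba(X) for _, m in self.members]
        w = self.weights or [1.0] * len(blocks)
        total = sum(w)
        return sum(wi * b for wi, b in zip(w, blocks)) / total

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)


def build_classifier(spec: ClassifierSpec) -> Any:
    """Instantiate a configured model handle (fit / predict / predict_proba).

    Defaults: SVM RBF with C=10, gamma=0.1 (probability-calibrated so it
    can join the soft vote); RF 100 trees; KNN 5 neighbors; LR max_iter
    1000; DT gini/unbounded/min-split 2; GB 100 estimators, rate 0.1,
    depth 3; AdaBoost 50 estimators, rate 1.0; Gaussian NB.
    """
    hp = dict(spec.hyperparameters)
    seed = spec.seed
    if spec.name == "SVM":
        params = {"kernel": "rbf", "C": 10.0, "gamma": 0.1, "probability": True, "random_state": seed}
        params.update(hp)
        return SVC(**params)
    if spec.name == "RandomForest":
        params = {"n_estimators": 100, "random_state": seed}
        params.update(hp)
        return RandomForestClassifier(**params)
    if spec.name == "KNN":
        params = {"n_neighbors": 5}
        params.update(hp)
        return KNeighborsClassifier(**params)
    if spec.name == "LogisticRegression":
        params = {"max_iter": 1000, "random_state": seed}
        params.update(hp)
        return LogisticRegression(**params)
    if spec.name == "NaiveBayes":
        return GaussianNB(**hp)
    if spec.name == "DecisionTree":
        params = {"criterion": "gini", "max_depth": None, "min_samples_split": 2, "random_state": seed}
        params.update(hp)
        return DecisionTreeClassifier(**params)
    if spec.name == "GradientBoost":
        params = {"n_estimators": 100, "learning_rate": 0.1, "max_depth": 3, "random_state": seed}
        params.update(hp)
        return GradientBoostingClassifier(**params)
    if spec.name == "AdaBoost":
        params = {"n_estimators": 50, "learning_rate": 1.0, "random_state": seed}
        params.update(hp)
        return AdaBoostClassifier(**params)
    if spec.name == "SoftVote":
        members = [
            (name, build_classifier(ClassifierSpec(name=name, seed=seed))) for name in spec.members
        ]
        return SoftVotingClassifier(members, weights=hp.get("weights"))
    raise ValueError(f"unknown classifier {spec.name!r}; valid names: {', '.join(CLASSIFIER_NAMES)}")


def soft_vote(prob_blocks: list[np.ndarray], weights: list[float] | None = None) -> np.ndarray:
    """Predicted labels from the weighted mean of probability matrices.

    Ties resolve to the lowest class index (argmax semantics).
    """
    if len(prob_blocks) < 2:
        raise ValueError("need at least 2 probability blocks")
    blocks = [np.asarray(b, dtype=np.float64) for b in prob_blocks]
    shape = blocks[0].shape
    for b in blocks:
        if b.shape != shape:
            raise ValueError(f"probability block shapes differ: {b.shape} vs {shape}")
        if not np.allclose(b.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("probability rows must sum to 1")
    w = weights or [1.0] * len(blocks)
    if len(w) != len(blocks):
        raise ValueError("one weight per block required")
    mean = sum(wi * b for wi, b in zip(w, blocks)) / sum(w)
    return np.argmax(mean, axis=1)


def split_indices(
    data: FeatureMatrix, fractions: tuple[float, float, float] = (0.7, 0.15, 0.15), seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Index arrays of the stratified train/val/test split.

    Per class the shuffled indices are apportioned with largest-remainder
    rounding; remainder ties break in subset order train, val, test.
    Classes too small to populate every subset fall back to train with a
    warning.
    """
    fractions = tuple(float(f) for f in fractions)
    if any(f <= 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must be positive and sum to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    parts: list[list[np.ndarray]] = [[], [], []]
    for code in range(data.n_classes):
        idx = np.flatnonzero(data.y == code)
        if len(idx) == 0:
            continue
        idx = rng.permutation(idx)
        if len(idx) < 3:
            logger.warning(
                "class %r has only %d sample(s); assigning all to train", data.class_names[code], len(idx)
            )
            parts[0].append(idx)
            continue
        ideal = np.array(fractions) * len(idx)
        counts = np.floor(ideal).astype(int)
        remainder = ideal - counts
        for j in np.argsort(-remainder, kind="stable")[: len(idx) - counts.sum()]:
            counts[j] += 1
        pos = 0
        for j in range(3):
            parts[j].append(idx[pos : pos + counts[j]])
            pos += counts[j]
    return tuple(
        np.sort(np.concatenate(chunk)).astype(np.intp) if chunk else np.array([], dtype=np.intp)
        for chunk in parts
    )


def split_dataset(
    data: FeatureMatrix, fractions: tuple[float, float, float] = (0.7, 0.15, 0.15), seed: int = 0
) -> tuple[FeatureMatrix, FeatureMatrix, FeatureMatrix]:
    """Stratified train/validation/test split (see :func:`split_indices`)."""
    return tuple(data.subset(idx) for idx in split_indices(data, fractions, seed))


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray, k: int) -> np.ndarray:
    """k x k counts; rows are actual classes, columns predicted classes."""
    cm = np.zeros((k, k), dtype=np.int64)
    np.add.at(cm, (np.asarray(y_true, dtype=np.intp), np.asarray(y_pred, dtype=np.intp)), 1)
    return cm


def confusion_metrics(cm: np.ndarray) -> dict[str, Any]:
    """Per-class precision/recall/F1 plus accuracy and macro averages.

    Rows of *cm* are actual classes, columns predicted.  Precision uses
    the predicted-column sum, recall the actual-row sum; a zero
    denominator yields 0 (logged), so reports survive never-predicted
    classes.
    """
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError(f"confusion matrix must be square, got shape {cm.shape}")
    if np.any(cm < 0):
        raise ValueError("confusion matrix entries must be non-negative")
    diag = np.diag(cm).astype(np.float64)
    col = cm.sum(axis=0).astype(np.float64)
    row = cm.sum(axis=1).astype(np.float64)
    if np.any(col == 0) or np.any(row == 0):
        logger.info("zero-denominator metric encountered; reporting 0 for the affected class")
    precision = np.divide(diag, col, out=np.zeros_like(diag), where=col > 0)
    recall = np.divide(diag, row, out=np.zeros_like(diag), where=row > 0)
    pr = precision + recall
    f1 = np.divide(2 * precision * recall, pr, out=np.zeros_like(diag), where=pr > 0)
    total = cm.sum()
    accuracy = float(diag.sum() / total) if total > 0 else 0.0
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "accuracy": accuracy,
        "macro_precision": float(precision.mean()),
        "macro_recall": float(recall.mean()),
        "macro_f1": float(f1.mean()),
    }


@dataclass
class FoldResult:
    classifier: str
    fold: int
    cm: np.ndarray
    metrics: dict[str, Any]
    n_test: int


@dataclass
class EvaluationReport:
    """Per-(classifier, fold) confusion matrices and CVp aggregates."""

    folds: list[FoldResult]
    cv: dict[str, dict[str, float]]  # classifier -> metric -> fold mean (CVp)
    class_names: list[str]
    config: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "class_names": self.class_names,
            "config": self.config,
            "folds": [
                {
                    "classifier": f.classifier,
                    "fold": f.fold,
                    "confusion_matrix": f.cm.tolist(),
                    "accuracy": f.metrics["accuracy"],
                    "precision": list(f.metrics["precision"]),
                    "recall": list(f.metrics["recall"]),
                    "f1": list(f.metrics["f1"]),
                    "n_test": f.n_test,
                }
                for f in self.folds
            ],
            "cv": self.cv,
        }


def stratified_folds(y: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    """Deterministic stratified fold assignment; returns k test-index arrays."""
    rng = np.random.default_rng(seed)
    folds: list[list[np.ndarray]] = [[] for _ in range(k)]
    for code in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == code))
        if len(idx) < k:
            logger.warning("class %s has %d < k=%d samples; folds will be uneven", code, len(idx), k)
        for j, chunk in enumerate(np.array_split(idx, k)):
            folds[j].append(chunk)
    return [np.sort(np.concatenate(f)).astype(np.intp) for f in folds]


def kfold_evaluate(
    data: FeatureMatrix,
    specs: list[ClassifierSpec],
    k: int = 5,
    seed: int = 42,
    smote_mode: str = "guarded",
    smote_k: int = 5,
) -> EvaluationReport:
    """Stratified k-fold cross-validation of the classifier suite.

    In ``guarded`` mode SMOTE and standardization are fit on the k-1
    training folds only and the held-out fold is scored with the
    train-fitted transform.  ``paper_order`` resamples and standardizes
    the full matrix before folding (the leaky published ordering, kept
    for comparison); ``off`` skips SMOTE.  CVp is the unweighted mean of
    each metric across folds.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(data.y):
        raise ValueError(f"k={k} exceeds the {len(data.y)} available samples")
    if smote_mode not in ("guarded", "paper_order", "off"):
        raise ValueError(f"unknown smote_mode {smote_mode!r}")

    if smote_mode == "paper_order":
        full = smote_resample(data, k_neighbors=smote_k, seed=seed)
        full, _, _ = standardize(full)
    else:
        full = data

    fold_idx = stratified_folds(full.y, k, seed)
    all_idx = np.arange(len(full.y))
    results: list[FoldResult] = []
    for fold_no, test_idx in enumerate(fold_idx):
        train_idx = np.setdiff1d(all_idx, test_idx)
        train, test = full.subset(train_idx), full.subset(test_idx)
        if smote_mode == "guarded":
            train = smote_resample(train, k_neighbors=smote_k, seed=seed + fold_no)
            train, (test,), _ = standardize(train, [test])
        elif smote_mode == "off":
            train, (test,), _ = standardize(train, [test])
        for spec in specs:
            model = build_classifier(spec)
            model.fit(train.X, train.y)
            pred = model.predict(test.X)
            cm = confusion_matrix(test.y, pred, data.n_classes)
            results.append(
                FoldResult(
                    classifier=spec.name,
                    fold=fold_no,
                    cm=cm,
                    metrics=confusion_metrics(cm),
                    n_test=len(test.y),
                )
            )

    cv: dict[str, dict[str, float]] = {}
    for spec in specs:
        rows = [r for r in results if r.classifier == spec.name]
        cv[spec.name] = {
            metric: float(np.mean([r.metrics[metric] for r in rows]))
            for metric in ("accuracy", "macro_precision", "macro_recall", "macro_f1")
        }
    return EvaluationReport(
        folds=results,
        cv=cv,
        class_names=list(data.class_names),
        config={"k": k, "seed": seed, "smote_mode": smote_mode, "smote_k": smote_k},
    )
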