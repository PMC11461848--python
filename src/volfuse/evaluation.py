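"""Classical-classifier evaluation with stratified k-fold cross-validation.

Reports the four metrics used throughout: accuracy, macro-averaged
precision, recall and F1 (weighted averaging available by flag), plus a
fold-summed confusion matrix. Precision of a never-predicted class is 0
(with a logged warning) rather than undefined.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

__all__ = ["EvaluationReport", "CLASSIFIERS", "make_classifier",
           "compute_metrics", "kfold_evaluate"]

CLASSIFIERS = ("svm", "knn", "gb", "rf")


def make_classifier(name: str, seed: int = 0):
    if name == "svm":
        return SVC(kernel="rbf", random_state=seed)
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    if name == "gb":
        return GradientBoostingClassifier(n_estimators=100, random_state=seed)
    if name == "rf":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    raise ValueError(f"unknown classifier {name!r}; expected one of {CLASSIFIERS}")


@dataclass
class EvaluationReport:
    classifier: str
    k_folds: int
    per_fold: list[dict]
    mean_metrics: dict
    confusion: np.ndarray
    seed: int
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "classifier": self.classifier,
            "k_folds": self.k_folds,
            "per_fold": self.per_fold,
            "mean_metrics": self.mean_metrics,
            "confusion": self.confusion.astype(int).tolist(),
            "seed": self.seed,
            "config": self.config,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def compute_metrics(y_true, y_pred, average: str = "macro") -> dict:
    """Accuracy + averaged precision/recall/F1 for one prediction set."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("y_true and y_pred must be nonempty with equal length")
    if not set(np.unique(y_pred)) >= set(np.unique(y_true)):
        missing = set(np.unique(y_true)) - set(np.unique(y_pred))
        if missing:
            logger.warning(
                "classes %s never predicted; their precision is scored 0",
                sorted(missing))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        precision, recall, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, average=average, zero_division=0)
    return {
        "accuracy": float((y_true == y_pred).mean()),
        "precision": float(precision),
        "recall": float(recall),
        "f1": float(f1),
    }


def kfold_evaluate(X, y, classifier: str = "gb", k: int = 5, seed: int = 0,
                   average: str = "macro") -> EvaluationReport:
    """Stratified k-fold cross-validation of one classical classifier."""
    x = np.asarray(getattr(X, "values", X), dtype=np.float64)
    y = np.asarray(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("labels must contain at least 2 classes")
    k_eff = k
    if counts.min() < k:
        k_eff = max(2, int(counts.min()))
        logger.warning(
            "smallest class has %d members < k=%d; degrading to %d folds",
            counts.min(), k, k_eff)
    skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
    per_fold = []
    confusion = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for fold_i, (tr, te) in enumerate(skf.split(x, y)):
        clf = make_classifier(classifier, seed=seed)
        clf.fit(x[tr], y[tr])
        pred = clf.predict(x[te])
        metrics = compute_metrics(y[te], pred, average=average)
        metrics["fold"] = fold_i
        per_fold.append(metrics)
        confusion += confusion_matrix(y[te], pred, labels=classes)
    mean_metrics = {m: float(np.mean([f[m] for f in per_fold]))
                    for m in ("accuracy", "precision", "recall", "f1")}
    return EvaluationReport(
        classifier=classifier, k_folds=k_eff, per_fold=per_fold,
        mean_metrics=mean_metrics, confusion=confusion, seed=seed,
        config={"requested_k": k, "average": average})
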