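"""Micro-averaged F1 and grid-searched statistical classifiers.

Micro-F1 pools true positives, false positives and false negatives over all
classes before computing F1, weighting every document equally:

    micro_F1 = 2·ΣTP / (2·ΣTP + ΣFP + ΣFN)

For single-label multiclass prediction each error is simultaneously one FP
and one FN, so micro-F1 reduces to accuracy; it is nevertheless computed
from the pooled tallies so the report also carries per-class counts.

Classification is a linear model trained by stochastic gradient descent
(``sgd_linear``) or a support-vector classifier (``svc``), each wrapped
one-vs-rest and tuned by stratified 10-fold cross-validated grid search on
the training vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import SGDClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.multiclass import OneVsRestClassifier
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

FAMILIES = ("sgd_linear", "svc")

#: Default hyperparameter grids, recorded in the fitted model for provenance.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "sgd_linear": {
        "loss": ["hinge", "log_loss"],
        "alpha": [1e-5, 1e-4, 1e-3, 1e-2, 1e-1],
    },
    "svc": {
        "C": [0.1, 1.0, 10.0, 100.0],
        "kernel": ["linear", "rbf"],
    },
}


@dataclass
class EvaluationReport:
    """Pooled and per-class tallies for single-label multiclass predictions."""

    labels: tuple[str, ...]
    tp: dict[str, int]
    fp: dict[str, int]
    fn: dict[str, int]
    confusion: np.ndarray  # rows gold, columns predicted
    micro_f1: float
    n_documents: int

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "confusion": self.confusion.tolist(),
            "micro_f1": self.micro_f1,
            "n_documents": self.n_documents,
        }


def evaluation_report(
    gold: Sequence[str], pred: Sequence[str], labels: Sequence[str] | None = None
) -> EvaluationReport:
    """Tally TP/FP/FN per class and pool them into micro-F1."""
    if len(gold) != len(pred):
        raise ValueError(f"length mismatch: {len(gold)} gold vs {len(pred)} predicted")
    if len(gold) == 0:
        raise ValueError("cannot evaluate empty label sequences")
    if labels is None:
        labels = sorted(set(gold) | set(pred))
    labels = tuple(labels)
    index = {l: i for i, l in enumerate(labels)}
    confusion = np.zeros((len(labels), len(labels)), dtype=int)
    for g, p in zip(gold, pred):
        confusion[index[g], index[p]] += 1
    tp = {l: int(confusion[i, i]) for l, i in index.items()}
    fp = {l: int(confusion[:, i].sum() - confusion[i, i]) for l, i in index.items()}
    fn = {l: int(confusion[i, :].sum() - confusion[i, i]) for l, i in index.items()}
    sum_tp, sum_fp, sum_fn = sum(tp.values()), sum(fp.values()), sum(fn.values())
    score = 2 * sum_tp / (2 * sum_tp + sum_fp + sum_fn) if sum_tp else 0.0
    return EvaluationReport(
        labels=labels, tp=tp, fp=fp, fn=fn, confusion=confusion,
        micro_f1=score, n_documents=len(gold),
    )


def micro_f1(gold: Sequence[str], pred: Sequence[str]) -> float:
    """Micro-averaged F1 over pooled per-class TP/FP/FN."""
    return evaluation_report(gold, pred).micro_f1


def _normalize_grid(family: str, grid: dict | None) -> dict[str, list]:
    if grid is None:
        grid = DEFAULT_GRIDS[family]
    if not grid or not all(len(v) for v in grid.values()):
        raise ValueError("hyperparameter grid must be non-empty")
    out = {}
    for key, values in grid.items():
        key = key.removeprefix("estimator__")
        if key == "loss":  # accept the historical spelling of logistic loss
            values = ["log_loss" if v == "log" else v for v in values]
        out[f"estimator__{key}"] = list(values)
    return out


class GridSearchTextClassifier(ClassifierMixin, BaseEstimator):
    """One-vs-rest linear-SGD or SVC classifier tuned by stratified CV grid search.

    Parameters
    ----------
    family : {"sgd_linear", "svc"}
        Learner family.
    grid : dict or None
        Hyperparameter grid (plain parameter names); ``None`` uses the
        family's default grid.
    folds : int
        Cross-validation folds; reduced (with a warning) when the smallest
        class has fewer members.
    seed : int
        Controls CV shuffling and SGD; fixed seed means identical
        ``best_params_`` and ``cv_score_`` run to run.  Ties between grid
        points are broken by grid order.

    Attributes
    ----------
    best_params_ : dict — chosen grid point.
    cv_score_ : float — micro-F1 of the chosen point under CV.
    classes_ : ndarray of class labels.
    """

    def __init__(self, family: str = "sgd_linear", grid: dict | None = None,
                 folds: int = 10, seed: int = 0):
        self.family = family
        self.grid = grid
        self.folds = folds
        self.seed = seed

    def _base_estimator(self):
        if self.family == "sgd_linear":
            return SGDClassifier(random_state=self.seed, max_iter=2000, tol=1e-3)
        if self.family == "svc":
            return SVC(random_state=self.seed)
        raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one row per label")
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("training data contains a single class")
        folds = min(self.folds, int(counts.min()))
        if folds < 2:
            raise ValueError(
                f"smallest class has {int(counts.min())} member(s); cannot cross-validate"
            )
        if folds < self.folds:
            logger.warning("reducing CV folds from %d to %d (smallest class size)",
                           self.folds, folds)
        param_grid = _normalize_grid(self.family, self.grid)
        search = GridSearchCV(
            OneVsRestClassifier(self._base_estimator()),
            param_grid=param_grid,
            scoring="f1_micro",
            cv=StratifiedKFold(n_splits=folds, shuffle=True, random_state=self.seed),
            refit=True,
            n_jobs=1,
        )
        search.fit(X, y)
        self.best_params_ = {
            k.removeprefix("estimator__"): v for k, v in search.best_params_.items()
        }
        self.cv_score_ = float(search.best_score_)
        self.cv_folds_ = folds
        self.classes_ = search.best_estimator_.classes_
        self.n_features_in_ = X.shape[1]
        self.best_estimator_ = search.best_estimator_
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected vectors of dimension {self.n_features_in_}, got shape {X.shape}"
            )
        return self.best_estimator_.predict(X)


def grid_search_fit(
    vectors, labels, family: str = "sgd_linear", grid: dict | None = None,
    folds: int = 10, seed: int = 0,
) -> GridSearchTextClassifier:
    """Fit a :class:`GridSearchTextClassifier` on document vectors."""
    return GridSearchTextClassifier(family=family, grid=grid, folds=folds, seed=seed).fit(
        vectors, labels
    )


def predict(model: GridSearchTextClassifier, vectors) -> list[str]:
    return list(model.predict(vectors))
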