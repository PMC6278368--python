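"""Fingerprint-classification benchmarking.

Runs a panel of standard binary classifiers (kNN, logistic regression,
naive Bayes, a one-hidden-layer MLP, linear SVM, random forest and a
decision tree, at the study's hyperparameters) over binary fingerprint
matrices, evaluating by stratified 10-fold cross-validation and on an
external test set with sensitivity, specificity, overall accuracy and
ROC AUC:

    SE = TP/(TP+FN),  SP = TN/(TN+FP),  CA = (TP+TN)/total.

Out-of-fold predictions are pooled before metrics are computed, so the
cross-validation confusion counts are integers over the whole training
set.  The learners themselves are delegated to scikit-learn; the
metrics and the harness are owned here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import BernoulliNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "ConfusionCounts",
    "ClassifMetrics",
    "LearnerSpec",
    "DEFAULT_LEARNERS",
    "confusion_metrics",
    "roc_auc",
    "run_cv",
    "evaluate_external",
    "rank_models",
]


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class ClassifMetrics:
    model: str
    counts: ConfusionCounts
    se: float
    sp: float
    ca: float
    auc: float | None = None
    failed: bool = False


def confusion_metrics(counts: ConfusionCounts, model: str = "") -> ClassifMetrics:
    """SE/SP/CA from a confusion matrix."""
    if counts.total == 0:
        raise ValueError("empty confusion matrix")
    if counts.tp + counts.fn == 0:
        raise ValueError("no positives: sensitivity undefined")
    if counts.tn + counts.fp == 0:
        raise ValueError("no negatives: specificity undefined")
    return ClassifMetrics(
        model=model,
        counts=counts,
        se=counts.tp / (counts.tp + counts.fn),
        sp=counts.tn / (counts.tn + counts.fp),
        ca=(counts.tp + counts.tn) / counts.total,
    )


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve via the Mann-Whitney statistic.

    Equivalent to the trapezoidal area under the TP-rate/FP-rate curve;
    the rank formulation handles ties by mid-rank averaging (scores
    identical for all compounds give 0.5).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class LearnerSpec:
    """One classifier with the study's hyperparameters.

    ``method`` is one of kNN, LR, NB, ANN, SVM, RF, Tree.  Defaults:
    kNN k=5 distance-weighted Euclidean; ANN a single hidden layer of
    200 neurons; SVM linear kernel with cost 1.00 (RBF available via
    ``params``); RF 20 trees; Tree minimum 3 instances per leaf, no
    splitting below 5.
    """

    method: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def build(self):
        m = self.method
        p = dict(self.params)
        if m == "kNN":
            return KNeighborsClassifier(
                n_neighbors=p.pop("k", 5), weights="distance", metric="euclidean", **p
            )
        if m == "LR":
            return LogisticRegression(max_iter=p.pop("max_iter", 1000), **p)
        if m == "NB":
            return BernoulliNB(**p)
        if m == "ANN":
            return MLPClassifier(
                hidden_layer_sizes=p.pop("hidden", (200,)),
                max_iter=p.pop("max_iter", 300),
                random_state=self.seed,
                **p,
            )
        if m == "SVM":
            return SVC(kernel=p.pop("kernel", "linear"), C=p.pop("C", 1.0),
                       random_state=self.seed, **p)
        if m == "RF":
            return RandomForestClassifier(
                n_estimators=p.pop("n_trees", 20), random_state=self.seed, **p
            )
        if m == "Tree":
            return DecisionTreeClassifier(
                min_samples_leaf=p.pop("min_leaf", 3),
                min_samples_split=p.pop("min_split", 5),
                random_state=self.seed,
                **p,
            )
        raise ValueError(f"unknown learner method {self.method!r}")


DEFAULT_LEARNERS = ("kNN", "LR", "NB", "ANN", "SVM", "RF", "Tree")


def _scores(clf, X: np.ndarray) -> np.ndarray:
    # class-probability output where available, decision values otherwise
    if hasattr(clf, "predict_proba"):
        proba = clf.predict_proba(X)
        return proba[:, list(clf.classes_).index(1)]
    return clf.decision_function(X)


def _to_binary(labels: pd.Series | np.ndarray) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "UOS":
        return (arr == "P").astype(int)
    return arr.astype(int)


def run_cv(
    fingerprints: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    learners: Sequence[LearnerSpec] | None = None,
    folds: int = 10,
    seed: int = 0,
) -> list[ClassifMetrics]:
    """Stratified k-fold cross-validation of a learner panel.

    Out-of-fold predictions are pooled into a single confusion matrix
    and a single AUC per learner.  Fold assignment is deterministic
    under ``seed``.  A learner failing on any fold is returned with
    ``failed=True`` instead of aborting the benchmark.
    """
    if learners is None:
        learners = [LearnerSpec(m, seed=seed) for m in DEFAULT_LEARNERS]
    X = fingerprints.to_numpy(dtype=float)
    y = _to_binary(labels)
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise ValueError(
            f"need at least {folds} compounds per class for {folds}-fold CV"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    split = list(skf.split(X, y))

    results = []
    for spec in learners:
        pred = np.empty_like(y)
        score = np.empty(len(y), dtype=float)
        ok = True
        for tr, te in split:
            try:
                clf = spec.build()
                clf.fit(X[tr], y[tr])
                pred[te] = clf.predict(X[te])
                score[te] = _scores(clf, X[te])
            except Exception:  # noqa: BLE001 - learner failure is data, not a crash
                ok = False
                break
        if not ok:
            results.append(
                ClassifMetrics(
                    model=spec.method,
                    counts=ConfusionCounts(0, 0, 0, 0),
                    se=float("nan"), sp=float("nan"), ca=float("nan"),
                    failed=True,
                )
            )
            continue
        cc = ConfusionCounts(
            tp=int(((pred == 1) & (y == 1)).sum()),
            tn=int(((pred == 0) & (y == 0)).sum()),
            fp=int(((pred == 1) & (y == 0)).sum()),
            fn=int(((pred == 0) & (y == 1)).sum()),
        )
        metrics = confusion_metrics(cc, model=spec.method)
        metrics.auc = roc_auc(score, y)
        results.append(metrics)
    return results


def evaluate_external(
    X_train: pd.DataFrame,
    y_train: pd.Series | np.ndarray,
    X_test: pd.DataFrame,
    y_test: pd.Series | np.ndarray,
    learners: Sequence[LearnerSpec] | None = None,
    seed: int = 0,
) -> list[ClassifMetrics]:
    """Fit on the training set, evaluate on the external test set."""
    if learners is None:
        learners = [LearnerSpec(m, seed=seed) for m in DEFAULT_LEARNERS]
    Xtr, Xte = X_train.to_numpy(dtype=float), X_test.to_numpy(dtype=float)
    ytr, yte = _to_binary(y_train), _to_binary(y_test)
    results = []
    for spec in learners:
        clf = spec.build()
        clf.fit(Xtr, ytr)
        pred = clf.predict(Xte)
        cc = ConfusionCounts(
            tp=int(((pred == 1) & (yte == 1)).sum()),
            tn=int(((pred == 0) & (yte == 0)).sum()),
            fp=int(((pred == 1) & (yte == 0)).sum()),
            fn=int(((pred == 0) & (yte == 1)).sum()),
        )
        metrics = confusion_metrics(cc, model=spec.method)
        metrics.auc = roc_auc(_scores(clf, Xte), yte)
        results.append(metrics)
    return results


def rank_models(metrics: Sequence[ClassifMetrics], top_n: int = 10) -> list[ClassifMetrics]:
    """Rank by AUC descending, ties by CA descending, then model name."""
    if not metrics:
        raise ValueError("no models to rank")
    usable = [m for m in metrics if not m.failed]
    ordered = sorted(
        usable, key=lambda m: (-(m.auc if m.auc is not None else -1), -m.ca, m.model)
    )
    return ordered[:top_n]


def metrics_table(metrics: Sequence[ClassifMetrics]) -> pd.DataFrame:
    """Flat report: CA, AUC, SE, SP, TP, TN, FP, FN per model."""
    rows = [
        {
            "model": m.model,
            "CA": round(m.ca, 3),
            "AUC": None if m.auc is None else round(m.auc, 3),
            "SE": round(m.se, 2),
            "SP": round(m.sp, 2),
            "TP": m.counts.tp,
            "TN": m.counts.tn,
            "FP": m.counts.fp,
            "FN": m.counts.fn,
        }
        for m in metrics
        if not m.failed
    ]
    return pd.DataFrame(rows)
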