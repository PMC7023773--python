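"""Cross-validated classification of feature tables and the hemisphere
summary.

Four classifier families are supported — RBF support vector machine,
5-nearest-neighbour with Euclidean distance, Gaussian naive Bayes, and
maximum-likelihood logistic regression — evaluated with stratified k-fold
cross-validation (default 5 folds, no validation split).  Features are
z-scored per fold with statistics fit on the training folds only, since
SVM and KNN are scale-sensitive and the feature bank spans orders of
magnitude.  The seizure class is the positive class (label 1).

Metrics are confusion-derived percentages: accuracy, sensitivity,
specificity, precision, and the F-score (harmonic mean of precision and
sensitivity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, NamedTuple, Sequence, Tuple

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureTable
from .synthetic import CHANNELS_LEFT, CHANNELS_RIGHT

__all__ = [
    "CLASSIFIERS",
    "POSITIVE_LABEL",
    "ConfusionCounts",
    "Metrics",
    "CVResult",
    "make_classifier",
    "compute_metrics",
    "cross_validate",
    "hemisphere_summary",
]

POSITIVE_LABEL = "seizure"

CLASSIFIERS = ("svm", "knn", "naive_bayes", "logistic_regression")


def make_classifier(name: str, seed: int = 0, *, svm_kernel: str = "rbf"):
    """Instantiate one of the four supported classifier families."""
    if name == "svm":
        return SVC(kernel=svm_kernel, random_state=seed)
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=5, metric="euclidean")
    if name == "naive_bayes":
        return GaussianNB()
    if name == "logistic_regression":
        return LogisticRegression(max_iter=2000, random_state=seed)
    raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIERS}")


@dataclass
class ConfusionCounts:
    """Binary confusion counts; seizure (class 1) is positive."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
        )


class Metrics(NamedTuple):
    acc: float
    sen: float
    spe: float
    pre: float
    f: float


def compute_metrics(c: ConfusionCounts) -> Metrics:
    """Accuracy, sensitivity, specificity, precision and F-score, in %.

    Any metric with a zero denominator (e.g. no positives in a fold) is
    reported as the NaN sentinel rather than an arbitrary value.
    """
    if c.total == 0:
        raise ValueError("empty confusion matrix")

    def ratio(num: int, den: int) -> float:
        return 100.0 * num / den if den > 0 else np.nan

    acc = ratio(c.tp + c.tn, c.total)
    sen = ratio(c.tp, c.tp + c.fn)
    spe = ratio(c.tn, c.fp + c.tn)
    pre = ratio(c.tp, c.tp + c.fp)
    if np.isfinite(pre) and np.isfinite(sen) and (pre + sen) > 0:
        f = 2.0 * pre * sen / (pre + sen)
    else:
        f = np.nan
    return Metrics(acc, sen, spe, pre, f)


@dataclass
class CVResult:
    """Per-fold and aggregate confusion-derived metrics for one
    classifier/feature-table pairing."""

    classifier_name: str
    per_fold: List[ConfusionCounts]
    per_fold_metrics: List[Metrics]
    mean_metrics: Metrics
    seed: int
    feature_group: str = ""
    component_set: str = ""

    @property
    def mean_acc(self) -> float:
        return self.mean_metrics.acc

    @property
    def mean_f(self) -> float:
        return self.mean_metrics.f

    def pooled_confusion(self) -> ConfusionCounts:
        total = ConfusionCounts()
        for c in self.per_fold:
            total = total + c
        return total


def _binary_labels(labels: np.ndarray) -> np.ndarray:
    return (np.asarray(labels) == POSITIVE_LABEL).astype(int)


def cross_validate(
    table: FeatureTable,
    classifier: str = "svm",
    folds: int = 5,
    seed: int = 0,
    *,
    feature_group: str = "",
    component_set: str = "",
) -> CVResult:
    """Stratified k-fold cross-validation of one classifier on a table.

    Each fold is held out once; the classifier (preceded by a
    StandardScaler fit on the training folds only) is trained on the
    rest, and the held-out confusion counts are recorded.  The mean
    metrics are the arithmetic means of the per-fold metrics.  The fold
    partition is seeded and stratified, so results are reproducible and
    every fold contains both classes.
    """
    x = np.asarray(table.values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("feature table contains non-finite values")
    y = _binary_labels(table.labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need both classes present for cross-validation")
    if counts.min() < folds:
        raise ValueError(
            f"need at least {folds} samples per class, got {counts.min()}"
        )
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    per_fold: List[ConfusionCounts] = []
    per_fold_metrics: List[Metrics] = []
    for train_idx, test_idx in splitter.split(x, y):
        model = Pipeline(
            [
                ("scale", StandardScaler()),
                ("clf", make_classifier(classifier, seed=seed)),
            ]
        )
        model.fit(x[train_idx], y[train_idx])
        pred = model.predict(x[test_idx])
        truth = y[test_idx]
        c = ConfusionCounts(
            tp=int(np.sum((pred == 1) & (truth == 1))),
            tn=int(np.sum((pred == 0) & (truth == 0))),
            fp=int(np.sum((pred == 1) & (truth == 0))),
            fn=int(np.sum((pred == 0) & (truth == 1))),
        )
        per_fold.append(c)
        per_fold_metrics.append(compute_metrics(c))
    with warnings.catch_warnings():
        # a metric can be NaN in every fold (e.g. degenerate predictions)
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_metrics = Metrics(
            *(float(np.nanmean([m[i] for m in per_fold_metrics])) for i in range(5))
        )
    return CVResult(
        classifier_name=classifier,
        per_fold=per_fold,
        per_fold_metrics=per_fold_metrics,
        mean_metrics=mean_metrics,
        seed=seed,
        feature_group=feature_group,
        component_set=component_set,
    )


def hemisphere_summary(
    per_channel_results: Dict[str, "CVResult | float"],
) -> Tuple[float, float]:
    """Mean accuracy over the left and right hemisphere channel sets.

    Accepts per-channel CVResults (their mean accuracy is used) or bare
    accuracy values, keyed by channel name.  Unknown channel names are an
    error; channels missing from one hemisphere simply do not enter that
    mean.
    """
    known = set(CHANNELS_LEFT) | set(CHANNELS_RIGHT)
    unknown = set(per_channel_results) - known
    if unknown:
        raise ValueError(f"unknown channel names: {sorted(unknown)}")

    def acc(v) -> float:
        return v.mean_acc if isinstance(v, CVResult) else float(v)

    left = [acc(v) for ch, v in per_channel_results.items() if ch in CHANNELS_LEFT]
    right = [acc(v) for ch, v in per_channel_results.items() if ch in CHANNELS_RIGHT]
    if not left or not right:
        raise ValueError("need at least one channel per hemisphere")
    return float(np.mean(left)), float(np.mean(right))
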