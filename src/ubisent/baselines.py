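"""Classical baseline classifiers trained on the same 500-dim features.

Four comparison models, configured as in the study they benchmark:

- ``svm``: RBF-kernel support vector classifier with balanced class
  weights; AUC scores come from the decision function (rank-based, no
  probability calibration refit);
- ``logreg``: L2-penalized logistic regression;
- ``rf``: random forest, 100 trees, Gini criterion, bootstrap sampling;
- ``mlp``: feed-forward network with ReLU activation and 150 hidden
  units (one hidden layer of width 150 by default; a literal stack of
  150 layers is available via ``hidden_layer_sizes`` for fidelity
  experiments).

All baselines consume the identical feature matrix as the LSTM
classifier.  Evaluation uses 10-fold cross-validation over consecutive,
unshuffled folds of near-equal size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from ubisent.metrics import MetricsReport, compute_metrics, confusion, roc_auc

__all__ = [
    "BaselineSpec",
    "BASELINE_KINDS",
    "make_baseline",
    "train_baseline",
    "baseline_scores",
    "consecutive_folds",
    "cross_validate_10fold",
]

BASELINE_KINDS = ("svm", "logreg", "rf", "mlp")


@dataclass(frozen=True)
class BaselineSpec:
    """Which baseline to build, with hyperparameter overrides."""

    kind: str
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in BASELINE_KINDS:
            raise ValueError(f"unknown baseline kind {self.kind!r}; choose from {BASELINE_KINDS}")


def make_baseline(spec: BaselineSpec):
    """Instantiate the scikit-learn estimator for a baseline spec."""
    hp = dict(spec.hyperparameters)
    if spec.kind == "svm":
        return SVC(kernel="rbf", class_weight="balanced", random_state=spec.seed, **hp)
    if spec.kind == "logreg":
        hp.setdefault("max_iter", 1000)
        # default penalty is the L2 regularizer
        return LogisticRegression(**hp)
    if spec.kind == "rf":
        return RandomForestClassifier(
            n_estimators=100,
            criterion="gini",
            bootstrap=True,
            random_state=spec.seed,
            **hp,
        )
    if spec.kind == "mlp":
        hp.setdefault("hidden_layer_sizes", (150,))
        hp.setdefault("max_iter", 500)
        return MLPClassifier(activation="relu", random_state=spec.seed, **hp)
    raise ValueError(f"unknown baseline kind {spec.kind!r}")


def train_baseline(spec: BaselineSpec, X, y):
    """Fit the baseline on (X, y); requires both classes present."""
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("training set must contain both classes")
    return make_baseline(spec).fit(X, y)


def baseline_scores(model, X) -> np.ndarray:
    """Continuous positive-class scores for AUC (decision function or P(+))."""
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(X), dtype=np.float64)
    return np.asarray(model.predict_proba(X)[:, 1], dtype=np.float64)


def consecutive_folds(n: int, k: int = 10) -> list[np.ndarray]:
    """Partition indices 0..n-1 into k consecutive, unshuffled folds.

    Fold sizes differ by at most one (the first ``n % k`` folds take the
    extra item), and every index lands in exactly one fold.
    """
    if n < k:
        raise ValueError(f"need at least {k} items, got {n}")
    base, extra = divmod(n, k)
    folds = []
    start = 0
    for i in range(k):
        size = base + (1 if i < extra else 0)
        folds.append(np.arange(start, start + size))
        start += size
    return folds


def cross_validate_10fold(
    spec: BaselineSpec, X, y, k: int = 10
) -> tuple[list[MetricsReport], MetricsReport]:
    """Consecutive unshuffled k-fold CV; returns per-fold and averaged metrics.

    Each fold serves as the held-out set exactly once; the k metric sets
    are averaged indicator-wise (NaNs ignored in the mean so an undefined
    fold ratio does not zero out the average).
    """
    X = np.asarray(X)
    y = np.asarray(y)
    reports = []
    for fold in consecutive_folds(len(y), k):
        mask = np.ones(len(y), dtype=bool)
        mask[fold] = False
        model = train_baseline(spec, X[mask], y[mask])
        pred = model.predict(X[fold])
        scores = baseline_scores(model, X[fold])
        reports.append(
            compute_metrics(confusion(y[fold], pred), roc_auc=roc_auc(y[fold], scores))
        )
    keys = ("accuracy", "precision", "recall", "specificity", "f1", "roc_auc")
    means = {}
    for key in keys:
        vals = [getattr(r, key) for r in reports]
        finite = [v for v in vals if not math.isnan(v)]
        means[key] = float(np.mean(finite)) if finite else math.nan
    return reports, MetricsReport(**means)
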