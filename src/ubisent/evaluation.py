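"""Experiment drivers: held-out evaluation, epoch sweep, dimension sweep.

The epoch sweep retrains the LSTM classifier at each epoch count on a
grid (2, 4, ..., 30 by default — 15 points), repeating each point over
several seeded runs (5 by default) and averaging every indicator over
the runs, on both the training and the test partition.  The dimension
sweep rebuilds the representation at total widths 100..1000 (channel
width = total/5) and evaluates each.  Results come back as tidy
DataFrames with one row per (grid value, partition).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ubisent.corpus import AnnotatedSentence
from ubisent.lstm import LSTMSentenceClassifier
from ubisent.metrics import MetricsReport, compute_metrics, confusion, roc_auc
from ubisent.representation import RepresentationBuilder, expand_instances

__all__ = [
    "SweepResult",
    "evaluate_model",
    "epoch_sweep",
    "dimension_sweep",
    "DEFAULT_EPOCH_GRID",
    "DEFAULT_DIMENSION_GRID",
]

#: Epoch counts 2..30 in steps of 2 (15 grid points).
DEFAULT_EPOCH_GRID = tuple(range(2, 31, 2))

#: Total representation widths; 500 is the default model, the rest probe it.
DEFAULT_DIMENSION_GRID = (100, 200, 300, 400, 500, 600, 700, 800, 900, 1000)

_METRIC_KEYS = ("accuracy", "precision", "recall", "specificity", "f1", "roc_auc")


@dataclass(frozen=True)
class SweepResult:
    """Averaged metrics per grid point and partition."""

    axis: str
    grid: tuple
    runs: int
    seeds: tuple[int, ...]
    table: pd.DataFrame

    def metric(self, axis_value, partition: str, key: str) -> float:
        row = self.table[
            (self.table["axis_value"] == axis_value) & (self.table["partition"] == partition)
        ]
        return float(row[key].iloc[0])


def evaluate_model(model, X, y) -> MetricsReport:
    """Confusion-count metrics plus AUC from the model's positive scores."""
    y = np.asarray(y)
    pred = np.asarray(model.predict(X))
    if hasattr(model, "predict_proba"):
        scores = np.asarray(model.predict_proba(X))[:, 1]
    else:
        scores = pred.astype(float)
    return compute_metrics(confusion(y, pred), roc_auc=roc_auc(y, scores))


def _mean_report(reports: Sequence[MetricsReport]) -> dict[str, float]:
    out = {}
    for key in _METRIC_KEYS:
        vals = [getattr(r, key) for r in reports]
        finite = [v for v in vals if not math.isnan(v)]
        out[key] = float(np.mean(finite)) if finite else math.nan
    return out


def _derive_seeds(base_seed: int, runs: int) -> tuple[int, ...]:
    # Fixed offsets from the base seed keep the repeated runs reproducible.
    return tuple((base_seed + 10007 * (r + 1)) % (2**31) for r in range(runs))


def epoch_sweep(
    X_train,
    y_train,
    X_test,
    y_test,
    epochs_grid: Sequence[int] = DEFAULT_EPOCH_GRID,
    runs: int = 5,
    base_seed: int = 0,
    **classifier_kwargs,
) -> SweepResult:
    """Retrain at each epoch count, average metrics over seeded runs.

    For every value in ``epochs_grid`` the classifier is trained ``runs``
    times with distinct derived seeds and evaluated on both partitions;
    each indicator is averaged over the runs.
    """
    if not epochs_grid:
        raise ValueError("epochs_grid must be non-empty")
    if runs < 1:
        raise ValueError("runs must be >= 1")
    seeds = _derive_seeds(base_seed, runs)
    rows = []
    for n_epochs in epochs_grid:
        per_part: dict[str, list[MetricsReport]] = {"train": [], "test": []}
        for seed in seeds:
            model = LSTMSentenceClassifier(
                epochs=int(n_epochs), seed=int(seed), **classifier_kwargs
            )
            model.fit(X_train, y_train)
            per_part["train"].append(evaluate_model(model, X_train, y_train))
            per_part["test"].append(evaluate_model(model, X_test, y_test))
        for partition in ("train", "test"):
            rows.append(
                {"axis_value": n_epochs, "partition": partition}
                | _mean_report(per_part[partition])
            )
    return SweepResult(
        axis="epochs",
        grid=tuple(epochs_grid),
        runs=runs,
        seeds=seeds,
        table=pd.DataFrame(rows),
    )


def dimension_sweep(
    train_corpus: Sequence[AnnotatedSentence],
    test_corpus: Sequence[AnnotatedSentence],
    dims: Sequence[int] = DEFAULT_DIMENSION_GRID,
    seed: int = 0,
    epochs: int = 10,
    runs: int = 1,
    **builder_kwargs,
) -> SweepResult:
    """Rebuild the representation at each total width and evaluate.

    Every width must be divisible by 5 (five equal channels); width 500
    corresponds to the default channel width of 100.
    """
    for dim in dims:
        if dim % 5 != 0:
            raise ValueError(f"dimension {dim} is not divisible by 5")
    seeds = _derive_seeds(seed, runs)
    instances_train, y_train = expand_instances(train_corpus)
    instances_test, y_test = expand_instances(test_corpus)
    rows = []
    for dim in dims:
        builder = RepresentationBuilder(channel_dim=dim // 5, **builder_kwargs)
        X_train = builder.fit(instances_train).transform(instances_train)
        X_test = builder.transform(instances_test)
        per_part: dict[str, list[MetricsReport]] = {"train": [], "test": []}
        for s in seeds:
            model = LSTMSentenceClassifier(epochs=epochs, seed=int(s))
            model.fit(X_train, y_train)
            per_part["train"].append(evaluate_model(model, X_train, y_train))
            per_part["test"].append(evaluate_model(model, X_test, y_test))
        for partition in ("train", "test"):
            rows.append(
                {"axis_value": dim, "partition": partition} | _mean_report(per_part[partition])
            )
    return SweepResult(
        axis="input_dim", grid=tuple(dims), runs=runs, seeds=seeds, table=pd.DataFrame(rows)
    )
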