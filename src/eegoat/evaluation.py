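"""Repeated stratified cross-validation and the full metric suite.

Metrics are computed on the pooled out-of-fold predictions, so with k=10
on the 300-row feature matrix the confusion matrix covers the whole
dataset, mirroring the whole-dataset form of published per-class tables.
Per class (one-vs-rest reduction): sensitivity, specificity, precision,
F-measure and ROC area; overall: accuracy, class-frequency-weighted
aggregates, Cohen's kappa and the mean absolute error of the probability
estimates.  All implementations are self-contained; the test suite
cross-checks them against scikit-learn.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .classifiers import ClassifierSpec, fit_model, ordered_classes
from .eeg_io import FeatureMatrix
from .exceptions import ValidationError


@dataclass
class FoldPlan:
    """A stratified partition of instance indices into k folds."""

    folds: list[np.ndarray]
    seed: int
    n_instances: int

    def __post_init__(self) -> None:
        joined = np.concatenate(self.folds) if self.folds else np.empty(0, int)
        if np.sort(joined).size != self.n_instances or np.unique(joined).size != joined.size:
            raise ValidationError("folds must partition all instances exactly once")


@dataclass
class ConfusionMatrix:
    """counts[actual class][predicted class] over a fixed class list."""

    counts: np.ndarray
    classes: Sequence

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        J = len(self.classes)
        if self.counts.shape != (J, J):
            raise ValidationError("confusion matrix shape does not match class list")
        if np.any(self.counts < 0):
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class PerformanceReport:
    """Per-class and overall metrics (percent scale except kappa/MAE/ROC)."""

    classifier: str
    per_class: dict[str, dict[str, float]]
    overall: dict[str, float]
    confusion: list[list[float]]
    metadata: dict[str, Any] = field(default_factory=dict)
    per_repeat: list[dict[str, float]] | None = None
    std: dict[str, float] | None = None

    def to_dict(self) -> dict:
        out = {
            "classifier": self.classifier,
            "per_class": self.per_class,
            "overall": self.overall,
            "confusion": self.confusion,
            "metadata": self.metadata,
        }
        if self.per_repeat is not None:
            out["per_repeat"] = self.per_repeat
            out["std"] = self.std
        return out

    def to_json(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    def to_csv(self, path) -> None:
        """Per-class rows in the published column order, plus an Overall row."""
        import pandas as pd

        cols = ["sensitivity_pct", "specificity_pct", "precision_pct",
                "f_measure_pct", "roc_auc"]
        rows = {c: [self.per_class[c][m] for m in cols] for c in self.per_class}
        rows["Overall"] = [
            self.overall["sensitivity_pct"],
            self.overall["specificity_pct"],
            self.overall["precision_pct"],
            self.overall["f_measure_pct"],
            self.overall["roc_auc"],
        ]
        df = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
        df["total_accuracy_pct"] = self.overall["accuracy_pct"]
        df.index.name = "class"
        df.to_csv(path)


def make_stratified_folds(labels, k: int, seed: int) -> FoldPlan:
    """Stratified k-fold partition; per-class counts differ by ≤1 across folds."""
    labels = np.asarray(labels)
    n = labels.size
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k == 1:
        return FoldPlan([np.arange(n)], seed, n)
    classes, counts = np.unique(labels, return_counts=True)
    small = classes[counts < k]
    if small.size:
        raise ValidationError(
            f"classes {small.tolist()} have fewer than k={k} members"
        )
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for c in classes:
        members = np.flatnonzero(labels == c)
        members = members[rng.permutation(members.size)]
        for pos, idx in enumerate(members):
            folds[pos % k].append(int(idx))
    return FoldPlan([np.sort(np.array(f, dtype=int)) for f in folds], seed, n)


def confusion_from_predictions(actual, predicted, classes=None) -> ConfusionMatrix:
    """Accumulate counts per (actual, predicted) label pair."""
    actual = np.asarray(actual)
    predicted = np.asarray(predicted)
    if actual.size != predicted.size:
        raise ValidationError("actual and predicted lengths differ")
    if classes is None:
        classes = ordered_classes(np.concatenate([actual, predicted]))
    classes = np.asarray(classes)
    index = {label: i for i, label in enumerate(classes.tolist())}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for a, p in zip(actual.tolist(), predicted.tolist()):
        if a not in index or p not in index:
            raise ValidationError(f"unknown label in predictions: {a!r}/{p!r}")
        counts[index[a], index[p]] += 1
    return ConfusionMatrix(counts, classes.tolist())


def class_metrics(cm: ConfusionMatrix, c) -> dict[str, float]:
    """One-vs-rest sensitivity/specificity/precision/F for class c (fractions).

    0/0 cases return 0.0 and set the ``undefined`` flag.
    """
    classes = list(cm.classes)
    if c not in classes:
        raise ValidationError(f"class {c!r} not in confusion matrix")
    i = classes.index(c)
    counts = cm.counts.astype(float)
    tp = counts[i, i]
    fn = counts[i].sum() - tp
    fp = counts[:, i].sum() - tp
    tn = counts.sum() - tp - fn - fp
    undefined = False

    def ratio(num, den):
        nonlocal undefined
        if den == 0:
            undefined = True
            return 0.0
        return num / den

    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    prec = ratio(tp, tp + fp)
    f = ratio(2 * prec * sens, prec + sens)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "f_measure": f,
        "undefined": undefined,
    }


def roc_auc_ovr(scores: np.ndarray, positives: np.ndarray) -> float:
    """One-vs-rest ROC area by the trapezoidal rule over all thresholds.

    ``scores`` are the probability estimates for the positive class and
    ``positives`` a boolean indicator.  Returns NaN when only one side is
    present (the class weight is then zero in any weighted aggregate).
    """
    scores = np.asarray(scores, dtype=float)
    positives = np.asarray(positives, dtype=bool)
    n_pos = int(positives.sum())
    n_neg = positives.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    tps = np.cumsum(positives[order])
    fps = np.cumsum(~positives[order])
    # keep only threshold boundaries (last index of each tied score block)
    boundary = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    tpr = np.r_[0.0, tps[boundary] / n_pos]
    fpr = np.r_[0.0, fps[boundary] / n_neg]
    return float(np.trapezoid(tpr, fpr))


def overall_metrics(
    cm: ConfusionMatrix, proba: np.ndarray, actual
) -> dict[str, float]:
    """Accuracy, kappa, probability MAE, weighted aggregates and ROC areas.

    Fractions throughout; callers convert to percent for reporting.
    """
    counts = cm.counts.astype(float)
    total = counts.sum()
    if total == 0:
        raise ValidationError("empty confusion matrix")
    accuracy = float(np.trace(counts) / total)
    p_o = accuracy
    p_e = float((counts.sum(axis=1) * counts.sum(axis=0)).sum() / total**2)
    kappa = 0.0 if p_e == 1.0 else (p_o - p_e) / (1.0 - p_e)

    classes = list(cm.classes)
    actual = np.asarray(actual)
    proba = np.asarray(proba, dtype=float)
    if proba.shape != (actual.size, len(classes)):
        raise ValidationError("probability matrix shape mismatch")
    if np.any(np.abs(proba.sum(axis=1) - 1.0) > 1e-6):
        raise ValidationError("probability rows must sum to 1")
    onehot = np.array([[1.0 if a == c else 0.0 for c in classes] for a in actual])
    mae = float(np.mean(np.abs(proba - onehot)))

    weights = counts.sum(axis=1) / total  # actual class frequencies
    per_class = {c: class_metrics(cm, c) for c in classes}
    aucs = {
        c: roc_auc_ovr(proba[:, j], onehot[:, j].astype(bool))
        for j, c in enumerate(classes)
    }
    finite_auc = np.array(
        [aucs[c] if np.isfinite(aucs[c]) else 0.0 for c in classes]
    )

    def weighted(metric: str) -> float:
        vals = np.array([per_class[c][metric] for c in classes])
        return float(np.sum(weights * vals))

    return {
        "accuracy": accuracy,
        "kappa": float(kappa),
        "mae": mae,
        "sensitivity": weighted("sensitivity"),
        "specificity": weighted("specificity"),
        "precision": weighted("precision"),
        "f_measure": weighted("f_measure"),
        "roc_auc": float(np.sum(weights * finite_auc)),
        "per_class_roc": aucs,
    }


def _report_from_pooled(
    classifier: str,
    classes: Sequence,
    actual: np.ndarray,
    predicted: np.ndarray,
    proba: np.ndarray,
    metadata: dict,
) -> PerformanceReport:
    cm = confusion_from_predictions(actual, predicted, classes=classes)
    overall = overall_metrics(cm, proba, actual)
    per_class = {}
    for c in classes:
        m = class_metrics(cm, c)
        per_class[str(c)] = {
            "sensitivity_pct": 100 * m["sensitivity"],
            "specificity_pct": 100 * m["specificity"],
            "precision_pct": 100 * m["precision"],
            "f_measure_pct": 100 * m["f_measure"],
            "roc_auc": overall["per_class_roc"][c],
        }
    overall_out = {
        "accuracy_pct": 100 * overall["accuracy"],
        "sensitivity_pct": 100 * overall["sensitivity"],
        "specificity_pct": 100 * overall["specificity"],
        "precision_pct": 100 * overall["precision"],
        "f_measure_pct": 100 * overall["f_measure"],
        "roc_auc": overall["roc_auc"],
        "kappa": overall["kappa"],
        "mae": overall["mae"],
    }
    return PerformanceReport(
        classifier=classifier,
        per_class=per_class,
        overall=overall_out,
        confusion=cm.counts.tolist(),
        metadata=metadata,
    )


def cross_validate(
    fm: FeatureMatrix, spec: ClassifierSpec, k: int = 10, seed: int = 0
) -> PerformanceReport:
    """Stratified k-fold CV; metrics from the pooled out-of-fold predictions."""
    X = fm.X
    y = fm.labels
    classes = ordered_classes(y)
    plan = make_stratified_folds(y, k, seed)
    n = len(y)
    proba = np.zeros((n, classes.size))
    predicted = np.empty(n, dtype=object)
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(1,))
    fold_seeds = (ss.generate_state(max(k, 1)) % 2**31).tolist()
    for fold_i, test_idx in enumerate(plan.folds):
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        if not train_mask.any():  # k=1: train and test on everything
            train_mask[:] = True
        model = fit_model(spec, X[train_mask], y[train_mask], seed=fold_seeds[fold_i])
        P = model.predict_proba(X[test_idx])
        # align model's class columns with the global canonical order
        col = {label: j for j, label in enumerate(model.classes_.tolist())}
        for j, label in enumerate(classes.tolist()):
            if label in col:
                proba[test_idx, j] = P[:, col[label]]
        predicted[test_idx] = model.predict(X[test_idx])
    metadata = {
        "k": k,
        "seed": int(seed),
        "fold_sizes": [int(f.size) for f in plan.folds],
        "n_instances": n,
    }
    return _report_from_pooled(
        spec.name, classes.tolist(), y, predicted, proba, metadata
    )


_MEAN_KEYS = (
    "accuracy_pct",
    "sensitivity_pct",
    "specificity_pct",
    "precision_pct",
    "f_measure_pct",
    "roc_auc",
    "kappa",
    "mae",
)


def repeat_experiment(
    fm: FeatureMatrix,
    spec: ClassifierSpec,
    k: int = 10,
    n_repeats: int = 20,
    base_seed: int = 0,
) -> PerformanceReport:
    """Average every metric over n_repeats cross-validation runs.

    Per-repeat overall metrics are retained and the standard deviation is
    reported alongside each mean.
    """
    if n_repeats < 1:
        raise ValidationError("n_repeats must be >= 1")
    seeds = (
        np.random.SeedSequence(entropy=base_seed).generate_state(n_repeats) % 2**31
    ).tolist()
    reports = [cross_validate(fm, spec, k=k, seed=s) for s in seeds]
    if n_repeats == 1:
        only = reports[0]
        only.per_repeat = [dict(only.overall)]
        only.std = {m: 0.0 for m in _MEAN_KEYS}
        return only

    per_repeat = [dict(r.overall) for r in reports]
    overall = {
        m: float(np.mean([r.overall[m] for r in reports])) for m in _MEAN_KEYS
    }
    std = {m: float(np.std([r.overall[m] for r in reports])) for m in _MEAN_KEYS}
    classes = list(reports[0].per_class)
    per_class = {
        c: {
            m: float(np.mean([r.per_class[c][m] for r in reports]))
            for m in reports[0].per_class[c]
        }
        for c in classes
    }
    confusion = np.mean([np.asarray(r.confusion) for r in reports], axis=0)
    metadata = {
        "k": k,
        "n_repeats": n_repeats,
        "base_seed": int(base_seed),
        "repeat_seeds": [int(s) for s in seeds],
        "n_instances": reports[0].metadata["n_instances"],
    }
    return PerformanceReport(
        classifier=spec.name,
        per_class=per_class,
        overall=overall,
        confusion=confusion.tolist(),
        metadata=metadata,
        per_repeat=per_repeat,
        std=std,
    )
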