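"""Confusion matrices, one-vs-rest class metrics, and robustness reports.

Per-class performance is measured one-vs-rest: each class in turn is the
positive class, every other class pools into the negative class, and
TP/FP/FN/TN are tallied from the confusion matrix. Metrics are reported in
percent:

    sensitivity = 100 * TP / (TP + FN)       specificity = 100 * TN / (TN + FP)
    precision   = 100 * TP / (TP + FP)       accuracy    = 100 * (TP + TN) / n
    F1          = harmonic mean of precision and sensitivity

A zero denominator leaves the metric *undefined* (NaN, flagged), never 0 or
100. Internal values keep full precision; :func:`display_round` rounds half
away from zero to one decimal for display.

Robustness of the movement classifiers is probed by repeating stratified
k-fold cross-validation several times with different shuffles, with and
without SMOTE augmentation of the training folds, and reporting mean +/- SD
of accuracy, precision, sensitivity and macro F1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .imbalance import LabeledFeatureSet, smote_oversample
from .schema import ClassLabel, Movement, movement_feature_indices

METRIC_COLUMNS = ("accuracy", "precision", "sensitivity", "specificity", "f1")


def display_round(value: float, decimals: int = 1) -> float:
    """Round half away from zero (display convention for percent metrics)."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return float("nan")
    factor = 10**decimals
    return math.copysign(math.floor(abs(value) * factor + 0.5) / factor, value)


def _as_symbol(label) -> str:
    return label.symbol if isinstance(label, ClassLabel) else str(label)


@dataclass
class ConfusionMatrix:
    """Square count matrix: rows = true class, columns = predicted class."""

    classes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{k} classes"
            )
        if (self.counts < 0).any():
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def micro_accuracy(self) -> float:
        """Overall fraction correct, in percent: 100 * trace / n."""
        return 100.0 * np.trace(self.counts) / self.n

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.classes), columns=list(self.classes)
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ConfusionMatrix":
        return cls(classes=tuple(str(c) for c in df.columns), counts=df.to_numpy())


def confusion_matrix(y_true, y_pred, class_order) -> ConfusionMatrix:
    """Tally (true, predicted) pairs into a matrix over ``class_order``."""
    true_s = [_as_symbol(l) for l in y_true]
    pred_s = [_as_symbol(l) for l in y_pred]
    if len(true_s) != len(pred_s):
        raise ValueError(
            f"length mismatch: {len(true_s)} true vs {len(pred_s)} predicted"
        )
    classes = tuple(_as_symbol(c) for c in class_order)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(true_s, pred_s):
        if t not in index:
            raise ValueError(f"true label {t!r} not in class order {classes}")
        if p not in index:
            raise ValueError(f"predicted label {p!r} not in class order {classes}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(classes=classes, counts=counts)


@dataclass
class ClassMetrics:
    """One-vs-rest metrics per class, in percent, with undefined cells flagged.

    ``table`` has one row per class with TP/FP/FN/TN and the five metrics;
    ``undefined`` lists (class, metric) pairs whose denominator was zero.
    """

    table: pd.DataFrame
    undefined: list[tuple[str, str]] = field(default_factory=list)

    def value(self, class_symbol: str, metric: str) -> float:
        return float(self.table.loc[class_symbol, metric])

    def macro(self, metric: str) -> float:
        """Unweighted mean over classes, ignoring undefined cells."""
        return float(self.table[metric].mean(skipna=True))


def per_class_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    """Compute one-vs-rest TP/FP/FN/TN and percent metrics for every class."""
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    n = cm.n
    rows = []
    undefined: list[tuple[str, str]] = []

    def ratio(num: float, den: float, cls: str, metric: str) -> float:
        if den == 0:
            undefined.append((cls, metric))
            return float("nan")
        return 100.0 * num / den

    for i, cls in enumerate(cm.classes):
        tp = int(cm.counts[i, i])
        fn = int(cm.counts[i, :].sum() - tp)
        fp = int(cm.counts[:, i].sum() - tp)
        tn = n - tp - fn - fp
        acc = ratio(tp + tn, n, cls, "accuracy")
        prec = ratio(tp, tp + fp, cls, "precision")
        sens = ratio(tp, tp + fn, cls, "sensitivity")
        spec = ratio(tn, tn + fp, cls, "specificity")
        if math.isnan(prec) or math.isnan(sens) or (prec + sens) == 0:
            undefined.append((cls, "f1"))
            f1 = float("nan")
        else:
            f1 = 2 * prec * sens / (prec + sens)
        rows.append((cls, tp, fp, fn, tn, acc, prec, sens, spec, f1))
    table = pd.DataFrame(
        rows,
        columns=["class", "TP", "FP", "FN", "TN", *METRIC_COLUMNS],
    ).set_index("class")
    return ClassMetrics(table=table, undefined=undefined)


def summary_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Aggregate view: macro one-vs-rest metrics plus micro accuracy (percent)."""
    per_class = per_class_metrics(cm)
    out = {f"macro_{m}": per_class.macro(m) for m in METRIC_COLUMNS}
    out["micro_accuracy"] = cm.micro_accuracy()
    return out


# ---------------------------------------------------------------------------
# Robustness protocol: repeated k-fold CV with and without augmentation
# ---------------------------------------------------------------------------

ROBUSTNESS_METRICS = ("accuracy", "precision", "sensitivity", "f1")


def _fold_metrics(y_true, y_pred, classes) -> dict[str, float]:
    cm = confusion_matrix(y_true, y_pred, classes)
    per_class = per_class_metrics(cm)
    return {
        "accuracy": cm.micro_accuracy(),
        "precision": per_class.macro("precision"),
        "sensitivity": per_class.macro("sensitivity"),
        "f1": per_class.macro("f1"),
    }


def cv_robustness(
    data: LabeledFeatureSet,
    movement_params: dict[Movement, dict],
    folds: int = 5,
    repetitions: int = 5,
    augment: bool = False,
    augment_scope: str = "dataset",
    smote_k: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Repeated stratified k-fold CV of the per-movement SVM classifiers.

    Each repetition reshuffles the fold assignment. When ``augment`` is set,
    SMOTE runs either on the whole dataset before folding
    (``augment_scope="dataset"``, the original study's protocol — synthetic
    rows then also appear in validation folds) or on the training folds only
    (``augment_scope="fold"``, leakage-safe; validation folds keep the real
    class imbalance, so micro accuracy can drop even as minority recall
    improves). Returns one row per (movement, metric) with the
    per-repetition values, their mean and their standard deviation.
    """
    from .classifiers import train_movement_classifier

    if repetitions < 2:
        raise ValueError("robustness needs at least 2 repetitions")
    if augment_scope not in ("dataset", "fold"):
        raise ValueError(f"unknown augment_scope {augment_scope!r}")
    if augment and augment_scope == "dataset":
        data = smote_oversample(data, k=smote_k, seed=seed)
    symbols = np.array([l.symbol for l in data.labels])
    classes = tuple(dict.fromkeys(symbols))
    rows = []
    for movement, params in movement_params.items():
        idx = list(movement_feature_indices(movement))
        per_rep: dict[str, list[float]] = {m: [] for m in ROBUSTNESS_METRICS}
        for rep in range(repetitions):
            cv = StratifiedKFold(
                n_splits=folds, shuffle=True, random_state=seed + rep
            )
            y_true_all: list[str] = []
            y_pred_all: list[str] = []
            for fold_i, (tr, va) in enumerate(cv.split(data.matrix, symbols)):
                train = data.subset(tr)
                if augment and augment_scope == "fold":
                    train = smote_oversample(
                        train, k=smote_k, seed=seed + 1000 * rep + fold_i
                    )
                clf = train_movement_classifier(
                    movement,
                    train.matrix[:, idx],
                    train.labels,
                    params=params,
                    seed=seed,
                )
                preds = clf.predict(data.matrix[np.ix_(va, idx)])
                y_true_all.extend(symbols[va])
                y_pred_all.extend(p.symbol for p in preds)
            fm = _fold_metrics(y_true_all, y_pred_all, classes)
            for m in ROBUSTNESS_METRICS:
                per_rep[m].append(fm[m])
        for m in ROBUSTNESS_METRICS:
            vals = np.array(per_rep[m], dtype=float)
            rows.append(
                (
                    movement.value,
                    m,
                    augment,
                    vals.mean(),
                    vals.std(ddof=0),
                    list(vals),
                )
            )
    return pd.DataFrame(
        rows,
        columns=["movement", "metric", "augmented", "mean", "std", "values"],
    )


def robustness_report(
    data: LabeledFeatureSet,
    movement_params: dict[Movement, dict],
    folds: int = 5,
    repetitions: int = 5,
    augment_scope: str = "dataset",
    smote_k: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Both robustness conditions (with and without augmentation), stacked."""
    parts = [
        cv_robustness(
            data,
            movement_params,
            folds=folds,
            repetitions=repetitions,
            augment=augment,
            augment_scope=augment_scope,
            smote_k=smote_k,
            seed=seed,
        )
        for augment in (False, True)
    ]
    return pd.concat(parts, ignore_index=True)
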