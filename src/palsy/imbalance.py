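"""Preprocessing half of the hybrid class-imbalance strategy.

Healthy controls vastly outnumber patients, and the patient classes are
themselves uneven. Two resampling steps rebalance the training data:

* random undersampling of the majority (normal) class, removing rows
  uniformly at random without replacement;
* SMOTE oversampling of every minority class up to the majority count. A
  synthetic sample is ``x_i + u * (x_nn - x_i)`` with ``u ~ Uniform(0, 1)``,
  where ``x_i`` is a uniformly chosen seed row of the class and ``x_nn`` one
  of its k nearest same-class neighbours (Euclidean distance in feature
  space).

The third technique of the strategy — decision-threshold moving — lives in
:mod:`palsy.classifiers` because it acts on classifier probabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .schema import ClassLabel


@dataclass
class LabeledFeatureSet:
    """Feature matrix with labels and per-row provenance.

    Provenance is ``"original"`` for measured rows and ``"synthetic"`` for
    rows created by SMOTE.
    """

    matrix: np.ndarray
    labels: list[ClassLabel]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D")
        if len(self.labels) != self.matrix.shape[0]:
            raise ValueError(
                f"label count {len(self.labels)} != row count {self.matrix.shape[0]}"
            )
        if not self.provenance:
            self.provenance = ["original"] * self.matrix.shape[0]
        elif len(self.provenance) != self.matrix.shape[0]:
            raise ValueError("provenance length mismatch")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for label in self.labels:
            counts[label.symbol] = counts.get(label.symbol, 0) + 1
        return counts

    def rows_of(self, label: ClassLabel) -> np.ndarray:
        return np.array([i for i, l in enumerate(self.labels) if l == label])

    def subset(self, indices: np.ndarray) -> "LabeledFeatureSet":
        indices = np.asarray(indices, dtype=int)
        return LabeledFeatureSet(
            matrix=self.matrix[indices],
            labels=[self.labels[i] for i in indices],
            provenance=[self.provenance[i] for i in indices],
        )


def random_undersample(
    data: LabeledFeatureSet,
    target_class: ClassLabel,
    target_n: int,
    seed: int = 0,
) -> LabeledFeatureSet:
    """Reduce ``target_class`` to ``target_n`` rows chosen uniformly at random.

    All other classes pass through untouched and row order of the kept rows
    is preserved. Raises ``ValueError`` if the class has fewer than
    ``target_n`` rows.
    """
    class_rows = data.rows_of(target_class)
    if target_n > len(class_rows):
        raise ValueError(
            f"cannot undersample {target_class.symbol} to {target_n}: "
            f"only {len(class_rows)} rows present"
        )
    rng = np.random.default_rng(seed)
    keep_class = rng.choice(class_rows, size=target_n, replace=False)
    keep = np.sort(
        np.concatenate(
            [
                keep_class,
                np.array(
                    [i for i, l in enumerate(data.labels) if l != target_class],
                    dtype=int,
                ),
            ]
        ).astype(int)
    )
    return data.subset(keep)


def smote_oversample(
    data: LabeledFeatureSet, k: int = 5, seed: int = 0
) -> LabeledFeatureSet:
    """Oversample every class to the majority-class count with SMOTE.

    Original rows are preserved verbatim (and first, in input order);
    synthetic rows are appended with provenance ``"synthetic"``. Neighbour
    search uses the class's original rows only. A class with fewer than two
    rows raises; ``k`` larger than ``class size - 1`` is reduced with a
    warning.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    counts = data.class_counts()
    if not counts:
        return data
    majority = max(counts.values())
    rng = np.random.default_rng(seed)

    new_rows: list[np.ndarray] = []
    new_labels: list[ClassLabel] = []
    seen: set[str] = set()
    for label in data.labels:
        if label.symbol in seen:
            continue
        seen.add(label.symbol)
        deficit = majority - counts[label.symbol]
        if deficit == 0:
            continue
        rows = data.rows_of(label)
        if len(rows) < 2:
            raise ValueError(
                f"class {label.symbol} has {len(rows)} sample(s); "
                "SMOTE needs at least 2"
            )
        k_eff = k
        if k_eff >= len(rows):
            k_eff = len(rows) - 1
            warnings.warn(
                f"class {label.symbol}: k={k} >= class size {len(rows)}; "
                f"using k={k_eff}",
                stacklevel=2,
            )
        X = data.matrix[rows]
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(X)
        # column 0 is the point itself; keep the k_eff true neighbours
        neighbor_idx = nn.kneighbors(X, return_distance=False)[:, 1:]
        seeds = rng.integers(0, len(rows), size=deficit)
        which = rng.integers(0, k_eff, size=deficit)
        u = rng.uniform(0.0, 1.0, size=deficit)
        for s, w, ui in zip(seeds, which, u):
            x_i = X[s]
            x_nn = X[neighbor_idx[s, w]]
            new_rows.append(x_i + ui * (x_nn - x_i))
            new_labels.append(label)

    if not new_rows:
        return data
    return LabeledFeatureSet(
        matrix=np.vstack([data.matrix, np.asarray(new_rows)]),
        labels=list(data.labels) + new_labels,
        provenance=list(data.provenance) + ["synthetic"] * len(new_rows),
    )
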