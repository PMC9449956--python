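"""First-level learners: per-movement classifiers and threshold post-processing.

Each voluntary facial movement gets its own classifier trained only on that
movement's feature subset (6 symmetry indices plus 2-3 grades). RBF-kernel
SVMs are the primary model, with C and gamma chosen by exhaustive grid
search over logarithmic ranges scored by stratified five-fold
cross-validation accuracy. K-nearest-neighbours and random forests serve as
baselines swept over their own canonical grids.

Features are standardized (training statistics) before SVM and K-NN fits;
random forests are fit unscaled. Probability estimates come from Platt-scaled
pairwise coupling and feed the third imbalance technique: *threshold moving*.
If the normal class wins the argmax but with probability below the threshold
(default 0.4) it is excluded and the second-ranked class is returned,
demoting over-confident normal calls caused by the class imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .schema import ClassLabel, Movement, label_from_symbol, movement_feature_indices

#: Hyperparameter ranges swept for the RBF SVM: C over 1e-3..1e8, gamma over
#: 1e-3..1e3 (84 combinations).
DEFAULT_C_GRID: tuple[float, ...] = tuple(10.0**e for e in range(-3, 9))
DEFAULT_GAMMA_GRID: tuple[float, ...] = tuple(10.0**e for e in range(-3, 4))

#: Reduced 4x4 subgrid for fast end-to-end runs.
SMALL_C_GRID: tuple[float, ...] = (1.0, 10.0, 100.0, 1000.0)
SMALL_GAMMA_GRID: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0)

#: Baseline sweeps: K-NN neighbour counts and the random-forest grid.
KNN_K_RANGE: tuple[int, ...] = tuple(range(1, 10))
RF_MAX_DEPTH_GRID: tuple[int, ...] = tuple(range(1, 11))
RF_N_ESTIMATORS_GRID: tuple[int, ...] = (5, 10, 20, 30, 50, 100)

#: Default probability threshold below which a winning normal call is demoted.
DEFAULT_THRESHOLD = 0.4

NORMAL_SYMBOL = "N"


def _symbols(labels) -> np.ndarray:
    return np.array(
        [l.symbol if isinstance(l, ClassLabel) else str(l) for l in labels]
    )


def _check_multiclass(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes to train a classifier")


def _cv_splitter(y: np.ndarray, folds: int, seed: int) -> StratifiedKFold:
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"stratified {folds}-fold CV needs >= {folds} samples per class; "
            f"smallest class has {counts.min()}"
        )
    return StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)


@dataclass
class GridSearchResult:
    """Outcome of an exhaustive (C, gamma) sweep.

    ``table`` holds one row per grid cell: C, gamma, mean CV accuracy. Ties
    on accuracy are broken toward the smallest C, then the smallest gamma.
    """

    best_C: float
    best_gamma: float
    cv_accuracy: float
    table: pd.DataFrame = field(repr=False)


def grid_search_svm(
    features: np.ndarray,
    labels,
    C_grid=DEFAULT_C_GRID,
    gamma_grid=DEFAULT_GAMMA_GRID,
    folds: int = 5,
    seed: int = 0,
) -> GridSearchResult:
    """Exhaustive RBF-SVM hyperparameter search by stratified k-fold CV."""
    X = np.asarray(features, dtype=float)
    y = _symbols(labels)
    _check_multiclass(y)
    cv = _cv_splitter(y, folds, seed)
    splits = list(cv.split(X, y))  # same folds for every cell

    rows = []
    best = (-np.inf, np.inf, np.inf)  # (accuracy, C, gamma) with tie-breaks
    for C in sorted(C_grid):
        for gamma in sorted(gamma_grid):
            model = Pipeline(
                [
                    ("scale", StandardScaler()),
                    ("svc", SVC(kernel="rbf", C=C, gamma=gamma)),
                ]
            )
            acc = cross_val_score(model, X, y, cv=splits, scoring="accuracy").mean()
            rows.append((C, gamma, acc))
            if (acc, -C, -gamma) > (best[0], -best[1], -best[2]):
                best = (acc, C, gamma)
    table = pd.DataFrame(rows, columns=["C", "gamma", "cv_accuracy"])
    return GridSearchResult(
        best_C=best[1], best_gamma=best[2], cv_accuracy=best[0], table=table
    )


@dataclass
class TrainedMovementClassifier:
    """A fitted classifier for one movement's feature subset."""

    movement: Movement
    kind: str  # "svm_rbf" | "knn" | "random_forest"
    params: dict
    model: Pipeline | RandomForestClassifier
    classes: tuple[str, ...]
    n_features: int

    def _check_arity(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"{self.movement.value} classifier expects {self.n_features} "
                f"features, got {X.shape[1]}"
            )
        return X

    def predict(self, X: np.ndarray) -> list[ClassLabel]:
        X = self._check_arity(X)
        return [label_from_symbol(s) for s in self.model.predict(X)]

    def predict_proba(self, X: np.ndarray) -> list[dict[str, float]]:
        """Per-sample probability vectors keyed by class symbol (sum to 1)."""
        X = self._check_arity(X)
        probs = self.model.predict_proba(X)
        order = list(self.model.classes_)
        return [dict(zip(order, row)) for row in probs]


def train_movement_classifier(
    movement: Movement,
    subset_features: np.ndarray,
    labels,
    params: dict | None = None,
    kind: str = "svm_rbf",
    seed: int = 0,
) -> TrainedMovementClassifier:
    """Fit a movement classifier on that movement's feature subset.

    ``subset_features`` must have exactly the movement's arity (8 columns, 9
    for whistling). ``params`` carries the model hyperparameters (e.g. C and
    gamma for the SVM).
    """
    params = dict(params or {})
    expected = len(movement_feature_indices(movement))
    X = np.asarray(subset_features, dtype=float)
    if X.ndim != 2 or X.shape[1] != expected:
        raise ValueError(
            f"{movement.value} subset must have {expected} columns, "
            f"got shape {X.shape}"
        )
    y = _symbols(labels)
    _check_multiclass(y)

    if kind == "svm_rbf":
        # Platt-scaled pairwise-coupled probabilities via sigmoid calibration;
        # unshuffled stratified folds keep the fit deterministic.
        _, class_counts = np.unique(y, return_counts=True)
        calib_cv = int(min(5, class_counts.min()))
        if calib_cv < 2:
            raise ValueError(
                "probability calibration needs >= 2 samples in every class"
            )
        svc = SVC(
            kernel="rbf",
            C=params.get("C", 1.0),
            gamma=params.get("gamma", "scale"),
            random_state=seed,
        )
        model: Pipeline | RandomForestClassifier = Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "svc",
                    CalibratedClassifierCV(
                        svc, method="sigmoid", cv=calib_cv, ensemble=False
                    ),
                ),
            ]
        )
    elif kind == "knn":
        model = Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "knn",
                    KNeighborsClassifier(n_neighbors=params.get("n_neighbors", 5)),
                ),
            ]
        )
    elif kind == "random_forest":
        model = RandomForestClassifier(
            max_depth=params.get("max_depth"),
            n_estimators=params.get("n_estimators", 100),
            random_state=seed,
        )
    else:
        raise ValueError(f"unknown classifier kind {kind!r}")

    model.fit(X, y)
    return TrainedMovementClassifier(
        movement=movement,
        kind=kind,
        params=params,
        model=model,
        classes=tuple(model.classes_),
        n_features=expected,
    )


def predict_with_threshold(
    prob: dict[str, float], threshold: float = DEFAULT_THRESHOLD
) -> ClassLabel:
    """Apply the threshold-moving rule to one probability vector.

    Returns the argmax class, except when the argmax is the normal class with
    probability below ``threshold``: then the second-ranked class is returned.
    """
    if not prob:
        raise ValueError("empty probability vector")
    # deterministic ranking: by probability descending, symbol as tie-break
    ranked = sorted(prob.items(), key=lambda kv: (-kv[1], kv[0]))
    top_symbol, top_p = ranked[0]
    if top_symbol == NORMAL_SYMBOL and top_p < threshold and len(ranked) > 1:
        return label_from_symbol(ranked[1][0])
    return label_from_symbol(top_symbol)


def evaluate_baselines(
    features: np.ndarray,
    labels,
    seed: int = 0,
    folds: int = 5,
    movements=None,
) -> dict:
    """Baseline sweeps per movement: K-NN accuracy curve and random-forest grid.

    ``features`` is the full 41-column matrix; each movement's subset is
    extracted internally. Returns ``{"knn": {movement: DataFrame(k, cv_accuracy)},
    "rf": {movement: DataFrame(max_depth, n_estimators, cv_accuracy)}}``.
    """
    from .schema import ACTIVE_MOVEMENTS

    X_full = np.asarray(features, dtype=float)
    y = _symbols(labels)
    _check_multiclass(y)
    movements = tuple(movements) if movements is not None else ACTIVE_MOVEMENTS
    cv = _cv_splitter(y, folds, seed)
    splits = None

    report: dict = {"knn": {}, "rf": {}}
    for movement in movements:
        idx = list(movement_feature_indices(movement))
        X = X_full[:, idx]
        if splits is None:
            splits = list(cv.split(X, y))
        knn_rows = []
        for k in KNN_K_RANGE:
            model = Pipeline(
                [
                    ("scale", StandardScaler()),
                    ("knn", KNeighborsClassifier(n_neighbors=k)),
                ]
            )
            acc = cross_val_score(model, X, y, cv=splits, scoring="accuracy").mean()
            knn_rows.append((k, acc))
        report["knn"][movement] = pd.DataFrame(
            knn_rows, columns=["k", "cv_accuracy"]
        )

        rf_rows = []
        for depth in RF_MAX_DEPTH_GRID:
            for n_est in RF_N_ESTIMATORS_GRID:
                model = RandomForestClassifier(
                    max_depth=depth, n_estimators=n_est, random_state=seed
                )
                acc = cross_val_score(
                    model, X, y, cv=splits, scoring="accuracy"
                ).mean()
                rf_rows.append((depth, n_est, acc))
        report["rf"][movement] = pd.DataFrame(
            rf_rows, columns=["max_depth", "n_estimators", "cv_accuracy"]
        )
    return report
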