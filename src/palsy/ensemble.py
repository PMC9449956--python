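"""Second-level learner and end-to-end pipeline orchestration.

The second level is a deterministic rule-based combiner over the five
movement classifiers' votes:

1. a strict majority (>= 3 votes) wins outright;
2. a unique plurality at 2 votes wins;
3. two classes tied at 2 votes: if exactly one of them is the normal class
   it is dropped and the other wins (the combiner, like the threshold rule,
   is biased against over-calling "normal"); otherwise the tied class with
   the larger probability mass summed over the five classifiers wins;
4. five distinct votes: the class with the highest summed probability wins.

The applied branch is recorded in the prediction's ``rationale`` so every
ensemble decision is auditable.

:func:`run_pipeline` chains the whole procedure: feature transform ->
majority-class undersampling -> stratified split -> SMOTE on the training
part -> per-movement grid search and SVM training -> thresholded first-level
prediction -> vote combination -> evaluation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifiers import (
    DEFAULT_C_GRID,
    DEFAULT_GAMMA_GRID,
    DEFAULT_THRESHOLD,
    GridSearchResult,
    TrainedMovementClassifier,
    grid_search_svm,
    predict_with_threshold,
    train_movement_classifier,
)
from .cohort import SubjectRecord
from .evaluation import (
    ClassMetrics,
    ConfusionMatrix,
    confusion_matrix,
    per_class_metrics,
    summary_metrics,
)
from .features import feature_table
from .imbalance import LabeledFeatureSet, random_undersample, smote_oversample
from .schema import (
    ACTIVE_MOVEMENTS,
    NORMAL,
    ClassLabel,
    Movement,
    label_from_symbol,
    movement_feature_indices,
)

NORMAL_SYMBOL = NORMAL.symbol


@dataclass
class EnsemblePrediction:
    """One combined decision with its full audit trail."""

    movement_labels: dict[str, ClassLabel]
    movement_probs: dict[str, dict[str, float]]
    vote_counts: dict[str, int]
    final: ClassLabel
    rationale: str  # majority | plurality | tie_rule_a | tie_rule_b | prob_sum_fallback


def _summed_probs(probs: list[dict[str, float]]) -> dict[str, float]:
    total: dict[str, float] = {}
    for p in probs:
        for symbol, v in p.items():
            total[symbol] = total.get(symbol, 0.0) + v
    return total


def combine_votes(
    predictions: list[ClassLabel],
    probs: list[dict[str, float]],
    movements=ACTIVE_MOVEMENTS,
) -> EnsemblePrediction:
    """Fuse the five first-level votes into a final class (rules above)."""
    if len(predictions) != 5 or len(probs) != 5:
        raise ValueError(
            f"expected 5 predictions and 5 probability vectors, "
            f"got {len(predictions)} and {len(probs)}"
        )
    votes = Counter(p.symbol for p in predictions)
    top_count = max(votes.values())
    summed = _summed_probs(probs)

    def by_prob(symbols) -> str:
        # larger summed probability wins; symbol order breaks exact ties
        return max(sorted(symbols), key=lambda s: summed.get(s, 0.0))

    if top_count >= 3:
        final = [s for s, c in votes.items() if c == top_count][0]
        rationale = "majority"
    elif top_count == 2:
        tied = sorted(s for s, c in votes.items() if c == 2)
        if len(tied) == 1:
            final = tied[0]
            rationale = "plurality"
        elif NORMAL_SYMBOL in tied:
            final = [s for s in tied if s != NORMAL_SYMBOL][0]
            rationale = "tie_rule_a"
        else:
            final = by_prob(tied)
            rationale = "tie_rule_b"
    else:
        final = by_prob(summed.keys())
        rationale = "prob_sum_fallback"

    movement_names = [
        m.value if isinstance(m, Movement) else str(m) for m in movements
    ]
    return EnsemblePrediction(
        movement_labels=dict(zip(movement_names, predictions)),
        movement_probs=dict(zip(movement_names, probs)),
        vote_counts=dict(votes),
        final=label_from_symbol(final),
        rationale=rationale,
    )


def stratified_split(
    data: LabeledFeatureSet, ratio: float = 0.8, seed: int = 0
) -> tuple[LabeledFeatureSet, LabeledFeatureSet]:
    """Split into (train+validation, test) preserving class proportions.

    ``ratio`` is the train+validation share. The test allocation rounds down
    per class, and the remaining slots (to reach ``round(n * (1 - ratio))``)
    go to the classes with the largest fractional remainders, keeping every
    class within one sample of its exact proportion. Every class needs at
    least 2 samples.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError(f"ratio must be in (0, 1), got {ratio}")
    counts = data.class_counts()
    singletons = sorted(s for s, c in counts.items() if c < 2)
    if singletons:
        raise ValueError(f"class(es) with fewer than 2 samples: {singletons}")
    test_frac = 1.0 - ratio
    symbols = sorted(counts)
    base = {s: int(np.floor(counts[s] * test_frac)) for s in symbols}
    remainder = {s: counts[s] * test_frac - base[s] for s in symbols}
    target_total = int(round(data.n * test_frac))
    extra = max(target_total - sum(base.values()), 0)
    for s in sorted(symbols, key=lambda s: (-remainder[s], s))[:extra]:
        base[s] += 1

    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    train_idx: list[int] = []
    for s in symbols:
        rows = np.array(
            [i for i, l in enumerate(data.labels) if l.symbol == s], dtype=int
        )
        rng.shuffle(rows)
        n_test = min(base[s], len(rows) - 1)  # never empty the training side
        test_idx.extend(rows[:n_test].tolist())
        train_idx.extend(rows[n_test:].tolist())
    return data.subset(np.sort(train_idx)), data.subset(np.sort(test_idx))


@dataclass
class PipelineConfig:
    """End-to-end run settings.

    ``undersample_target`` caps the normal class before splitting (None
    disables). SMOTE runs on the training part only unless
    ``augment_before_split`` reproduces the alternative, leakage-prone order.
    ``threshold_at_first_level`` applies the 0.4 rule at each movement
    classifier before voting (default); otherwise votes are plain argmax.
    """

    split_ratio: float = 0.8
    folds: int = 5
    seed: int = 0
    undersample_target: int | None = 289
    smote: bool = True
    smote_k: int = 5
    augment_before_split: bool = False
    threshold: float = DEFAULT_THRESHOLD
    threshold_at_first_level: bool = True
    C_grid: tuple[float, ...] = DEFAULT_C_GRID
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID
    normalized_asi: bool = False

    def validate(self) -> None:
        if not 0.0 < self.split_ratio < 1.0:
            raise ValueError(f"split_ratio must be in (0, 1): {self.split_ratio}")
        if self.folds < 2:
            raise ValueError(f"folds must be >= 2: {self.folds}")


@dataclass
class EvaluationReport:
    """Everything a pipeline run produced."""

    confusion: ConfusionMatrix
    class_metrics: ClassMetrics
    ensemble_summary: dict[str, float]
    classifier_metrics: pd.DataFrame
    hyperparameters: dict[str, dict]
    grid_results: dict[str, GridSearchResult] = field(repr=False, default_factory=dict)
    predictions: list[EnsemblePrediction] = field(repr=False, default_factory=list)
    n_features: int = 0
    seeds: dict[str, int] = field(default_factory=dict)


def _first_level_vote(
    clf: TrainedMovementClassifier,
    X: np.ndarray,
    threshold: float,
    use_threshold: bool,
) -> tuple[list[ClassLabel], list[dict[str, float]]]:
    probs = clf.predict_proba(X)
    if use_threshold:
        labels = [predict_with_threshold(p, threshold) for p in probs]
    else:
        labels = [
            label_from_symbol(max(sorted(p), key=lambda s: p[s])) for p in probs
        ]
    return labels, probs


def run_pipeline(
    config: PipelineConfig, records: list[SubjectRecord]
) -> EvaluationReport:
    """Run the full classification procedure on a cohort of records."""
    config.validate()
    seeds = {
        "undersample": config.seed,
        "split": config.seed + 1,
        "smote": config.seed + 2,
        "model": config.seed + 3,
        "grid": config.seed + 4,
    }

    table = feature_table(records, normalized_asi=config.normalized_asi)
    feature_cols = [c for c in table.columns if c not in ("record_id", "label")]
    data = LabeledFeatureSet(
        matrix=table[feature_cols].to_numpy(),
        labels=[label_from_symbol(s) for s in table["label"]],
    )

    if config.undersample_target is not None:
        n_normal = data.class_counts().get(NORMAL_SYMBOL, 0)
        if n_normal > config.undersample_target:
            data = random_undersample(
                data, NORMAL, config.undersample_target, seed=seeds["undersample"]
            )

    if config.smote and config.augment_before_split:
        data = smote_oversample(data, k=config.smote_k, seed=seeds["smote"])
    train, test = stratified_split(data, ratio=config.split_ratio, seed=seeds["split"])
    if config.smote and not config.augment_before_split:
        train = smote_oversample(train, k=config.smote_k, seed=seeds["smote"])

    class_order = tuple(
        dict.fromkeys(l.symbol for l in data.labels)
    )

    classifiers: dict[Movement, TrainedMovementClassifier] = {}
    grid_results: dict[str, GridSearchResult] = {}
    hyperparameters: dict[str, dict] = {}
    movement_votes: dict[Movement, list[ClassLabel]] = {}
    movement_probs: dict[Movement, list[dict[str, float]]] = {}
    per_classifier_rows = []
    y_test = [l.symbol for l in test.labels]

    for movement in ACTIVE_MOVEMENTS:
        idx = list(movement_feature_indices(movement))
        X_train = train.matrix[:, idx]
        gs = grid_search_svm(
            X_train,
            train.labels,
            C_grid=config.C_grid,
            gamma_grid=config.gamma_grid,
            folds=config.folds,
            seed=seeds["grid"],
        )
        grid_results[movement.value] = gs
        params = {"C": gs.best_C, "gamma": gs.best_gamma}
        hyperparameters[movement.value] = {**params, "cv_accuracy": gs.cv_accuracy}
        clf = train_movement_classifier(
            movement, X_train, train.labels, params=params, seed=seeds["model"]
        )
        classifiers[movement] = clf

        labels, probs = _first_level_vote(
            clf,
            test.matrix[:, idx],
            config.threshold,
            config.threshold_at_first_level,
        )
        movement_votes[movement] = labels
        movement_probs[movement] = probs

        cm = confusion_matrix(y_test, [l.symbol for l in labels], class_order)
        row = {"movement": movement.value, **summary_metrics(cm)}
        per_classifier_rows.append(row)

    predictions = [
        combine_votes(
            [movement_votes[m][i] for m in ACTIVE_MOVEMENTS],
            [movement_probs[m][i] for m in ACTIVE_MOVEMENTS],
        )
        for i in range(test.n)
    ]
    y_pred = [p.final.symbol for p in predictions]
    cm = confusion_matrix(y_test, y_pred, class_order)
    ens_summary = summary_metrics(cm)
    per_classifier_rows.append({"movement": "ensemble", **ens_summary})

    return EvaluationReport(
        confusion=cm,
        class_metrics=per_class_metrics(cm),
        ensemble_summary=ens_summary,
        classifier_metrics=pd.DataFrame(per_classifier_rows),
        hyperparameters=hyperparameters,
        grid_results=grid_results,
        predictions=predictions,
        n_features=len(feature_cols),
        seeds=seeds,
    )
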