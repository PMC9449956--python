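"""Vote combiner, stratified splitting, and the end-to-end pipeline."""

import itertools

import numpy as np
import pytest

from palsy import (
    CohortConfig,
    LabeledFeatureSet,
    PipelineConfig,
    combine_votes,
    generate_cohort,
    run_pipeline,
    stratified_split,
)
from palsy.classifiers import SMALL_C_GRID, SMALL_GAMMA_GRID
from palsy.schema import ALL_LABELS, label_from_symbol

SYMBOLS = ("N", "L_MI", "R_MI", "R_MO", "R_S")


def uniform_probs(n=5):
    return [{s: 1 / len(SYMBOLS) for s in SYMBOLS} for _ in range(n)]


def probs_favoring(symbol, n=5):
    out = []
    for _ in range(n):
        p = {s: 0.05 for s in SYMBOLS}
        p[symbol] = 1 - 0.05 * (len(SYMBOLS) - 1)
        out.append(p)
    return out


def labels(*symbols):
    return [label_from_symbol(s) for s in symbols]


def test_combiner_branch_examples():
    pred = combine_votes(labels("R_MO", "R_MO", "R_MO", "N", "L_MI"), uniform_probs())
    assert (pred.final.symbol, pred.rationale) == ("R_MO", "majority")

    # 2-2 tie with normal involved: normal is dropped no matter the probabilities
    pred = combine_votes(
        labels("N", "N", "R_S", "R_S", "L_MI"), probs_favoring("N")
    )
    assert (pred.final.symbol, pred.rationale) == ("R_S", "tie_rule_a")

    # 2-2 tie between two paralysis classes: larger summed probability wins
    probs = []
    for _ in range(5):
        probs.append({"L_MI": 0.38, "R_MO": 0.46, "N": 0.06, "R_MI": 0.05, "R_S": 0.05})
    pred = combine_votes(labels("L_MI", "L_MI", "R_MO", "R_MO", "N"), probs)
    assert (pred.final.symbol, pred.rationale) == ("R_MO", "tie_rule_b")

    # unique plurality at two votes
    pred = combine_votes(labels("R_S", "R_S", "N", "L_MI", "R_MI"), uniform_probs())
    assert (pred.final.symbol, pred.rationale) == ("R_S", "plurality")

    # five distinct votes fall back to summed probability
    pred = combine_votes(
        labels("N", "L_MI", "R_MI", "R_MO", "R_S"), probs_favoring("R_MI")
    )
    assert (pred.final.symbol, pred.rationale) == ("R_MI", "prob_sum_fallback")


def test_combiner_majority_precedence_exhaustive():
    """Over all 5^5 vote assignments, a strict majority always wins, even
    against probabilities concentrated on a different class."""
    for votes in itertools.product(SYMBOLS, repeat=5):
        counts = {s: votes.count(s) for s in set(votes)}
        top = max(counts.values())
        adversary = next(s for s in SYMBOLS if counts.get(s, 0) == 0) if len(
            counts
        ) < len(SYMBOLS) else "N"
        pred = combine_votes(labels(*votes), probs_favoring(adversary))
        assert sum(pred.vote_counts.values()) == 5
        if top >= 3:
            winner = [s for s, c in counts.items() if c == top][0]
            assert pred.final.symbol == winner
            assert pred.rationale == "majority"
        elif top == 2:
            tied = sorted(s for s, c in counts.items() if c == 2)
            if len(tied) == 1:
                assert pred.final.symbol == tied[0]
                assert pred.rationale == "plurality"
            elif "N" in tied:
                assert pred.final.symbol == [s for s in tied if s != "N"][0]
                assert pred.rationale == "tie_rule_a"
            else:
                assert pred.final.symbol in tied
                assert pred.rationale == "tie_rule_b"
        else:
            assert pred.rationale == "prob_sum_fallback"
            assert pred.final.symbol == adversary


def test_combiner_invariant_to_classifier_order():
    votes = labels("L_MI", "R_MO", "L_MI", "R_MO", "N")
    probs = [probs_favoring(s)[0] for s in ("L_MI", "R_MO", "R_MO", "R_MO", "N")]
    finals = set()
    for perm in itertools.permutations(range(5)):
        pred = combine_votes([votes[i] for i in perm], [probs[i] for i in perm])
        finals.add((pred.final.symbol, pred.rationale))
    assert len(finals) == 1


def test_combiner_arity_check():
    with pytest.raises(ValueError):
        combine_votes(labels("N", "N", "N"), uniform_probs(3))


def _toy_set(counts: dict, dim=3, seed=0) -> LabeledFeatureSet:
    rng = np.random.default_rng(seed)
    labels_, rows = [], []
    for sym, n in counts.items():
        for _ in range(n):
            labels_.append(label_from_symbol(sym))
            rows.append(rng.uniform(0, 1, dim))
    return LabeledFeatureSet(matrix=np.array(rows), labels=labels_)


def test_stratified_split_sizes_and_proportions():
    data = _toy_set({"N": 289, "L_MI": 127, "R_MI": 35, "R_MO": 177, "R_S": 36})
    train, test = stratified_split(data, ratio=0.8, seed=1)
    assert test.n in (132, 133)
    assert train.n + test.n == data.n
    for sym, n in data.class_counts().items():
        expected_test = n * 0.2
        assert abs(test.class_counts().get(sym, 0) - expected_test) <= 1


def test_stratified_split_disjoint_union_and_determinism():
    data = _toy_set({"N": 20, "R_MO": 10}, seed=2)
    t1, s1 = stratified_split(data, ratio=0.8, seed=3)
    t2, s2 = stratified_split(data, ratio=0.8, seed=3)
    assert t1.matrix == pytest.approx(t2.matrix)
    assert s1.matrix == pytest.approx(s2.matrix)
    all_rows = [tuple(r) for r in np.vstack([t1.matrix, s1.matrix])]
    assert sorted(all_rows) == sorted(tuple(r) for r in data.matrix)


def test_stratified_split_errors():
    data = _toy_set({"N": 10, "R_S": 1})
    with pytest.raises(ValueError, match="fewer than 2"):
        stratified_split(data, ratio=0.8, seed=0)
    ok = _toy_set({"N": 10, "R_S": 5})
    with pytest.raises(ValueError, match="ratio"):
        stratified_split(ok, ratio=1.2, seed=0)


@pytest.fixture(scope="module")
def zero_noise_report():
    counts = {"N": 25, "L_MI": 15, "R_MI": 15, "R_MO": 15, "R_S": 15}
    records = generate_cohort(
        CohortConfig(class_counts=counts, noise_sd=0.0, seed=4)
    )
    config = PipelineConfig(
        seed=4,
        undersample_target=None,
        C_grid=SMALL_C_GRID,
        gamma_grid=SMALL_GAMMA_GRID,
    )
    return config, records, run_pipeline(config, records)


def test_pipeline_perfect_on_noise_free_cohort(zero_noise_report):
    _, _, report = zero_noise_report
    assert report.ensemble_summary["micro_accuracy"] == pytest.approx(100.0)
    cm = report.confusion.counts
    assert (cm == np.diag(np.diag(cm))).all()


def test_pipeline_uses_41_features_and_logs_hyperparameters(zero_noise_report):
    _, _, report = zero_noise_report
    assert report.n_features == 41
    assert set(report.hyperparameters) == {
        "smiling", "eye_closure", "eyebrow_raise", "cheek_blow", "whistle"
    }
    for hp in report.hyperparameters.values():
        assert hp["C"] in SMALL_C_GRID and hp["gamma"] in SMALL_GAMMA_GRID


def test_pipeline_is_deterministic(zero_noise_report):
    config, records, report = zero_noise_report
    again = run_pipeline(config, records)
    assert (again.confusion.counts == report.confusion.counts).all()
    assert again.hyperparameters == report.hyperparameters
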