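"""Feature transformation: symmetry indices, grades, and the 41-vector."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from palsy import (
    build_feature_vector,
    compute_asis,
    compute_grades,
    feature_table,
    movement_subset,
)
from palsy.cohort import MovementFrame, SubjectRecord, records_to_frame
from palsy.schema import (
    ACTIVE_MOVEMENTS,
    FAU_PAIRS,
    GRADE_FAUS,
    MOVEMENTS,
    NORMAL,
    N_FAUS,
    Movement,
    feature_schema,
)


def make_record(values_by_movement, label=NORMAL, record_id="r0"):
    frames = {
        m: MovementFrame(movement=m, fau=tuple(values_by_movement[m]))
        for m in MOVEMENTS
    }
    return SubjectRecord(record_id=record_id, label=label, frames=frames)


def uniform_record(rng, record_id="r0"):
    return make_record(
        {m: rng.uniform(0, 1, N_FAUS) for m in MOVEMENTS}, record_id=record_id
    )


@st.composite
def records(draw):
    vals = {
        m: draw(
            st.lists(
                st.floats(0, 1, allow_nan=False, width=32),
                min_size=N_FAUS,
                max_size=N_FAUS,
            )
        )
        for m in MOVEMENTS
    }
    return make_record(vals)


def test_symmetric_record_has_zero_asis_and_grades():
    sym = [0.5] * N_FAUS
    record = make_record({m: sym for m in MOVEMENTS})
    assert all(v == 0 for v in compute_asis(record).values())
    assert all(v == 0 for v in compute_grades(record).values())
    assert build_feature_vector(record) == pytest.approx(np.zeros(41))


def test_asi_and_grade_values_match_definitions():
    vals = {m: [0.0] * N_FAUS for m in MOVEMENTS}
    vals[Movement.SMILING][5] = 0.8  # FAU6 (left lip corner)
    vals[Movement.SMILING][6] = 0.2  # FAU7 (right lip corner)
    vals[Movement.REST][5] = 0.1
    record = make_record(vals)
    asis = compute_asis(record)
    assert asis[(Movement.SMILING, (6, 7))] == pytest.approx(0.6)
    grades = compute_grades(record)
    assert grades[(Movement.SMILING, 6)] == pytest.approx(0.7)  # 0.8 - 0.1
    assert grades[(Movement.SMILING, 7)] == pytest.approx(0.2)


def test_output_sizes():
    record = uniform_record(np.random.default_rng(0))
    assert len(compute_asis(record)) == 36
    assert len(compute_grades(record)) == 11
    assert build_feature_vector(record).shape == (41,)


def test_normalized_asi_variant_bounded_and_zero_iff_equal():
    record = uniform_record(np.random.default_rng(1))
    for (m, pair), v in compute_asis(record, normalized=True).items():
        frame = record.frame(m)
        left, right = frame.value(pair[0]), frame.value(pair[1])
        assert 0 <= v <= 1
        assert (v == 0) == (left == right)


def test_movement_subset_sizes():
    record = uniform_record(np.random.default_rng(2))
    vec = build_feature_vector(record)
    assert movement_subset(vec, Movement.WHISTLE).shape == (9,)
    assert movement_subset(vec, Movement.SMILING).shape == (8,)


@settings(max_examples=30, derandomize=True)
@given(records())
def test_asi_invariant_to_left_right_swap(record):
    """Swapping every pair's left and right values leaves all ASIs unchanged."""
    swapped_vals = {}
    for m in MOVEMENTS:
        fau = list(record.frame(m).fau)
        for left, right in FAU_PAIRS:
            fau[left - 1], fau[right - 1] = fau[right - 1], fau[left - 1]
        swapped_vals[m] = fau
    swapped = make_record(swapped_vals)
    orig, new = compute_asis(record), compute_asis(swapped)
    for key in orig:
        assert new[key] == pytest.approx(orig[key], abs=1e-12)


@settings(max_examples=30, derandomize=True)
@given(records(), st.floats(-0.2, 0.2, allow_nan=False))
def test_asi_invariant_to_common_pair_shift(record, delta):
    """Adding a constant to both members of each pair keeps |L - R| fixed."""
    shifted_vals = {}
    for m in MOVEMENTS:
        fau = list(record.frame(m).fau)
        for left, right in FAU_PAIRS:
            if 0 <= fau[left - 1] + delta <= 1 and 0 <= fau[right - 1] + delta <= 1:
                fau[left - 1] += delta
                fau[right - 1] += delta
        shifted_vals[m] = fau
    shifted = make_record(shifted_vals)
    orig, new = compute_asis(record), compute_asis(shifted)
    for key in orig:
        assert new[key] == pytest.approx(orig[key], abs=1e-9)


def test_feature_vector_matches_brute_force_recomputation():
    """Each of the 41 features recomputed independently from CSV fields."""
    rng = np.random.default_rng(42)
    records_list = [uniform_record(rng, record_id=f"r{i}") for i in range(100)]
    df = records_to_frame(records_list).set_index(["record_id", "movement"])
    table = feature_table(records_list).set_index("record_id")
    schema = feature_schema()
    for rec in records_list:
        row = table.loc[rec.record_id]
        for feat in schema:
            if feat.kind == "asi":
                left = df.loc[(rec.record_id, feat.movement.value)][
                    f"FAU{feat.pair[0]}"
                ]
                right = df.loc[(rec.record_id, feat.movement.value)][
                    f"FAU{feat.pair[1]}"
                ]
                expected = abs(left - right)
            else:
                moved = df.loc[(rec.record_id, feat.movement.value)][
                    f"FAU{feat.fau}"
                ]
                rest = df.loc[(rec.record_id, "rest")][f"FAU{feat.fau}"]
                expected = moved - rest
            assert row[feat.name] == pytest.approx(expected, abs=1e-12)


def test_grade_schema_covers_expected_faus():
    grades = compute_grades(uniform_record(np.random.default_rng(3)))
    per_movement = {
        m: sorted(f for (mm, f) in grades if mm is m) for m in ACTIVE_MOVEMENTS
    }
    assert per_movement[Movement.WHISTLE] == [14, 16, 17]
    assert per_movement[Movement.SMILING] == [6, 7]
    assert per_movement[Movement.EYE_CLOSURE] == [2, 3]
    assert per_movement[Movement.EYEBROW_RAISE] == [4, 5]
    assert per_movement[Movement.CHEEK_BLOW] == [16, 17]
    assert GRADE_FAUS[Movement.WHISTLE] == (14, 16, 17)
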