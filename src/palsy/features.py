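"""Transform raw FAU sessions into classifier-input features.

Two transformations feed classification:

* **Animation symmetry indices (ASIs).** For each of the six left/right FAU
  pairs, during each of the six states, the asymmetry of the pair is scored.
  The default index is the unnormalized absolute asymmetry
  ``ASI = |left - right|``; a normalized variant
  ``|L - R| / (L + R + eps)`` is available behind a switch. 6 pairs x 6
  states = 36 ASIs, of which the 30 non-rest ones enter classification.

* **Facial function grades.** For each movement's most-affected FAUs, the
  activation change from rest (``movement - rest``, signed) grades how well
  the movement is performed: 11 values.

Concatenated in canonical order these form the 41-dimensional feature vector.
Each voluntary movement owns a subset (its 6 ASIs plus its 2-3 grades; 8
features per movement, 9 for whistling) that trains that movement's
first-level classifier.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import SubjectRecord
from .schema import (
    ACTIVE_MOVEMENTS,
    FAU_PAIRS,
    FEATURE_NAMES,
    GRADE_FAUS,
    MOVEMENTS,
    Movement,
    feature_schema,
    movement_feature_indices,
)
from .schema import selected_fau_count as selected_fau_count  # re-export


def _asi(left: float, right: float, normalized: bool, eps: float = 1e-6) -> float:
    d = abs(left - right)
    if normalized:
        return d / (left + right + eps)
    return d


def compute_asis(
    record: SubjectRecord, normalized: bool = False
) -> dict[tuple[Movement, tuple[int, int]], float]:
    """All 36 symmetry indices of a record, keyed by (movement, pair)."""
    out: dict[tuple[Movement, tuple[int, int]], float] = {}
    for m in MOVEMENTS:
        frame = record.frame(m)
        for pair in FAU_PAIRS:
            left, right = frame.value(pair[0]), frame.value(pair[1])
            out[(m, pair)] = _asi(left, right, normalized)
    return out


def compute_grades(record: SubjectRecord) -> dict[tuple[Movement, int], float]:
    """The 11 movement grades (movement value minus rest value), signed."""
    rest = record.frame(Movement.REST)
    out: dict[tuple[Movement, int], float] = {}
    for m in ACTIVE_MOVEMENTS:
        frame = record.frame(m)
        for fau in GRADE_FAUS[m]:
            out[(m, fau)] = frame.value(fau) - rest.value(fau)
    return out


def build_feature_vector(record: SubjectRecord, normalized_asi: bool = False) -> np.ndarray:
    """The 41 classifier-input features of a record, in canonical order."""
    asis = compute_asis(record, normalized=normalized_asi)
    grades = compute_grades(record)
    values = []
    for f in feature_schema():
        if f.kind == "asi":
            values.append(asis[(f.movement, f.pair)])
        else:
            values.append(grades[(f.movement, f.fau)])
    return np.asarray(values, dtype=float)


def movement_subset(vector: np.ndarray, movement: Movement) -> np.ndarray:
    """Extract one movement's feature subset (8 features; 9 for whistling)."""
    vector = np.asarray(vector)
    idx = list(movement_feature_indices(movement))
    return vector[..., idx]


def feature_table(
    records: list[SubjectRecord], normalized_asi: bool = False
) -> pd.DataFrame:
    """Feature matrix for a cohort: record_id, label, then 41 named columns."""
    rows = [
        (r.record_id, r.label.symbol, *build_feature_vector(r, normalized_asi))
        for r in records
    ]
    return pd.DataFrame(rows, columns=["record_id", "label", *FEATURE_NAMES])


def labeled_feature_set(records: list[SubjectRecord], normalized_asi: bool = False):
    """Transform a cohort straight into a :class:`~palsy.imbalance.LabeledFeatureSet`."""
    from .imbalance import LabeledFeatureSet

    return LabeledFeatureSet(
        matrix=np.vstack(
            [build_feature_vector(r, normalized_asi) for r in records]
        ),
        labels=[r.label for r in records],
    )
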