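"""Label and feature schema for FAU-based facial-paralysis classification.

The face is captured in six movement states (rest plus five voluntary
movements). Each state yields 17 facial animation units (FAUs), continuous
activations in [0, 1] tracked by a depth sensor. Twelve of the FAUs form six
left/right pairs; FAU14 (lip pucker) is midline and unpaired. Severity labels
combine an affected side (left/right) with a grade (mild/moderate/severe),
plus the normal class.

Everything downstream — the symmetry indices, the movement grades, the
41-dimensional classifier input and the per-movement feature subsets — is
derived from the constants in this module rather than hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable

N_FAUS = 17
FAU_NAMES: tuple[str, ...] = tuple(f"FAU{i}" for i in range(1, N_FAUS + 1))


class Movement(str, Enum):
    """The six captured facial states, in canonical order (rest first)."""

    REST = "rest"
    SMILING = "smiling"
    EYE_CLOSURE = "eye_closure"
    EYEBROW_RAISE = "eyebrow_raise"
    CHEEK_BLOW = "cheek_blow"
    WHISTLE = "whistle"


MOVEMENTS: tuple[Movement, ...] = tuple(Movement)
#: Canonical order of the five voluntary movements used for classification.
ACTIVE_MOVEMENTS: tuple[Movement, ...] = (
    Movement.SMILING,
    Movement.EYE_CLOSURE,
    Movement.EYEBROW_RAISE,
    Movement.CHEEK_BLOW,
    Movement.WHISTLE,
)

#: Left/right FAU pairs, as (left index, right index); even index = left side.
#: (2,3) eye closure, (4,5) eyebrow raiser, (6,7) lip-corner puller,
#: (8,9) lip-corner depressor, (10,11) lower-lip depressor, (16,17) cheek puff.
FAU_PAIRS: tuple[tuple[int, int], ...] = (
    (2, 3),
    (4, 5),
    (6, 7),
    (8, 9),
    (10, 11),
    (16, 17),
)

#: Midline (unpaired) FAU involved in whistling: lip pucker.
MIDLINE_FAU = 14

#: FAUs whose change from rest grades how well each movement is performed.
GRADE_FAUS: dict[Movement, tuple[int, ...]] = {
    Movement.SMILING: (6, 7),
    Movement.EYE_CLOSURE: (2, 3),
    Movement.EYEBROW_RAISE: (4, 5),
    Movement.CHEEK_BLOW: (16, 17),
    Movement.WHISTLE: (MIDLINE_FAU, 16, 17),
}


class Side(str, Enum):
    NONE = "none"
    LEFT = "left"
    RIGHT = "right"


class Severity(str, Enum):
    NONE = "none"
    MILD = "mild"
    MODERATE = "moderate"
    SEVERE = "severe"


#: Severity ranking used for monotonicity checks (none < mild < mod < severe).
SEVERITY_ORDER: tuple[Severity, ...] = (
    Severity.NONE,
    Severity.MILD,
    Severity.MODERATE,
    Severity.SEVERE,
)


@dataclass(frozen=True)
class ClassLabel:
    """One of the seven severity categories (symbol <-> side/severity bijection)."""

    symbol: str
    side: Side
    severity: Severity

    def __post_init__(self) -> None:
        if (self.side is Side.NONE) != (self.severity is Severity.NONE):
            raise ValueError(
                f"inconsistent label: side={self.side.value}, "
                f"severity={self.severity.value}"
            )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.symbol


def _mk(symbol: str, side: Side, severity: Severity) -> ClassLabel:
    return ClassLabel(symbol=symbol, side=side, severity=severity)


NORMAL = _mk("N", Side.NONE, Severity.NONE)
L_MI = _mk("L_MI", Side.LEFT, Severity.MILD)
L_MO = _mk("L_MO", Side.LEFT, Severity.MODERATE)
L_S = _mk("L_S", Side.LEFT, Severity.SEVERE)
R_MI = _mk("R_MI", Side.RIGHT, Severity.MILD)
R_MO = _mk("R_MO", Side.RIGHT, Severity.MODERATE)
R_S = _mk("R_S", Side.RIGHT, Severity.SEVERE)

#: All seven categories in display order.
ALL_LABELS: tuple[ClassLabel, ...] = (NORMAL, L_MI, L_MO, L_S, R_MI, R_MO, R_S)
LABELS_BY_SYMBOL: dict[str, ClassLabel] = {l.symbol: l for l in ALL_LABELS}


def label_from_symbol(symbol: str) -> ClassLabel:
    """Look up a category by its symbol (e.g. ``"R_MO"``)."""
    try:
        return LABELS_BY_SYMBOL[symbol]
    except KeyError:
        raise ValueError(
            f"unknown label symbol {symbol!r}; expected one of "
            f"{sorted(LABELS_BY_SYMBOL)}"
        ) from None


# ---------------------------------------------------------------------------
# Feature schema
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureId:
    """Identity of one classifier-input feature.

    kind ``asi``: absolute left/right asymmetry of ``pair`` during ``movement``.
    kind ``grade``: change of ``fau`` during ``movement`` relative to rest.
    """

    movement: Movement
    kind: str  # "asi" | "grade"
    pair: tuple[int, int] | None = None
    fau: int | None = None

    @property
    def name(self) -> str:
        if self.kind == "asi":
            assert self.pair is not None
            return f"asi_{self.movement.value}_{self.pair[0]}_{self.pair[1]}"
        assert self.fau is not None
        return f"grade_{self.movement.value}_FAU{self.fau}"


def asi_schema(include_rest: bool = True) -> tuple[FeatureId, ...]:
    """All symmetry-index slots: 6 pairs x 6 movements (36), or 30 without rest."""
    movements: Iterable[Movement] = MOVEMENTS if include_rest else ACTIVE_MOVEMENTS
    return tuple(
        FeatureId(movement=m, kind="asi", pair=p) for m in movements for p in FAU_PAIRS
    )


def grade_schema() -> tuple[FeatureId, ...]:
    """The 11 movement-grade slots, in canonical movement order."""
    return tuple(
        FeatureId(movement=m, kind="grade", fau=f)
        for m in ACTIVE_MOVEMENTS
        for f in GRADE_FAUS[m]
    )


def feature_schema() -> tuple[FeatureId, ...]:
    """The 41 classifier-input features, grouped by movement (ASIs then grades).

    Movements follow the canonical order smiling, eye_closure, eyebrow_raise,
    cheek_blow, whistle; within a movement the six ASIs precede the grades.
    """
    out: list[FeatureId] = []
    for m in ACTIVE_MOVEMENTS:
        out.extend(FeatureId(movement=m, kind="asi", pair=p) for p in FAU_PAIRS)
        out.extend(FeatureId(movement=m, kind="grade", fau=f) for f in GRADE_FAUS[m])
    return tuple(out)


FEATURE_NAMES: tuple[str, ...] = tuple(f.name for f in feature_schema())


def movement_feature_indices(movement: Movement) -> tuple[int, ...]:
    """Column indices (into the 41-vector) of one movement's feature subset."""
    if movement not in ACTIVE_MOVEMENTS:
        raise ValueError(f"no classifier subset for movement {movement.value!r}")
    schema = feature_schema()
    return tuple(i for i, f in enumerate(schema) if f.movement is movement)


def raw_feature_count() -> int:
    """Raw FAU values per record: 6 states x 17 FAUs."""
    return len(MOVEMENTS) * N_FAUS


def symmetry_input_faus() -> set[tuple[Movement, int]]:
    """Feature set 1: the 12 paired FAUs in each of the six states (72 slots)."""
    paired = sorted(i for p in FAU_PAIRS for i in p)
    return {(m, f) for m in MOVEMENTS for f in paired}


def grading_input_faus() -> set[tuple[Movement, int]]:
    """Feature set 2: each movement's most-affected FAUs plus their rest values."""
    movement_slots = {(m, f) for m in ACTIVE_MOVEMENTS for f in GRADE_FAUS[m]}
    rest_slots = {(Movement.REST, f) for m, faus in GRADE_FAUS.items() for f in faus}
    return movement_slots | rest_slots


def selected_fau_count() -> int:
    """Number of distinct raw FAU slots feeding the two transform modules."""
    return len(symmetry_input_faus() | grading_input_faus())
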