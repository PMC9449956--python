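"""Subject records and a synthetic cohort generator.

Real sessions are captured with a depth sensor: one subject performs the
five voluntary movements plus rest, and each state yields 17 FAU activations.
The patient data behind the published study are not deposited, so this module
also provides a generator that emulates the dataset's statistical structure:
the seven-category class frequencies, unilateral side-specific attenuation of
movement-related FAUs graded by severity, and additive Gaussian noise.

A paralysed side performs every movement weakly: for a record with side *s*
and severity *v*, the side-*s* member of each movement's active FAU pair is
drawn around ``attenuation(v)`` times the healthy template activation while
the contralateral member stays at full template activation. Rest-state FAUs
sit near zero for everyone. Noise is added last and values are clipped to
[0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .schema import (
    ACTIVE_MOVEMENTS,
    ALL_LABELS,
    FAU_NAMES,
    FAU_PAIRS,
    GRADE_FAUS,
    MIDLINE_FAU,
    MOVEMENTS,
    N_FAUS,
    ClassLabel,
    Movement,
    Severity,
    Side,
    label_from_symbol,
)


class CohortConfigError(ValueError):
    """Raised for invalid cohort-generation settings."""


class RecordParseError(ValueError):
    """Raised when a record file violates the CSV contract."""


@dataclass(frozen=True)
class MovementFrame:
    """17 FAU activations captured during one facial state."""

    movement: Movement
    fau: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.fau) != N_FAUS:
            raise ValueError(
                f"{self.movement.value}: expected {N_FAUS} FAU values, "
                f"got {len(self.fau)}"
            )

    def value(self, index: int) -> float:
        """FAU activation by 1-based FAU index."""
        if not 1 <= index <= N_FAUS:
            raise IndexError(f"FAU index {index} outside 1..{N_FAUS}")
        return self.fau[index - 1]


@dataclass(frozen=True)
class SubjectRecord:
    """One full session: a label plus one frame per each of the six states."""

    record_id: str
    label: ClassLabel
    frames: dict[Movement, MovementFrame]

    def __post_init__(self) -> None:
        missing = [m.value for m in MOVEMENTS if m not in self.frames]
        if missing:
            raise ValueError(
                f"record {self.record_id!r} missing movement(s): {missing}"
            )
        for m, frame in self.frames.items():
            if frame.movement is not m:
                raise ValueError(
                    f"record {self.record_id!r}: frame keyed {m.value} "
                    f"carries movement {frame.movement.value}"
                )

    def frame(self, movement: Movement) -> MovementFrame:
        return self.frames[movement]


#: Class frequencies of the study dataset after majority-class undersampling.
DATASET_CLASS_COUNTS: dict[str, int] = {
    "N": 289,
    "L_MI": 127,
    "L_MO": 0,
    "L_S": 0,
    "R_MI": 35,
    "R_MO": 177,
    "R_S": 36,
}

#: Normal records originally captured, before undersampling.
RAW_NORMAL_COUNT = 1650

DEFAULT_ATTENUATION: dict[Severity, float] = {
    Severity.NONE: 1.0,
    Severity.MILD: 0.65,
    Severity.MODERATE: 0.35,
    Severity.SEVERE: 0.10,
}


def _default_template() -> dict[tuple[Movement, int], float]:
    """Healthy activation template: which FAUs fire in which movement.

    Primary muscles of each movement activate strongly (0.8); synergist pairs
    weakly; everything else (and all of rest) stays at zero.
    """
    t: dict[tuple[Movement, int], float] = {}
    strong, weak = 0.8, 0.3
    for fau in GRADE_FAUS[Movement.SMILING]:
        t[(Movement.SMILING, fau)] = strong
    t[(Movement.SMILING, 8)] = weak  # lip-corner depressors co-activate
    t[(Movement.SMILING, 9)] = weak
    for fau in GRADE_FAUS[Movement.EYE_CLOSURE]:
        t[(Movement.EYE_CLOSURE, fau)] = strong
    for fau in GRADE_FAUS[Movement.EYEBROW_RAISE]:
        t[(Movement.EYEBROW_RAISE, fau)] = strong
    for fau in GRADE_FAUS[Movement.CHEEK_BLOW]:
        t[(Movement.CHEEK_BLOW, fau)] = strong
    t[(Movement.WHISTLE, MIDLINE_FAU)] = 0.7
    t[(Movement.WHISTLE, 16)] = 0.5
    t[(Movement.WHISTLE, 17)] = 0.5
    t[(Movement.WHISTLE, 10)] = weak  # lower-lip depressors assist pursing
    t[(Movement.WHISTLE, 11)] = weak
    return t


@dataclass(frozen=True)
class CohortConfig:
    """Settings for synthetic cohort generation.

    class_counts maps label symbols to record counts; attenuation maps
    severity to the multiplicative weakening of the paralysed side's
    activations (strictly decreasing with severity); activation_template maps
    (movement, FAU index) to the healthy baseline activation; noise_sd is the
    SD of additive Gaussian measurement noise applied to every FAU value.
    """

    class_counts: dict[str, int] = field(
        default_factory=lambda: dict(DATASET_CLASS_COUNTS)
    )
    attenuation: dict[Severity, float] = field(
        default_factory=lambda: dict(DEFAULT_ATTENUATION)
    )
    activation_template: dict[tuple[Movement, int], float] = field(
        default_factory=_default_template
    )
    noise_sd: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for symbol, count in self.class_counts.items():
            label_from_symbol(symbol)
            if count < 0:
                raise CohortConfigError(f"negative count for class {symbol}: {count}")
        for sev, a in self.attenuation.items():
            if not 0.0 <= a <= 1.0:
                raise CohortConfigError(
                    f"attenuation({sev.value})={a} outside [0, 1]"
                )
        graded = [
            self.attenuation[s]
            for s in (Severity.MILD, Severity.MODERATE, Severity.SEVERE)
            if s in self.attenuation
        ]
        if any(b >= a for a, b in zip(graded, graded[1:])):
            raise CohortConfigError(
                "attenuation must be strictly decreasing with severity"
            )
        for (m, fau), v in self.activation_template.items():
            if not 0.0 <= v <= 1.0:
                raise CohortConfigError(
                    f"template activation ({m.value}, FAU{fau})={v} outside [0, 1]"
                )
        if self.noise_sd < 0:
            raise CohortConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")


def _record_mean_faus(
    label: ClassLabel, config: CohortConfig
) -> dict[Movement, np.ndarray]:
    """Noise-free FAU means for one record of the given class."""
    att = config.attenuation[label.severity]
    means: dict[Movement, np.ndarray] = {}
    for m in MOVEMENTS:
        row = np.zeros(N_FAUS)
        for fau in range(1, N_FAUS + 1):
            base = config.activation_template.get((m, fau), 0.0)
            if base == 0.0:
                continue
            factor = 1.0
            if fau == MIDLINE_FAU:
                # both facial sides contribute to the midline pucker
                factor = (1.0 + att) / 2.0
            else:
                side = Side.LEFT if fau % 2 == 0 else Side.RIGHT
                if side is label.side:
                    factor = att
            row[fau - 1] = base * factor
        means[m] = row
    return means


def generate_cohort(config: CohortConfig) -> list[SubjectRecord]:
    """Generate a reproducible synthetic cohort with the configured structure.

    Returns exactly ``class_counts[c]`` records per class, ordered by the
    canonical label order then record index. Same config (including seed)
    yields an identical cohort.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    records: list[SubjectRecord] = []
    for label in ALL_LABELS:
        count = config.class_counts.get(label.symbol, 0)
        means = _record_mean_faus(label, config)
        for i in range(count):
            frames: dict[Movement, MovementFrame] = {}
            for m in MOVEMENTS:
                values = means[m].copy()
                if config.noise_sd > 0:
                    values = values + rng.normal(0.0, config.noise_sd, N_FAUS)
                values = np.clip(values, 0.0, 1.0)
                frames[m] = MovementFrame(movement=m, fau=tuple(values.tolist()))
            records.append(
                SubjectRecord(
                    record_id=f"{label.symbol}_{i:04d}", label=label, frames=frames
                )
            )
    return records


# ---------------------------------------------------------------------------
# CSV I/O — one row per (record, movement); header
# record_id,label,movement,FAU1,...,FAU17
# ---------------------------------------------------------------------------

CSV_COLUMNS: tuple[str, ...] = ("record_id", "label", "movement", *FAU_NAMES)


def records_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """Long-format table: one row per (record, movement)."""
    rows = []
    for rec in records:
        for m in MOVEMENTS:
            frame = rec.frames[m]
            rows.append((rec.record_id, rec.label.symbol, m.value, *frame.fau))
    return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


def write_records(records: list[SubjectRecord], path) -> None:
    """Write records as UTF-8 CSV (one row per record/movement)."""
    records_to_frame(records).to_csv(path, index=False)


def _parse_group(record_id: str, group: pd.DataFrame, strict: bool) -> SubjectRecord:
    labels = group["label"].unique()
    if len(labels) > 1:
        raise RecordParseError(
            f"record {record_id!r}: conflicting labels {sorted(labels)}"
        )
    label = label_from_symbol(str(labels[0]))
    frames: dict[Movement, MovementFrame] = {}
    for _, row in group.iterrows():
        try:
            movement = Movement(str(row["movement"]))
        except ValueError:
            raise RecordParseError(
                f"record {record_id!r}: unknown movement {row['movement']!r}"
            ) from None
        if movement in frames:
            raise RecordParseError(
                f"record {record_id!r}: duplicate movement {movement.value!r}"
            )
        values = []
        for name in FAU_NAMES:
            raw = row[name]
            try:
                v = float(raw)
            except (TypeError, ValueError):
                raise RecordParseError(
                    f"record {record_id!r}, movement {movement.value!r}: "
                    f"non-numeric {name} value {raw!r}"
                ) from None
            if np.isnan(v):
                raise RecordParseError(
                    f"record {record_id!r}, movement {movement.value!r}: "
                    f"missing {name} value"
                )
            if not 0.0 <= v <= 1.0:
                if strict:
                    raise RecordParseError(
                        f"record {record_id!r}, movement {movement.value!r}: "
                        f"{name}={v} outside [0, 1]"
                    )
                warnings.warn(
                    f"record {record_id!r}: clipping {name}={v} into [0, 1]",
                    stacklevel=3,
                )
                v = min(max(v, 0.0), 1.0)
            values.append(v)
        frames[movement] = MovementFrame(movement=movement, fau=tuple(values))
    missing = [m.value for m in MOVEMENTS if m not in frames]
    if missing:
        raise RecordParseError(
            f"record {record_id!r}: missing movement(s) {missing}"
        )
    return SubjectRecord(record_id=record_id, label=label, frames=frames)


def load_records(path, strict: bool = True) -> list[SubjectRecord]:
    """Load records from CSV; round-trips :func:`write_records` output.

    In strict mode (default) FAU values outside [0, 1] raise
    :class:`RecordParseError`; in lenient mode they are clipped with a warning.
    """
    df = pd.read_csv(path, dtype={"record_id": str, "label": str, "movement": str})
    missing_cols = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing_cols:
        raise RecordParseError(f"missing column(s): {missing_cols}")
    records = []
    for record_id, group in df.groupby("record_id", sort=False):
        records.append(_parse_group(str(record_id), group, strict))
    return records
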