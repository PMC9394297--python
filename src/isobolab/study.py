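"""Domain types, validation and tabular I/O for formalin-test studies.

A study is two tidy tables:

* a **timecourse table** with one row per (subject, observation time):
  ``subject,arm,time_min,count``
* an **arms table** describing each treatment arm:
  ``arm,role,n,drug1,dose1,unit1,route1,...,drug4,dose4,unit4,route4``
  (unused drug slots left empty)

Counts are flinches per 5-min bin; the standard observation grid is
5, 10, ..., 60 minutes (bin-end convention). Both tables are plain CSV.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ValidationError

STANDARD_GRID: tuple[int, ...] = tuple(range(5, 65, 5))

MAX_DRUGS_PER_ARM = 4

TIMECOURSE_COLUMNS = ["subject", "arm", "time_min", "count"]


class DoseUnit(str, enum.Enum):
    MG_PER_KG = "mg_per_kg"
    UG_PER_PAW = "ug_per_paw"


class Route(str, enum.Enum):
    SYSTEMIC = "systemic"
    INTRAPLANTAR_IPSILATERAL = "intraplantar_ipsilateral"
    INTRAPLANTAR_CONTRALATERAL = "intraplantar_contralateral"


class ArmRole(str, enum.Enum):
    VEHICLE_CONTROL = "vehicle_control"
    MONOTHERAPY = "monotherapy"
    COMBINATION = "combination"
    COMBINATION_WITH_ANTAGONIST = "combination_with_antagonist"


@dataclass(frozen=True)
class DoseSpec:
    """One administered drug: label, dose, unit and route."""

    drug: str
    dose: float
    unit: DoseUnit
    route: Route

    def __post_init__(self):
        if not self.drug:
            raise ValidationError("DoseSpec.drug must be a non-empty label")
        if not (self.dose >= 0):
            raise ValidationError(f"dose must be >= 0, got {self.dose!r}")
        object.__setattr__(self, "unit", DoseUnit(self.unit))
        object.__setattr__(self, "route", Route(self.route))


@dataclass(frozen=True)
class TreatmentArm:
    """A treatment group: its label, drug list, role and planned group size."""

    label: str
    doses: tuple[DoseSpec, ...]
    role: ArmRole
    n: int

    def __post_init__(self):
        object.__setattr__(self, "doses", tuple(self.doses))
        object.__setattr__(self, "role", ArmRole(self.role))
        if not self.label:
            raise ValidationError("arm label must be non-empty")
        if self.n < 1:
            raise ValidationError(f"arm {self.label!r}: n must be >= 1, got {self.n}")
        if len(self.doses) > MAX_DRUGS_PER_ARM:
            raise ValidationError(
                f"arm {self.label!r}: at most {MAX_DRUGS_PER_ARM} drugs per arm"
            )
        if self.role is ArmRole.VEHICLE_CONTROL and self.doses:
            raise ValidationError(
                f"arm {self.label!r}: vehicle control must have an empty dose list"
            )
        if self.role is ArmRole.COMBINATION and len(self.doses) < 2:
            raise ValidationError(
                f"arm {self.label!r}: a combination arm needs >= 2 DoseSpecs"
            )


@dataclass(frozen=True)
class TimeCourse:
    """One subject's binned flinch counts over the observation period."""

    subject: str
    arm: str
    observations: tuple[tuple[float, int], ...]

    def __post_init__(self):
        obs = tuple((float(t), int(c)) for t, c in self.observations)
        object.__setattr__(self, "observations", obs)
        times = [t for t, _ in obs]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValidationError(
                f"subject {self.subject!r}: observation times must be strictly increasing"
            )
        for t, c in zip(times, (c for _, c in self.observations)):
            if c < 0:
                raise ValidationError(
                    f"subject {self.subject!r}: negative count {c} at t={t}"
                )

    @property
    def times(self) -> tuple[float, ...]:
        return tuple(t for t, _ in self.observations)

    @property
    def counts(self) -> tuple[int, ...]:
        return tuple(c for _, c in self.observations)


@dataclass
class StudyTable:
    """A validated study: treatment arms plus per-subject timecourses."""

    arms: dict[str, TreatmentArm] = field(default_factory=dict)
    timecourses: list[TimeCourse] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        controls = [a for a in self.arms.values() if a.role is ArmRole.VEHICLE_CONTROL]
        if len(controls) != 1:
            raise ValidationError(
                f"study must have exactly one vehicle_control arm, found {len(controls)}"
            )
        for label, arm in self.arms.items():
            if label != arm.label:
                raise ValidationError(f"arm keyed {label!r} has label {arm.label!r}")
        seen: set[tuple[str, str]] = set()
        populated: set[str] = set()
        for tc in self.timecourses:
            if tc.arm not in self.arms:
                raise ValidationError(
                    f"timecourse for subject {tc.subject!r} references unknown arm {tc.arm!r}"
                )
            key = (tc.subject, tc.arm)
            if key in seen:
                raise ValidationError(f"duplicate timecourse for subject {tc.subject!r}")
            seen.add(key)
            populated.add(tc.arm)
        missing = set(self.arms) - populated
        if missing:
            raise ValidationError(
                f"arms without any subject: {sorted(missing)}"
            )

    @property
    def control_arm(self) -> TreatmentArm:
        return next(
            a for a in self.arms.values() if a.role is ArmRole.VEHICLE_CONTROL
        )

    def timecourses_for(self, arm: str) -> list[TimeCourse]:
        if arm not in self.arms:
            raise ValidationError(f"unknown arm {arm!r}")
        return [tc for tc in self.timecourses if tc.arm == arm]

    def __eq__(self, other) -> bool:
        if not isinstance(other, StudyTable):
            return NotImplemented
        return self.arms == other.arms and sorted(
            self.timecourses, key=lambda tc: (tc.arm, tc.subject)
        ) == sorted(other.timecourses, key=lambda tc: (tc.arm, tc.subject))


def _arms_columns() -> list[str]:
    cols = ["arm", "role", "n"]
    for i in range(1, MAX_DRUGS_PER_ARM + 1):
        cols += [f"drug{i}", f"dose{i}", f"unit{i}", f"route{i}"]
    return cols


ARMS_COLUMNS = _arms_columns()


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{what}: missing column(s) {missing}")


def read_study(timecourse_table: str | Path, arms_table: str | Path) -> StudyTable:
    """Read and validate a study from its two CSV tables.

    Raises :class:`ValidationError` with row context on any malformed cell
    (non-integer count, negative dose, unknown arm label, duplicate
    (subject, time) observation, missing control arm, ...).
    """
    tc_path, arms_path = Path(timecourse_table), Path(arms_table)
    for p in (tc_path, arms_path):
        if not p.exists():
            raise ValidationError(f"input file does not exist: {p}")

    arms_df = pd.read_csv(arms_path, dtype=str, keep_default_na=False)
    _require_columns(arms_df, ["arm", "role", "n"], f"arms table {arms_path}")
    arms: dict[str, TreatmentArm] = {}
    for idx, row in arms_df.iterrows():
        ctx = f"{arms_path} row {idx + 2}"
        label = row["arm"]
        if label in arms:
            raise ValidationError(f"duplicate arm label {label!r}", context=ctx)
        doses = []
        for i in range(1, MAX_DRUGS_PER_ARM + 1):
            drug = row.get(f"drug{i}", "")
            if not drug:
                continue
            try:
                dose = float(row[f"dose{i}"])
            except (KeyError, ValueError) as exc:
                raise ValidationError(
                    f"arm {label!r}: bad dose{i} value {row.get(f'dose{i}')!r}",
                    context=ctx,
                ) from exc
            try:
                doses.append(
                    DoseSpec(drug, dose, DoseUnit(row[f"unit{i}"]), Route(row[f"route{i}"]))
                )
            except (KeyError, ValueError, ValidationError) as exc:
                raise ValidationError(
                    f"arm {label!r}: invalid drug slot {i}: {exc}", context=ctx
                ) from exc
        try:
            n = int(row["n"])
            arm = TreatmentArm(label, tuple(doses), ArmRole(row["role"]), n)
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"invalid arm row: {exc}", context=ctx) from exc
        arms[label] = arm

    tc_df = pd.read_csv(tc_path, dtype=str, keep_default_na=False)
    _require_columns(tc_df, TIMECOURSE_COLUMNS, f"timecourse table {tc_path}")
    grouped: dict[tuple[str, str], list[tuple[float, int]]] = {}
    for idx, row in tc_df.iterrows():
        ctx = f"{tc_path} row {idx + 2}"
        try:
            t = float(row["time_min"])
        except ValueError as exc:
            raise ValidationError(
                f"bad time_min {row['time_min']!r}", context=ctx
            ) from exc
        raw = row["count"]
        try:
            c = int(raw)
        except ValueError as exc:
            raise ValidationError(f"non-integer count {raw!r}", context=ctx) from exc
        if c < 0:
            raise ValidationError(f"negative count {c}", context=ctx)
        if row["arm"] not in arms:
            raise ValidationError(f"unknown arm label {row['arm']!r}", context=ctx)
        key = (row["subject"], row["arm"])
        obs = grouped.setdefault(key, [])
        if any(t == t0 for t0, _ in obs):
            raise ValidationError(
                f"duplicate (subject, time) = ({key[0]!r}, {t})", context=ctx
            )
        obs.append((t, c))

    timecourses = []
    for (subject, arm), obs in grouped.items():
        obs.sort(key=lambda p: p[0])
        timecourses.append(TimeCourse(subject, arm, tuple(obs)))
    return StudyTable(arms=arms, timecourses=timecourses)


def write_study(
    study: StudyTable, timecourse_table: str | Path, arms_table: str | Path
) -> None:
    """Write a study to the two-table CSV schema; inverse of :func:`read_study`."""
    if not study.timecourses:
        raise ValidationError("refusing to write a study with no timecourses")
    arm_rows = []
    for arm in study.arms.values():
        row: dict[str, object] = {"arm": arm.label, "role": arm.role.value, "n": arm.n}
        for i, ds in enumerate(arm.doses, start=1):
            row[f"drug{i}"] = ds.drug
            row[f"dose{i}"] = repr(ds.dose)
            row[f"unit{i}"] = ds.unit.value
            row[f"route{i}"] = ds.route.value
        arm_rows.append(row)
    arms_df = pd.DataFrame(arm_rows, columns=ARMS_COLUMNS).fillna("")
    arms_df.to_csv(arms_table, index=False)

    tc_rows = [
        {"subject": tc.subject, "arm": tc.arm, "time_min": t, "count": c}
        for tc in study.timecourses
        for t, c in tc.observations
    ]
    pd.DataFrame(tc_rows, columns=TIMECOURSE_COLUMNS).to_csv(
        timecourse_table, index=False
    )


def study_from_records(
    arms: Iterable[TreatmentArm], timecourses: Iterable[TimeCourse]
) -> StudyTable:
    """Assemble a StudyTable from in-memory objects (validates on build)."""
    return StudyTable(arms={a.label: a for a in arms}, timecourses=list(timecourses))
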