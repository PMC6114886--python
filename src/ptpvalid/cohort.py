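"""Patient-level data model, CSV I/O and derived clinical classifications.

A cohort is a collection of symptomatic individuals referred for coronary CT
angiography (CCTA).  Each record carries demographics, chest-pain typology,
the four traditional risk factors (smoking, diabetes, hypertension,
hyperlipidemia) plus family history, the Agatston coronary calcium score
(CCS), the obstructive-CAD outcome on CCTA, and optional follow-up events
used for the MACE composite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "Sex",
    "ChestPain",
    "CcsCategory",
    "EventKind",
    "FollowUpEvent",
    "PatientRecord",
    "CohortTable",
    "DataError",
    "SchemaError",
    "DAYS_PER_MONTH",
    "LATE_REVASC_DAYS",
    "count_risk_factors",
    "classify_obstructive",
    "ccs_category",
    "classify_mace",
    "read_cohort",
    "write_cohort",
]

# Mean Gregorian month length; used to convert the 60-day late-revascularization
# threshold into the months unit that records store.
DAYS_PER_MONTH = 30.4375
LATE_REVASC_DAYS = 60.0
LATE_REVASC_MONTHS = LATE_REVASC_DAYS / DAYS_PER_MONTH

RISK_FACTOR_FIELDS = ("smoking", "diabetes", "hypertension", "hyperlipidemia")

AGE_MIN, AGE_MAX = 18.0, 90.0


class DataError(ValueError):
    """A record or value violates a domain invariant."""


class SchemaError(ValueError):
    """An input table is missing or misdeclares a required column."""


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class ChestPain(str, Enum):
    NONANGINAL = "nonanginal"
    ATYPICAL = "atypical"
    TYPICAL = "typical"


class CcsCategory(str, Enum):
    """Agatston score strata: {0}, (0, 100], (100, 400], (400, inf)."""

    ZERO = "zero"
    GT0_LE100 = "gt0_le100"
    GT100_LE400 = "gt100_le400"
    GT400 = "gt400"


class EventKind(str, Enum):
    CARDIAC_DEATH = "cardiac_death"
    NONFATAL_MI = "nonfatal_mi"
    UNSTABLE_ANGINA_HOSP = "unstable_angina_hosp"
    REVASCULARIZATION = "revascularization"


@dataclass(frozen=True)
class FollowUpEvent:
    kind: EventKind
    time_months: float

    def __post_init__(self) -> None:
        if self.time_months < 0:
            raise DataError(f"event time must be >= 0, got {self.time_months}")


@dataclass
class PatientRecord:
    """One symptomatic individual.

    ``obstructive_cad`` may be supplied directly (validation cohorts that only
    carry the final label) or derived from ``max_stenosis_pct`` and
    ``nonassessable_calcified`` via :func:`classify_obstructive`.
    """

    id: str
    age: float
    sex: Sex
    chest_pain: ChestPain
    diabetes: bool
    hypertension: bool
    hyperlipidemia: bool
    smoking: bool
    family_history: bool
    ccs: float
    max_stenosis_pct: Optional[float] = None
    nonassessable_calcified: Optional[bool] = None
    obstructive_cad: Optional[bool] = None
    followup_months: Optional[float] = None
    events: Optional[list[FollowUpEvent]] = None

    def __post_init__(self) -> None:
        self.sex = Sex(self.sex)
        self.chest_pain = ChestPain(self.chest_pain)
        if not (AGE_MIN <= self.age <= AGE_MAX):
            raise DataError(
                f"record {self.id!r}: age {self.age} outside [{AGE_MIN}, {AGE_MAX}]"
            )
        if self.ccs < 0:
            raise DataError(f"record {self.id!r}: ccs must be >= 0, got {self.ccs}")
        if self.max_stenosis_pct is not None and not (0 <= self.max_stenosis_pct <= 100):
            raise DataError(
                f"record {self.id!r}: max_stenosis_pct outside [0, 100]"
            )
        if self.obstructive_cad is None and (
            self.max_stenosis_pct is None or self.nonassessable_calcified is None
        ):
            raise DataError(
                f"record {self.id!r}: obstructive_cad absent and stenosis/"
                "nonassessable fields incomplete; outcome cannot be derived"
            )
        if self.followup_months is not None and self.followup_months < 0:
            raise DataError(f"record {self.id!r}: followup_months must be >= 0")
        if self.events is not None and self.followup_months is not None:
            for ev in self.events:
                if ev.time_months > self.followup_months + 1e-9:
                    raise DataError(
                        f"record {self.id!r}: event at {ev.time_months} months "
                        f"exceeds follow-up {self.followup_months}"
                    )


@dataclass
class CohortTable:
    """Ordered collection of patient records with a stratum label."""

    records: list[PatientRecord]
    stratum_label: str = ""

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DataError(f"duplicate record ids: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        """Columnar view of the cohort (events excluded)."""
        rows = []
        for r in self.records:
            rows.append(
                dict(
                    id=r.id,
                    age=r.age,
                    sex=r.sex.value,
                    chest_pain=r.chest_pain.value,
                    diabetes=r.diabetes,
                    hypertension=r.hypertension,
                    hyperlipidemia=r.hyperlipidemia,
                    smoking=r.smoking,
                    family_history=r.family_history,
                    ccs=r.ccs,
                    max_stenosis_pct=r.max_stenosis_pct,
                    nonassessable_calcified=r.nonassessable_calcified,
                    obstructive_cad=r.obstructive_cad,
                    followup_months=r.followup_months,
                )
            )
        return pd.DataFrame(rows)

    def outcomes(self) -> list[bool]:
        return [classify_obstructive(r) for r in self.records]


def count_risk_factors(r: PatientRecord) -> int:
    """Number of traditional risk factors present.

    Counts exactly smoking, diabetes, hypertension and hyperlipidemia;
    family history is a model covariate but not part of the risk-factor
    burden that defines the 0-RF / 1-RF strata.
    """
    return sum(bool(getattr(r, f)) for f in RISK_FACTOR_FIELDS)


def classify_obstructive(r: PatientRecord) -> bool:
    """Obstructive CAD: >=50% diameter stenosis in any segment, or any
    non-assessable segment due to severe calcification.

    An explicitly provided ``obstructive_cad`` label takes precedence over
    derivation from stenosis fields.
    """
    if r.obstructive_cad is not None:
        return bool(r.obstructive_cad)
    if r.max_stenosis_pct is None or r.nonassessable_calcified is None:
        raise DataError(f"record {r.id!r}: no source for obstructive-CAD outcome")
    return r.max_stenosis_pct >= 50.0 or bool(r.nonassessable_calcified)


def ccs_category(ccs: float) -> CcsCategory:
    """Agatston-score stratum: {0}, (0,100], (100,400], (400,inf).

    CCS = 0 is its own stratum (absence of detectable coronary calcium is
    qualitatively distinct); the shared printed endpoints 100 and 400 are
    resolved by half-open bins closed on the right.
    """
    if ccs < 0 or math.isnan(ccs):
        raise DataError(f"ccs must be >= 0, got {ccs}")
    if ccs == 0:
        return CcsCategory.ZERO
    if ccs <= 100:
        return CcsCategory.GT0_LE100
    if ccs <= 400:
        return CcsCategory.GT100_LE400
    return CcsCategory.GT400


def classify_mace(r: PatientRecord) -> tuple[bool, list[EventKind]]:
    """MACE composite and the event kinds that contribute to it.

    Cardiac death, nonfatal MI and unstable-angina hospitalization qualify at
    any time; revascularization qualifies only when late (>60 days after
    CCTA), because early revascularizations reflect the index findings rather
    than disease progression.
    """
    if r.events is None:
        raise DataError(f"record {r.id!r}: events list absent")
    kinds: list[EventKind] = []
    for ev in r.events:
        if ev.kind is EventKind.REVASCULARIZATION:
            if ev.time_months > LATE_REVASC_MONTHS:
                kinds.append(ev.kind)
        else:
            kinds.append(ev.kind)
    return (len(kinds) > 0, kinds)


# ---------------------------------------------------------------------------
# CSV I/O

_COHORT_COLUMNS = [
    "id",
    "age",
    "sex",
    "chest_pain",
    "diabetes",
    "hypertension",
    "hyperlipidemia",
    "smoking",
    "family_history",
    "ccs",
    "max_stenosis_pct",
    "nonassessable_calcified",
    "obstructive_cad",
    "followup_months",
]
_MANDATORY = [
    "id",
    "age",
    "sex",
    "chest_pain",
    "diabetes",
    "hypertension",
    "hyperlipidemia",
    "smoking",
    "family_history",
    "ccs",
]

_TRUE = {"1", "true", "yes", "t", "y"}
_FALSE = {"0", "false", "no", "f", "n"}


def _parse_bool(raw: object, *, row: int, col: str) -> Optional[bool]:
    if raw is None:
        return None
    s = str(raw).strip().lower()
    if s in ("", "nan", "na", "none"):
        return None
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    # pandas may have read "1.0"
    try:
        v = float(s)
    except ValueError:
        raise DataError(f"row {row}: cannot parse boolean {col}={raw!r}") from None
    if v in (0.0, 1.0):
        return bool(v)
    raise DataError(f"row {row}: cannot parse boolean {col}={raw!r}")


def _parse_float(raw: object, *, row: int, col: str) -> Optional[float]:
    if raw is None:
        return None
    s = str(raw).strip()
    if s == "" or s.lower() in ("nan", "na", "none"):
        return None
    try:
        return float(s)
    except ValueError:
        raise DataError(f"row {row}: cannot parse number {col}={raw!r}") from None


def read_cohort(
    path: str | Path,
    schema: Optional[Mapping[str, str]] = None,
    events_path: str | Path | None = None,
    stratum_label: str = "",
) -> CohortTable:
    """Read a cohort CSV (plus optional companion events CSV).

    ``schema`` maps canonical column names to the file's column names, for
    ingesting tables with foreign headers.  Booleans accept 0/1, true/false,
    yes/no case-insensitively.  Missing optional columns or blank cells are
    left absent.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"cohort file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    rename = {v: k for k, v in (schema or {}).items()}
    df = df.rename(columns=rename)
    for col in _MANDATORY:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column: {col!r}")

    events_by_id: dict[str, list[FollowUpEvent]] = {}
    have_events = events_path is not None
    if have_events:
        edf = pd.read_csv(events_path, dtype=str, keep_default_na=False)
        for col in ("id", "kind", "time_months"):
            if col not in edf.columns:
                raise SchemaError(f"events file missing column: {col!r}")
        for i, row in enumerate(edf.itertuples(index=False), start=2):
            t = _parse_float(row.time_months, row=i, col="time_months")
            if t is None:
                raise DataError(f"events row {i}: blank time_months")
            events_by_id.setdefault(str(row.id), []).append(
                FollowUpEvent(EventKind(row.kind), t)
            )

    records: list[PatientRecord] = []
    for i, row in enumerate(df.to_dict("records"), start=2):
        get = row.get

        def fnum(col: str) -> Optional[float]:
            return _parse_float(get(col), row=i, col=col)

        def fbool(col: str) -> Optional[bool]:
            return _parse_bool(get(col), row=i, col=col)

        rid = str(row["id"])
        age = fnum("age")
        ccs = fnum("ccs")
        if age is None or ccs is None:
            raise DataError(f"row {i}: blank mandatory cell (age or ccs)")
        required_bools = {}
        for col in ("diabetes", "hypertension", "hyperlipidemia", "smoking", "family_history"):
            b = fbool(col)
            if b is None:
                raise DataError(f"row {i}: blank mandatory cell {col}")
            required_bools[col] = b
        try:
            rec = PatientRecord(
                id=rid,
                age=age,
                sex=Sex(str(row["sex"]).strip().lower()),
                chest_pain=ChestPain(str(row["chest_pain"]).strip().lower()),
                ccs=ccs,
                max_stenosis_pct=fnum("max_stenosis_pct"),
                nonassessable_calcified=fbool("nonassessable_calcified"),
                obstructive_cad=fbool("obstructive_cad"),
                followup_months=fnum("followup_months"),
                events=events_by_id.get(rid) if have_events else None,
                **required_bools,
            )
        except ValueError as e:
            if isinstance(e, DataError):
                raise
            raise DataError(f"row {i}: {e}") from e
        if have_events and rec.followup_months is not None and rec.events is None:
            rec.events = []
        records.append(rec)
    return CohortTable(records, stratum_label=stratum_label)


def _fmt_bool(v: Optional[bool]) -> str:
    return "" if v is None else str(int(v))


def _fmt_num(v: Optional[float]) -> str:
    if v is None:
        return ""
    return repr(float(v))


def write_cohort(
    cohort: CohortTable,
    path: str | Path,
    events_path: str | Path | None = None,
) -> None:
    """Write the cohort (and its events, if requested) as canonical CSV.

    Booleans are emitted as 0/1; floats use ``repr`` so a read/write round
    trip preserves values bit-for-bit.
    """
    rows = []
    for r in cohort.records:
        rows.append(
            dict(
                id=r.id,
                age=_fmt_num(r.age),
                sex=r.sex.value,
                chest_pain=r.chest_pain.value,
                diabetes=_fmt_bool(r.diabetes),
                hypertension=_fmt_bool(r.hypertension),
                hyperlipidemia=_fmt_bool(r.hyperlipidemia),
                smoking=_fmt_bool(r.smoking),
                family_history=_fmt_bool(r.family_history),
                ccs=_fmt_num(r.ccs),
                max_stenosis_pct=_fmt_num(r.max_stenosis_pct),
                nonassessable_calcified=_fmt_bool(r.nonassessable_calcified),
                obstructive_cad=_fmt_bool(r.obstructive_cad),
                followup_months=_fmt_num(r.followup_months),
            )
        )
    pd.DataFrame(rows, columns=_COHORT_COLUMNS).to_csv(path, index=False)
    if events_path is not None:
        erows = []
        for r in cohort.records:
            for ev in r.events or []:
                erows.append(
                    dict(id=r.id, kind=ev.kind.value, time_months=_fmt_num(ev.time_months))
                )
        pd.DataFrame(erows, columns=["id", "kind", "time_months"]).to_csv(
            events_path, index=False
        )
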