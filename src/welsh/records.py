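"""Participant records and delimited-text I/O.

A :class:`ParticipantRecord` carries the demographics, comorbidity flags,
questionnaire marks, completion outcome, WELSH score and 6-minute-walk
maximal walking distance (MWD, meters) of one study participant.  Records
round-trip losslessly through a documented CSV column dictionary
(:data:`COLUMNS`); malformed rows are collected into a rejects report rather
than silently dropped.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, fields, replace
from typing import Optional, Sequence, Union

import pandas as pd

from .qc import CompletionOutcome, Status
from .scoring import DOUBLE, MISSING, Minutes, Pace, RawResponse, Sentinel


class Sex(enum.Enum):
    MALE = "male"
    FEMALE = "female"

    def __repr__(self) -> str:
        return self.name


class Education(enum.Enum):
    """School-level strata, ordered none < primary < secondary < university."""

    NONE = "none"
    PRIMARY = "primary"
    SECONDARY = "secondary"
    UNIVERSITY = "university"

    def __repr__(self) -> str:
        return self.name


COMORBIDITY_FIELDS = ("hypertension", "diabetes", "arthrosis", "pulmonary", "sickle_cell")


@dataclass(frozen=True)
class ParticipantRecord:
    """One participant: demographics, WELSH sheet, completion outcome, MWD."""

    id: str
    sex: Sex
    education: Education
    age: float
    weight_kg: float
    height_cm: float
    smoker: bool
    hypertension: bool
    diabetes: bool
    arthrosis: bool
    pulmonary: bool
    sickle_cell: bool
    #: final (investigator-corrected) questionnaire marks
    response: RawResponse
    #: the sheet as first handed back, if it differed from the final marks
    first_attempt: Optional[RawResponse] = None
    outcome: Optional[CompletionOutcome] = None
    score: Optional[int] = None
    mwd: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mwd is not None and self.mwd < 0:
            raise ValueError(f"mwd={self.mwd} must be non-negative")

    @property
    def bmi(self) -> float:
        """Body-mass index (kg/m^2), derived from weight and height."""
        return self.weight_kg / (self.height_cm / 100.0) ** 2


#: CSV column dictionary, in file order.
COLUMNS = (
    "id", "sex", "education", "age", "weight_kg", "height_cm", "bmi",
    "smoker", *COMORBIDITY_FIELDS,
    "t_turtle", "t_human", "t_rabbit", "pace",
    "first_t_turtle", "first_t_human", "first_t_rabbit", "first_pace",
    "completion_round", "n_errors_corrected", "completion_status",
    "score", "mwd_m",
)


@dataclass(frozen=True)
class RejectedRow:
    """A row that failed parsing, with its position and the reason."""

    row: int
    reason: str


def _fmt_minutes(v: Optional[Minutes]) -> str:
    if v is None:
        return ""
    return v.value if isinstance(v, Sentinel) else str(v)


def _fmt_pace(v) -> str:
    if v is None:
        return ""
    return v.value if isinstance(v, Sentinel) else v.name.lower()


def _parse_minutes(s: str, col: str) -> Minutes:
    s = s.strip().lower()
    if s in ("missing", "double"):
        return Sentinel(s)
    try:
        f = float(s)
    except ValueError:
        raise ValueError(f"{col}: {s!r} is not minutes or a sentinel") from None
    if f != int(f):
        raise ValueError(f"{col}: fractional minutes {s!r} are not a valid dial mark")
    return int(f)


def _parse_pace(s: str, col: str) -> Union[Pace, Sentinel]:
    s = s.strip().lower()
    if s in ("missing", "double"):
        return Sentinel(s)
    try:
        return Pace[s.upper()]
    except KeyError:
        raise ValueError(f"{col}: unknown pace {s!r}") from None


def record_to_row(rec: ParticipantRecord) -> dict:
    fa = rec.first_attempt
    return {
        "id": rec.id,
        "sex": rec.sex.value,
        "education": rec.education.value,
        "age": rec.age,
        "weight_kg": rec.weight_kg,
        "height_cm": rec.height_cm,
        "bmi": rec.bmi,
        "smoker": int(rec.smoker),
        **{f: int(getattr(rec, f)) for f in COMORBIDITY_FIELDS},
        "t_turtle": _fmt_minutes(rec.response.t_turtle),
        "t_human": _fmt_minutes(rec.response.t_human),
        "t_rabbit": _fmt_minutes(rec.response.t_rabbit),
        "pace": _fmt_pace(rec.response.pace),
        "first_t_turtle": _fmt_minutes(fa.t_turtle) if fa else "",
        "first_t_human": _fmt_minutes(fa.t_human) if fa else "",
        "first_t_rabbit": _fmt_minutes(fa.t_rabbit) if fa else "",
        "first_pace": _fmt_pace(fa.pace) if fa else "",
        "completion_round": rec.outcome.round if rec.outcome else "",
        "n_errors_corrected": rec.outcome.n_errors_corrected if rec.outcome else "",
        "completion_status": rec.outcome.status.value if rec.outcome else "",
        "score": "" if rec.score is None else rec.score,
        "mwd_m": "" if rec.mwd is None else rec.mwd,
    }


def row_to_record(row: dict) -> ParticipantRecord:
    sex_s = str(row["sex"]).strip().lower()
    try:
        sex = Sex(sex_s)
    except ValueError:
        raise ValueError(f"sex: unknown code {sex_s!r}") from None
    edu_s = str(row["education"]).strip().lower()
    try:
        education = Education(edu_s)
    except ValueError:
        raise ValueError(f"education: unknown code {edu_s!r}") from None

    response = RawResponse(
        t_turtle=_parse_minutes(str(row["t_turtle"]), "t_turtle"),
        t_human=_parse_minutes(str(row["t_human"]), "t_human"),
        t_rabbit=_parse_minutes(str(row["t_rabbit"]), "t_rabbit"),
        pace=_parse_pace(str(row["pace"]), "pace"),
    )
    first_attempt = None
    if str(row.get("first_t_turtle", "")).strip() != "":
        first_attempt = RawResponse(
            t_turtle=_parse_minutes(str(row["first_t_turtle"]), "first_t_turtle"),
            t_human=_parse_minutes(str(row["first_t_human"]), "first_t_human"),
            t_rabbit=_parse_minutes(str(row["first_t_rabbit"]), "first_t_rabbit"),
            pace=_parse_pace(str(row["first_pace"]), "first_pace"),
        )
    outcome = None
    if str(row.get("completion_status", "")).strip() != "":
        outcome = CompletionOutcome(
            round=int(float(row["completion_round"])),
            n_errors_corrected=int(float(row["n_errors_corrected"])),
            status=Status(str(row["completion_status"]).strip().lower()),
        )
    score_s = str(row.get("score", "")).strip()
    mwd_s = str(row.get("mwd_m", "")).strip()
    mwd = float(mwd_s) if mwd_s != "" else None
    if mwd is not None and mwd < 0:
        raise ValueError(f"mwd_m: negative walking distance {mwd}")
    return ParticipantRecord(
        id=str(row["id"]),
        sex=sex,
        education=education,
        age=float(row["age"]),
        weight_kg=float(row["weight_kg"]),
        height_cm=float(row["height_cm"]),
        smoker=bool(int(float(row["smoker"]))),
        **{f: bool(int(float(row[f]))) for f in COMORBIDITY_FIELDS},
        response=response,
        first_attempt=first_attempt,
        outcome=outcome,
        score=int(float(score_s)) if score_s != "" else None,
        mwd=mwd,
    )


def write_records(records: Sequence[ParticipantRecord], path) -> None:
    """Write records as CSV under the :data:`COLUMNS` dictionary."""
    df = pd.DataFrame([record_to_row(r) for r in records], columns=COLUMNS)
    df.to_csv(path, index=False)


def read_records(path) -> tuple[list[ParticipantRecord], list[RejectedRow]]:
    """Read a participant CSV; malformed rows go to the rejects report."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in ("id", "sex", "education", "t_turtle", "t_human",
                                "t_rabbit", "pace") if c not in df.columns]
    if missing_cols:
        raise ValueError(f"input file lacks required columns: {missing_cols}")
    records: list[ParticipantRecord] = []
    rejects: list[RejectedRow] = []
    for i, row in enumerate(df.to_dict(orient="records")):
        try:
            records.append(row_to_record(row))
        except (ValueError, KeyError) as exc:
            rejects.append(RejectedRow(row=i, reason=str(exc)))
    return records, rejects
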