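"""Domain types for clinical encounters and their JSONL/CSV serialization.

An :class:`Encounter` is the unit the sentry scans: one clinical visit with
its free-text notes (social work, care coordination, ED triage), coded
diagnoses, and basic demographics. Timestamps are ISO-8601; naive values are
interpreted as UTC and all comparisons happen in UTC so that 15-minute batch
windows order unambiguously.
"""

from __future__ import annotations

import csv
import json
import logging
from datetime import datetime, timedelta, timezone
from enum import Enum
from pathlib import Path
from typing import Iterable, List, Literal, Union

from pydantic import BaseModel, Field, field_serializer, field_validator, model_validator

logger = logging.getLogger(__name__)

__all__ = [
    "EncounterType",
    "Sex",
    "NoteType",
    "NoteDocument",
    "DiagnosisCode",
    "Encounter",
    "EncounterParseError",
    "read_encounters",
    "write_encounters",
    "normalize_code",
]

CSV_COLUMNS = [
    "encounter_id",
    "patient_id",
    "start_time",
    "facility_id",
    "encounter_type",
    "sex",
    "age_years",
    "disposition",
    "notes_json",
    "diagnoses_json",
]

#: Notes may precede the formal visit start by at most this much (triage,
#: pre-registration documentation).
NOTE_LEAD_WINDOW = timedelta(hours=24)


class EncounterType(str, Enum):
    ED = "ED"
    INPATIENT = "inpatient"
    OUTPATIENT = "outpatient"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class NoteType(str, Enum):
    SOCIAL_WORK = "social_work"
    CARE_COORDINATION = "care_coordination"
    ED_TRIAGE = "ed_triage"
    OTHER = "other"


def _to_utc(value: datetime) -> datetime:
    if value.tzinfo is None:
        return value.replace(tzinfo=timezone.utc)
    return value.astimezone(timezone.utc)


def normalize_code(code: str) -> str:
    """Canonical ICD-10-CM form: uppercase, dot and internal whitespace removed."""
    return "".join(code.upper().split()).replace(".", "")


class NoteDocument(BaseModel):
    note_id: str
    note_type: NoteType = NoteType.OTHER
    created_at: datetime
    text: str = ""

    @field_validator("note_type", mode="before")
    @classmethod
    def _coerce_note_type(cls, v):
        if isinstance(v, str) and v not in NoteType._value2member_map_:
            logger.warning("unknown note_type %r mapped to 'other'", v)
            return NoteType.OTHER
        return v

    @field_validator("created_at")
    @classmethod
    def _utc(cls, v: datetime) -> datetime:
        return _to_utc(v)

    @field_serializer("created_at")
    def _ser_dt(self, v: datetime) -> str:
        return v.isoformat(timespec="seconds")


class DiagnosisCode(BaseModel):
    code: str
    description: str = ""
    coded_at: datetime

    @field_validator("code")
    @classmethod
    def _valid_code(cls, v: str) -> str:
        norm = normalize_code(v)
        if not norm or not norm.isalnum():
            raise ValueError(f"ICD-10 code {v!r} is empty or non-alphanumeric after normalization")
        return v

    @field_validator("coded_at")
    @classmethod
    def _utc(cls, v: datetime) -> datetime:
        return _to_utc(v)

    @field_serializer("coded_at")
    def _ser_dt(self, v: datetime) -> str:
        return v.isoformat(timespec="seconds")

    @property
    def normalized(self) -> str:
        return normalize_code(self.code)


class Encounter(BaseModel):
    encounter_id: str = Field(min_length=1)
    patient_id: str = Field(min_length=1)
    start_time: datetime
    facility_id: str = ""
    encounter_type: EncounterType = EncounterType.ED
    sex: Sex = Sex.UNKNOWN
    age_years: float = Field(ge=0)
    notes: List[NoteDocument] = Field(default_factory=list)
    diagnoses: List[DiagnosisCode] = Field(default_factory=list)
    disposition: str = ""

    @field_validator("start_time")
    @classmethod
    def _utc(cls, v: datetime) -> datetime:
        return _to_utc(v)

    @field_serializer("start_time")
    def _ser_dt(self, v: datetime) -> str:
        return v.isoformat(timespec="seconds")

    @model_validator(mode="after")
    def _check_notes(self) -> "Encounter":
        seen = set()
        for note in self.notes:
            if note.note_id in seen:
                raise ValueError(f"duplicate note_id {note.note_id!r} in encounter {self.encounter_id!r}")
            seen.add(note.note_id)
            if note.created_at < self.start_time - NOTE_LEAD_WINDOW:
                raise ValueError(
                    f"note {note.note_id!r} created_at {note.created_at.isoformat()} precedes "
                    f"the visit window of encounter {self.encounter_id!r}"
                )
        return self


class EncounterParseError(ValueError):
    """Raised when a serialized encounter record is malformed.

    Carries the 1-based line (JSONL) or row (CSV) number so a bad record in a
    feed can be located without re-parsing.
    """

    def __init__(self, line: int, message: str):
        self.line = line
        super().__init__(f"line {line}: {message}")


def _encounter_from_record(record: dict, line: int) -> Encounter:
    try:
        return Encounter.model_validate(record)
    except Exception as exc:  # pydantic ValidationError carries field locs
        raise EncounterParseError(line, str(exc)) from exc


def read_encounters(path: Union[str, Path], format: Literal["jsonl", "csv"] = "jsonl") -> List[Encounter]:
    """Read encounters from *path*, validating every record.

    Records are returned in file order. Malformed records raise
    :class:`EncounterParseError` naming the offending line; a duplicate
    ``encounter_id`` within the file is an error.
    """
    path = Path(path)
    encounters: List[Encounter] = []
    if format == "jsonl":
        with path.open("r", encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, start=1):
                raw = raw.strip()
                if not raw:
                    continue
                try:
                    record = json.loads(raw)
                except json.JSONDecodeError as exc:
                    raise EncounterParseError(lineno, f"invalid JSON: {exc}") from exc
                encounters.append(_encounter_from_record(record, lineno))
    elif format == "csv":
        with path.open("r", encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            for rowno, row in enumerate(reader, start=2):  # header is line 1
                record = {k: v for k, v in row.items() if k not in ("notes_json", "diagnoses_json")}
                for json_col, field in (("notes_json", "notes"), ("diagnoses_json", "diagnoses")):
                    cell = row.get(json_col) or "[]"
                    try:
                        record[field] = json.loads(cell)
                    except json.JSONDecodeError as exc:
                        raise EncounterParseError(rowno, f"invalid JSON in {json_col}: {exc}") from exc
                encounters.append(_encounter_from_record(record, rowno))
    else:
        raise ValueError(f"unknown format {format!r}; expected 'jsonl' or 'csv'")

    seen_ids = set()
    for i, enc in enumerate(encounters, start=1):
        if enc.encounter_id in seen_ids:
            raise EncounterParseError(i, f"duplicate encounter_id {enc.encounter_id!r}")
        seen_ids.add(enc.encounter_id)
    return encounters


def write_encounters(
    encounters: Iterable[Encounter],
    path: Union[str, Path],
    format: Literal["jsonl", "csv"] = "jsonl",
) -> None:
    """Write encounters so that :func:`read_encounters` round-trips them."""
    path = Path(path)
    encounters = list(encounters)
    if format == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for enc in encounters:
                fh.write(json.dumps(enc.model_dump(mode="json"), ensure_ascii=False) + "\n")
    elif format == "csv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=CSV_COLUMNS)
            writer.writeheader()
            for enc in encounters:
                record = enc.model_dump(mode="json")
                row = {k: record[k] for k in CSV_COLUMNS if k in record}
                row["notes_json"] = json.dumps(record["notes"], ensure_ascii=False)
                row["diagnoses_json"] = json.dumps(record["diagnoses"], ensure_ascii=False)
                writer.writerow(row)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'jsonl' or 'csv'")
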