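"""Micro-batch scanning of encounters against the active phenotype.

The sentry applies the date-appropriate rule set to each incoming batch of
encounters and emits at most one :class:`Alert` per encounter, aggregating
every distinct (pattern, source) hit as :class:`MatchEvidence`. Patients who
have alerted before are re-surfaced on every subsequent visit (longitudinal
follow-up) so one navigator can keep building rapport over time.

Alert identifiers are deterministic hashes of (encounter_id, fired_at), so a
re-run over the same feed produces byte-identical alerts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from enum import Enum
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple, Union

from pydantic import BaseModel, Field

from .ehr_model import Encounter, EncounterType, Sex
from .phenotype_ruleset import RuleSet, RuleSetVersion, assemble_ruleset_as_of

logger = logging.getLogger(__name__)

__all__ = [
    "EvidenceSource",
    "AlertStatus",
    "MatchEvidence",
    "Alert",
    "UtilizationFlag",
    "SentryConfig",
    "PatientHistory",
    "RetroReport",
    "scan_encounter",
    "run_batch",
    "scan_stream",
    "retrospective_scan",
    "read_alerts",
    "write_alerts",
]

LONGITUDINAL_TAG = "longitudinal_followup"
UTILIZATION_TAG = "ed_utilization"


class EvidenceSource(str, Enum):
    NOTE_TEXT = "note_text"
    DIAGNOSIS_CODE = "diagnosis_code"
    DIAGNOSIS_DESCRIPTION = "diagnosis_description"
    UTILIZATION = "utilization"


class AlertStatus(str, Enum):
    PENDING = "pending"
    SCREENED = "screened"
    EXPIRED = "expired"


class MatchEvidence(BaseModel):
    pattern_raw: str
    source: EvidenceSource
    source_id: str
    span: Optional[Tuple[int, int]] = None
    matched_text: str = ""


class Alert(BaseModel):
    alert_id: str
    encounter_id: str
    patient_id: str
    fired_at: datetime
    evidence: List[MatchEvidence] = Field(min_length=1)
    is_repeat: bool = False
    status: AlertStatus = AlertStatus.PENDING


class UtilizationFlag(BaseModel):
    patient_id: str
    window_days: int = Field(gt=0)
    ed_visit_count: int = Field(ge=0)
    threshold: int = Field(gt=0)

    @property
    def fires(self) -> bool:
        return self.ed_visit_count >= self.threshold


@dataclass
class SentryConfig:
    """Tunable engine behavior.

    The utilization threshold (>=4 ED visits in 90 days) is an artifact
    default, not an empirically derived value; increased ED utilization is a
    recognized risk marker but no published cutoff exists.
    """

    utilization_threshold: int = 4
    utilization_window_days: int = 90
    longitudinal_followup: bool = True


@dataclass
class PatientHistory:
    """Mutable index of prior alerts and ED visits, persistable as JSON."""

    alerted_patients: Set[str] = field(default_factory=set)
    alerted_encounters: Set[str] = field(default_factory=set)
    ed_visits: Dict[str, Set[str]] = field(default_factory=dict)  # patient -> ISO timestamps

    def record_ed_visit(self, patient_id: str, when: datetime) -> None:
        self.ed_visits.setdefault(patient_id, set()).add(when.isoformat(timespec="seconds"))

    def ed_visit_count(self, patient_id: str, as_of: datetime, window_days: int) -> int:
        visits = self.ed_visits.get(patient_id, ())
        lo = as_of - timedelta(days=window_days)
        count = 0
        for iso in visits:
            ts = datetime.fromisoformat(iso)
            if lo < ts <= as_of:
                count += 1
        return count

    def record_alert(self, alert: Alert) -> None:
        self.alerted_patients.add(alert.patient_id)
        self.alerted_encounters.add(alert.encounter_id)

    def to_dict(self) -> dict:
        return {
            "alerted_patients": sorted(self.alerted_patients),
            "alerted_encounters": sorted(self.alerted_encounters),
            "ed_visits": {p: sorted(v) for p, v in sorted(self.ed_visits.items())},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PatientHistory":
        return cls(
            alerted_patients=set(d.get("alerted_patients", ())),
            alerted_encounters=set(d.get("alerted_encounters", ())),
            ed_visits={p: set(v) for p, v in d.get("ed_visits", {}).items()},
        )

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1), encoding="utf-8")

    @classmethod
    def load(cls, path: Union[str, Path]) -> "PatientHistory":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def _alert_id(encounter_id: str, fired_at: datetime) -> str:
    digest = hashlib.sha1(f"{encounter_id}|{fired_at.isoformat(timespec='seconds')}".encode()).hexdigest()
    return f"A{digest[:16]}"


def scan_encounter(
    enc: Encounter,
    rules: RuleSet,
    history: Optional[PatientHistory] = None,
    config: SentryConfig = SentryConfig(),
    fired_at: Optional[datetime] = None,
) -> Optional[Alert]:
    """Scan one encounter; return an :class:`Alert` or ``None``.

    An alert fires iff at least one keyword matches any note text (respecting
    the pattern's sex scope), a diagnosis code matches a code pattern
    (normalized compare; prefix mode covers code extensions), the
    ED-utilization flag fires, or the patient has alerted before and
    longitudinal follow-up is enabled. Empty notes and diagnosis lists are
    legal — simply no match.

    The *history* is read, never mutated here; :func:`run_batch` owns updates.
    """
    fired_at = fired_at or enc.start_time
    evidence: List[MatchEvidence] = []

    matcher = rules.matcher_for_sex(enc.sex)
    for note in enc.notes:
        for kw, start, end, matched in matcher.match_text(note.text):
            evidence.append(
                MatchEvidence(
                    pattern_raw=kw.raw,
                    source=EvidenceSource.NOTE_TEXT,
                    source_id=note.note_id,
                    span=(start, end),
                    matched_text=matched,
                )
            )

    for dx in enc.diagnoses:
        for cp in rules.match_codes(dx.code):
            evidence.append(
                MatchEvidence(
                    pattern_raw=cp.raw_code,
                    source=EvidenceSource.DIAGNOSIS_CODE,
                    source_id=dx.code,
                    matched_text=dx.code,
                )
            )
        for cp, (start, end) in rules.match_code_descriptions(dx.description):
            evidence.append(
                MatchEvidence(
                    pattern_raw=cp.description,
                    source=EvidenceSource.DIAGNOSIS_DESCRIPTION,
                    source_id=dx.code,
                    span=(start, end),
                    matched_text=dx.description[start:end],
                )
            )

    if history is not None and enc.encounter_type == EncounterType.ED:
        count = history.ed_visit_count(enc.patient_id, enc.start_time, config.utilization_window_days)
        flag = UtilizationFlag(
            patient_id=enc.patient_id,
            window_days=config.utilization_window_days,
            ed_visit_count=count,
            threshold=config.utilization_threshold,
        )
        if flag.fires:
            evidence.append(
                MatchEvidence(
                    pattern_raw=UTILIZATION_TAG,
                    source=EvidenceSource.UTILIZATION,
                    source_id=enc.patient_id,
                    matched_text=f"{count} ED visits in {config.utilization_window_days} days",
                )
            )

    is_repeat = history is not None and enc.patient_id in history.alerted_patients
    if is_repeat and config.longitudinal_followup:
        evidence.append(
            MatchEvidence(
                pattern_raw=LONGITUDINAL_TAG,
                source=EvidenceSource.UTILIZATION,
                source_id=enc.patient_id,
                matched_text="subsequent visit of previously alerted patient",
            )
        )

    if not evidence:
        return None
    return Alert(
        alert_id=_alert_id(enc.encounter_id, fired_at),
        encounter_id=enc.encounter_id,
        patient_id=enc.patient_id,
        fired_at=fired_at,
        evidence=evidence,
        is_repeat=is_repeat,
    )


def run_batch(
    encounters: Sequence[Encounter],
    versions: Sequence[RuleSetVersion],
    batch_time: datetime,
    history: PatientHistory,
    config: SentryConfig = SentryConfig(),
    window_minutes: int = 15,
) -> List[Alert]:
    """Scan one micro-batch with the ruleset active at *batch_time*.

    Output order is deterministic (by encounter_id); encounters already
    alerted in *history* are skipped so re-running a batch never duplicates
    alerts. Late-arriving encounters (outside the batch window) are warned
    about but still scanned with the current ruleset.
    """
    rules = assemble_ruleset_as_of(versions, batch_time.date())
    window_start = batch_time - timedelta(minutes=window_minutes)
    alerts: List[Alert] = []
    for enc in sorted(encounters, key=lambda e: e.encounter_id):
        if not (window_start < enc.start_time <= batch_time):
            logger.warning(
                "encounter %s start_time %s outside batch window ending %s; scanning anyway",
                enc.encounter_id, enc.start_time.isoformat(), batch_time.isoformat(),
            )
        if enc.encounter_id in history.alerted_encounters:
            continue
        if enc.encounter_type == EncounterType.ED:
            history.record_ed_visit(enc.patient_id, enc.start_time)
        alert = scan_encounter(enc, rules, history=history, config=config, fired_at=batch_time)
        if alert is not None:
            alerts.append(alert)
            history.record_alert(alert)
    return alerts


def scan_stream(
    encounters: Sequence[Encounter],
    versions: Sequence[RuleSetVersion],
    batch_minutes: int = 15,
    history: Optional[PatientHistory] = None,
    config: SentryConfig = SentryConfig(),
) -> Tuple[List[Alert], PatientHistory]:
    """Run a whole encounter stream through consecutive micro-batches.

    Encounters are bucketed into ``batch_minutes`` windows by start time and
    each bucket is scanned with :func:`run_batch` at the window's end.
    """
    if history is None:
        history = PatientHistory()
    if not encounters:
        return [], history
    ordered = sorted(encounters, key=lambda e: (e.start_time, e.encounter_id))
    step = timedelta(minutes=batch_minutes)
    epoch = ordered[0].start_time.replace(hour=0, minute=0, second=0, microsecond=0)
    alerts: List[Alert] = []
    batch: List[Encounter] = []
    batch_end: Optional[datetime] = None
    for enc in ordered:
        offset = (enc.start_time - epoch).total_seconds()
        slots = max(1, math.ceil(offset / step.total_seconds()))  # window is (start, end]
        this_end = epoch + slots * step
        if batch_end is None:
            batch_end = this_end
        if this_end != batch_end:
            alerts.extend(run_batch(batch, versions, batch_end, history, config, batch_minutes))
            batch = []
            batch_end = this_end
        batch.append(enc)
    if batch:
        alerts.extend(run_batch(batch, versions, batch_end, history, config, batch_minutes))
    return alerts, history


@dataclass
class RetroReport:
    """Result of a retrospective scan of an encounter archive."""

    as_of: date
    n_encounters: int
    alerted_encounter_ids: List[str]
    pattern_hits: Dict[str, int]
    sensitivity: Optional[float] = None

    @property
    def n_alerts(self) -> int:
        return len(self.alerted_encounter_ids)

    def to_dict(self) -> dict:
        return {
            "as_of": self.as_of.isoformat(),
            "n_encounters": self.n_encounters,
            "n_alerts": self.n_alerts,
            "alerted_encounter_ids": self.alerted_encounter_ids,
            "pattern_hits": dict(sorted(self.pattern_hits.items())),
            "sensitivity": self.sensitivity,
        }


def retrospective_scan(
    versions: Sequence[RuleSetVersion],
    as_of: date,
    store: Sequence[Encounter],
    labels: Optional[Iterable[str]] = None,
    config: Optional[SentryConfig] = None,
) -> RetroReport:
    """Re-run a fixed ruleset vintage over an encounter archive.

    Longitudinal follow-up is disabled (the question is what the phenotype
    itself would have caught). When *labels* (known-case encounter ids) are
    given, sensitivity = |alerted ∩ labeled| / |labeled|; an empty label set
    yields sensitivity ``None`` rather than zero.
    """
    if config is None:
        config = SentryConfig(longitudinal_followup=False)
    known_ids = {enc.encounter_id for enc in store}
    label_set = set(labels) if labels is not None else set()
    unknown = sorted(label_set - known_ids)
    if unknown:
        raise ValueError(f"labels reference unknown encounter ids: {unknown}")

    rules = assemble_ruleset_as_of(versions, as_of)
    history = PatientHistory()
    alerted: List[str] = []
    hits: Counter = Counter()
    for enc in sorted(store, key=lambda e: (e.start_time, e.encounter_id)):
        if enc.encounter_type == EncounterType.ED:
            history.record_ed_visit(enc.patient_id, enc.start_time)
        alert = scan_encounter(enc, rules, history=history, config=config)
        if alert is not None:
            alerted.append(enc.encounter_id)
            for ev in alert.evidence:
                hits[ev.pattern_raw] += 1

    sensitivity = None
    if label_set:
        sensitivity = len(set(alerted) & label_set) / len(label_set)
    return RetroReport(
        as_of=as_of,
        n_encounters=len(store),
        alerted_encounter_ids=sorted(alerted),
        pattern_hits=dict(hits),
        sensitivity=sensitivity,
    )


def write_alerts(alerts: Iterable[Alert], path: Union[str, Path]) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for alert in alerts:
            fh.write(alert.model_dump_json() + "\n")


def read_alerts(path: Union[str, Path]) -> List[Alert]:
    alerts = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                alerts.append(Alert.model_validate_json(line))
    return alerts
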