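"""Seeded synthetic encounter streams with planted triggers and truth labels.

The generator emulates a mid-sized hospital feed: encounter arrivals are
Poisson per day (default mean 440/day), a small fraction of encounters carry
phenotype triggers — keyword phrases planted into note text (respecting sex
scope) and/or an active ICD-10 code — and everything else is benign text
drawn from a template pool that is rejection-sampled against the generating
ruleset so it can never fire. Ground-truth "true case" labels are a subset
of the trigger encounters, so the alert stream contains both case-like and
noise-like alerts, as a real queue does.

The default trigger prevalence (0.008) is calibrated so that at 440
encounters/day the sentry fires on the order of a handful of alerts per day
(roughly 1–8), the regime a single navigator is expected to face.

All randomness flows through one ``numpy`` generator seeded once; the draw
order is: per-day arrivals, per-encounter attributes, then follow-up visit
scheduling. Inserting a draw stage is a breaking change for reproducibility
and is guarded by a byte-identity test.
"""

from __future__ import annotations

from datetime import date, datetime, timedelta, timezone
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

from .ehr_model import DiagnosisCode, Encounter, EncounterType, NoteDocument, NoteType, Sex
from .phenotype_ruleset import CompiledKeyword, KeywordPattern, RuleSet, compile_keyword

__all__ = [
    "CohortConfig",
    "SyntheticDataError",
    "generate_cohort",
    "plant_phrase",
    "BENIGN_SENTENCES",
    "TRIGGER_TEMPLATES",
    "BENIGN_CODES",
]

# Benign clinical boilerplate, including deliberate near-miss confounders
# ("analysis", "therapist", "assessment", "transportation", "hydration")
# that exercise whole-token boundary matching.
BENIGN_SENTENCES: List[str] = [
    "patient seen for ankle sprain and discharged home in stable condition",
    "routine follow up for diabetes management with labs reviewed",
    "analysis of laboratory results completed with no acute findings",
    "patient education provided regarding medication adherence",
    "assessment completed by the therapist and care plan updated",
    "presented with cough and congestion, supportive care advised",
    "chest pain ruled out and cardiology consult placed",
    "wound dressing changed, healing well at follow up",
    "transportation arranged for discharge to home",
    "immunization administered without complication",
    "mild headache resolved after hydration and rest",
    "physical therapy session completed, gait improving",
]

TRIGGER_TEMPLATES: List[str] = [
    "pt discloses {X} during social work interview",
    "note documents {X} reported by patient",
    "screening positive for {X} per care coordinator",
    "patient states {X} occurred prior to arrival",
    "concern for {X} raised by nursing staff",
]

BENIGN_CODES: List[Tuple[str, str]] = [
    ("E11.9", "Type 2 diabetes mellitus without complications"),
    ("J06.9", "Acute upper respiratory infection, unspecified"),
    ("I10", "Essential (primary) hypertension"),
    ("M54.50", "Low back pain, unspecified"),
    ("R51.9", "Headache, unspecified"),
    ("S93.401A", "Sprain of unspecified ligament of ankle, initial encounter"),
    ("Z23", "Encounter for immunization"),
]

#: Token runs substituted for ``%`` when realizing a wildcard pattern.
WILDCARD_COMPLETIONS: List[str] = ["", "s", "ed", "ing", "al"]

_NOTE_TYPES = [NoteType.SOCIAL_WORK, NoteType.CARE_COORDINATION, NoteType.ED_TRIAGE, NoteType.OTHER]
_ENC_TYPES = [EncounterType.ED, EncounterType.OUTPATIENT, EncounterType.INPATIENT]
_ENC_TYPE_P = [0.6, 0.3, 0.1]


class SyntheticDataError(RuntimeError):
    pass


class CohortConfig(BaseModel):
    """Parameters of the emulated hospital encounter stream.

    The window is [start_date, end_date): one Poisson arrival draw per day.
    """

    start_date: date
    end_date: date
    daily_volume: float = Field(default=440.0, gt=0)
    trigger_prevalence: float = Field(default=0.008, ge=0.0, le=1.0)
    sex_mix: Dict[Sex, float] = Field(
        default_factory=lambda: {Sex.FEMALE: 0.54, Sex.MALE: 0.44, Sex.UNKNOWN: 0.02}
    )
    repeat_visit_rate: float = Field(default=0.2, ge=0.0, le=1.0)
    truth_fraction: float = Field(default=0.4, ge=0.0, le=1.0)
    code_attach_prob: float = Field(default=0.2, ge=0.0, le=1.0)
    seed: int = 0
    benign_templates: List[str] = Field(default_factory=lambda: list(BENIGN_SENTENCES))
    trigger_templates: List[str] = Field(default_factory=lambda: list(TRIGGER_TEMPLATES))
    max_rejection_attempts: int = Field(default=20, gt=0)

    @field_validator("sex_mix")
    @classmethod
    def _mix_ok(cls, v: Dict[Sex, float]) -> Dict[Sex, float]:
        if any(p < 0 for p in v.values()) or not np.isclose(sum(v.values()), 1.0):
            raise ValueError("sex_mix proportions must be non-negative and sum to 1")
        return v

    @model_validator(mode="after")
    def _window_ok(self) -> "CohortConfig":
        if self.start_date >= self.end_date:
            raise ValueError("start_date must precede end_date")
        return self

    @property
    def n_days(self) -> int:
        return (self.end_date - self.start_date).days


def plant_phrase(template: str, pattern: KeywordPattern, rng: np.random.Generator) -> str:
    """Instantiate *template* with a concrete realization of *pattern*.

    Wildcards are realized with a sampled completion (``traffic%`` may become
    ``trafficking``); the result is self-checked against the compiled
    pattern before being returned.
    """
    ck = compile_keyword(pattern.raw)
    realized_tokens = []
    for tok in ck.tokens:
        while "%" in tok:
            tok = tok.replace("%", str(rng.choice(WILDCARD_COMPLETIONS)), 1)
        realized_tokens.append(tok)
    text = template.replace("{X}", " ".join(realized_tokens))
    if not ck.matches_text(text):
        raise SyntheticDataError(
            f"planting {pattern.raw!r} into {template!r} produced text the compiled pattern does not match"
        )
    return text


def _benign_text(
    config: CohortConfig,
    rng: np.random.Generator,
    matcher,
    cache: Dict[str, bool],
) -> str:
    """Compose 1–2 benign sentences, rejection-sampled against the ruleset."""
    for _ in range(config.max_rejection_attempts):
        k = int(rng.integers(1, 3))
        idx = rng.integers(0, len(config.benign_templates), size=k)
        text = ". ".join(config.benign_templates[i] for i in idx)
        clean = cache.get(text)
        if clean is None:
            clean = not matcher.match_text(text)
            cache[text] = clean
        if clean:
            return text
    raise SyntheticDataError(
        "benign template pool cannot avoid the active patterns "
        f"after {config.max_rejection_attempts} rejection attempts"
    )


def generate_cohort(config: CohortConfig, ruleset: RuleSet) -> Tuple[List[Encounter], Set[str]]:
    """Generate a seeded encounter stream plus ground-truth case labels.

    Returns ``(encounters, truth)`` where *truth* is the set of encounter ids
    regarded as genuine cases (a ``truth_fraction`` subset of the trigger
    encounters). Every trigger encounter matches the generating ruleset by
    construction; benign encounters never do. Identical config (including
    seed) and ruleset give byte-identical output.
    """
    if not ruleset.active_keywords and not ruleset.active_codes:
        raise ValueError("ruleset is empty; nothing to plant")
    rng = np.random.default_rng(config.seed)

    # Union-scope matcher: a benign note must be clean for every sex.
    union_matcher = ruleset.matcher_for_sex(Sex.UNKNOWN)
    for code, desc in BENIGN_CODES:
        if ruleset.match_codes(code) or ruleset.match_code_descriptions(desc):
            raise SyntheticDataError(f"benign code pool entry {code!r} collides with the active ruleset")

    sexes = list(config.sex_mix.keys())
    sex_p = [config.sex_mix[s] for s in sexes]
    kw_by_sex: Dict[Sex, List[KeywordPattern]] = {
        s: sorted(ruleset.keywords_for_sex(s), key=lambda kw: (kw.canonical, kw.sex_scope))
        for s in (Sex.MALE, Sex.FEMALE, Sex.UNKNOWN)
    }
    active_codes = sorted(ruleset.active_codes.values(), key=lambda cp: cp.normalized)
    benign_cache: Dict[str, bool] = {}

    encounters: List[Encounter] = []
    truth: Set[str] = set()
    followups: List[Tuple[int, str, Sex, float]] = []  # (day index, patient, sex, age)

    day0 = datetime.combine(config.start_date, datetime.min.time(), tzinfo=timezone.utc)
    for day in range(config.n_days):
        n = int(rng.poisson(config.daily_volume))
        for j in range(n):
            eid = f"E{day:04d}-{j:05d}"
            pid = f"P{day:04d}-{j:05d}"
            start = day0 + timedelta(days=day, seconds=float(rng.uniform(0, 86400)))
            start = start.replace(microsecond=0)
            sex = sexes[int(rng.choice(len(sexes), p=sex_p))]
            age = float(np.round(rng.uniform(16, 85), 1))
            enc_type = _ENC_TYPES[int(rng.choice(len(_ENC_TYPES), p=_ENC_TYPE_P))]
            is_trigger = bool(rng.random() < config.trigger_prevalence) and bool(kw_by_sex[sex])

            notes = [
                NoteDocument(
                    note_id=f"{eid}-n0",
                    note_type=_NOTE_TYPES[int(rng.integers(0, len(_NOTE_TYPES)))],
                    created_at=start,
                    text=_benign_text(config, rng, union_matcher, benign_cache),
                )
            ]
            diagnoses: List[DiagnosisCode] = []
            n_benign_dx = int(rng.integers(0, 3))
            for b in range(n_benign_dx):
                code, desc = BENIGN_CODES[int(rng.integers(0, len(BENIGN_CODES)))]
                diagnoses.append(DiagnosisCode(code=code, description=desc, coded_at=start))

            if is_trigger:
                # mode: keywords only / code only / both
                mode = rng.random()
                want_kw = mode < 0.8 or not active_codes
                want_code = (mode >= 0.6 and active_codes) or not want_kw
                if want_kw:
                    pool = kw_by_sex[sex]
                    n_kw = int(rng.integers(1, 4))
                    sentences = []
                    for _ in range(n_kw):
                        kw = pool[int(rng.integers(0, len(pool)))]
                        tmpl = config.trigger_templates[int(rng.integers(0, len(config.trigger_templates)))]
                        sentences.append(plant_phrase(tmpl, kw, rng))
                    notes.append(
                        NoteDocument(
                            note_id=f"{eid}-n1",
                            note_type=NoteType.SOCIAL_WORK,
                            created_at=start + timedelta(minutes=30),
                            text=". ".join(sentences),
                        )
                    )
                if want_code:
                    cp = active_codes[int(rng.integers(0, len(active_codes)))]
                    diagnoses.append(
                        DiagnosisCode(code=cp.raw_code, description=cp.description, coded_at=start)
                    )
                if rng.random() < config.truth_fraction:
                    truth.add(eid)
                if rng.random() < config.repeat_visit_rate:
                    ret_day = day + int(rng.integers(1, 22))
                    if ret_day < config.n_days:
                        followups.append((ret_day, pid, sex, age))

            encounters.append(
                Encounter(
                    encounter_id=eid,
                    patient_id=pid,
                    start_time=start,
                    facility_id="H1",
                    encounter_type=enc_type,
                    sex=sex,
                    age_years=age,
                    notes=notes,
                    diagnoses=diagnoses,
                    disposition="home",
                )
            )

    for k, (ret_day, pid, sex, age) in enumerate(followups):
        eid = f"F{ret_day:04d}-{k:05d}"
        start = (day0 + timedelta(days=ret_day, seconds=float(rng.uniform(0, 86400)))).replace(microsecond=0)
        encounters.append(
            Encounter(
                encounter_id=eid,
                patient_id=pid,
                start_time=start,
                facility_id="H1",
                encounter_type=_ENC_TYPES[int(rng.choice(len(_ENC_TYPES), p=_ENC_TYPE_P))],
                sex=sex,
                age_years=age,
                notes=[
                    NoteDocument(
                        note_id=f"{eid}-n0",
                        note_type=NoteType.OTHER,
                        created_at=start,
                        text=_benign_text(config, rng, union_matcher, benign_cache),
                    )
                ],
                diagnoses=[],
                disposition="home",
            )
        )

    encounters.sort(key=lambda e: (e.start_time, e.encounter_id))
    return encounters, truth
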