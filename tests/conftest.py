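from datetime import date, datetime, timezone

import pytest

from ehrsentry.ehr_model import DiagnosisCode, Encounter, NoteDocument
from ehrsentry.phenotype_ruleset import assemble_ruleset_as_of, load_default_ruleset_versions


@pytest.fixture(scope="session")
def versions():
    return load_default_ruleset_versions()


@pytest.fixture(scope="session")
def ruleset_2020(versions):
    return assemble_ruleset_as_of(versions, date(2020, 1, 1))


@pytest.fixture(scope="session")
def ruleset_2019q4(versions):
    return assemble_ruleset_as_of(versions, date(2019, 10, 1))


@pytest.fixture
def make_encounter():
    """Factory for minimal valid encounters with optional note text / codes."""

    counter = {"n": 0}

    def _make(
        text=None,
        codes=(),
        sex="female",
        encounter_type="ED",
        start=datetime(2020, 1, 15, 12, 0, tzinfo=timezone.utc),
        patient_id=None,
        encounter_id=None,
        note_type="social_work",
    ):
        counter["n"] += 1
        eid = encounter_id or f"enc-{counter['n']:04d}"
        notes = []
        if text is not None:
            notes = [
                NoteDocument(note_id=f"{eid}-n0", note_type=note_type, created_at=start, text=text)
            ]
        return Encounter(
            encounter_id=eid,
            patient_id=patient_id or f"pat-{counter['n']:04d}",
            start_time=start,
            encounter_type=encounter_type,
            sex=sex,
            age_years=30,
            notes=notes,
            diagnoses=[
                DiagnosisCode(code=c, description=d, coded_at=start)
                for c, d in (codes if codes and isinstance(codes[0], tuple) else [(c, "") for c in codes])
            ],
        )

    return _make
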