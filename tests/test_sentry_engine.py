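from datetime import date, datetime, timedelta, timezone

import pytest

from ehrsentry.ehr_model import Sex
from ehrsentry.phenotype_ruleset import assemble_ruleset_as_of, compile_keyword
from ehrsentry.sentry_engine import (
    LONGITUDINAL_TAG,
    UTILIZATION_TAG,
    EvidenceSource,
    PatientHistory,
    SentryConfig,
    read_alerts,
    retrospective_scan,
    run_batch,
    scan_encounter,
    scan_stream,
    write_alerts,
)

UTC = timezone.utc


def test_note_keyword_alert_with_evidence(make_encounter, ruleset_2019q4):
    enc = make_encounter(
        text="pt discloses forced labor situation",
        start=datetime(2019, 11, 1, tzinfo=UTC),
    )
    alert = scan_encounter(enc, ruleset_2019q4)
    patterns = {ev.pattern_raw for ev in alert.evidence}
    assert {"force%", "forced labor"} <= patterns
    for ev in alert.evidence:
        note = enc.notes[0]
        assert note.text[ev.span[0] : ev.span[1]] == ev.matched_text


def test_code_prefix_alert(make_encounter, ruleset_2020):
    enc = make_encounter(codes=["T74.21XA"])
    alert = scan_encounter(enc, ruleset_2020)
    assert any(
        ev.source == EvidenceSource.DIAGNOSIS_CODE and ev.pattern_raw == "T74.21"
        for ev in alert.evidence
    )


def test_code_description_keyword_match(make_encounter, ruleset_2020):
    # From late 2019 the code patterns also fire on diagnosis description text.
    enc = make_encounter(codes=[("R99", "adult sexual abuse, confirmed at follow up")])
    alert = scan_encounter(enc, ruleset_2020)
    assert any(ev.source == EvidenceSource.DIAGNOSIS_DESCRIPTION for ev in alert.evidence)


def test_male_black_eye_does_not_alert(make_encounter, versions):
    rules = assemble_ruleset_as_of(versions, date(2020, 6, 30))
    male = make_encounter(text="presents with black eye after fall", sex="male")
    female = make_encounter(text="presents with black eye after fall", sex="female")
    assert scan_encounter(male, rules) is None
    assert scan_encounter(female, rules) is not None


def test_benign_encounter_no_alert(make_encounter, ruleset_2020):
    enc = make_encounter(text="analysis of labs completed, assessment by therapist")
    assert scan_encounter(enc, ruleset_2020) is None


def test_empty_notes_and_diagnoses_are_legal(make_encounter, ruleset_2020):
    assert scan_encounter(make_encounter(), ruleset_2020) is None


def test_utilization_flag_fires_at_threshold(make_encounter, ruleset_2020):
    history = PatientHistory()
    t0 = datetime(2020, 2, 1, tzinfo=UTC)
    for i in range(3):
        history.record_ed_visit("freq-pat", t0 + timedelta(days=i))
    enc = make_encounter(patient_id="freq-pat", start=t0 + timedelta(days=10))
    history.record_ed_visit("freq-pat", enc.start_time)
    alert = scan_encounter(enc, ruleset_2020, history=history)
    assert alert is not None
    assert any(ev.pattern_raw == UTILIZATION_TAG for ev in alert.evidence)
    # visits outside the 90-day window do not count
    assert history.ed_visit_count("freq-pat", t0 + timedelta(days=200), 90) == 0


def test_run_batch_empty(versions):
    assert run_batch([], versions, datetime(2020, 1, 1, tzinfo=UTC), PatientHistory()) == []


def test_run_batch_counts_and_order(make_encounter, versions):
    t = datetime(2020, 5, 15, 12, 0, tzinfo=UTC)
    encs = [
        make_encounter(text="routine visit for cough", encounter_id="b-3", start=t),
        make_encounter(text="screening positive for trafficking", encounter_id="b-1", start=t),
        make_encounter(text="medication refill only", encounter_id="b-5", start=t),
        make_encounter(text="pt reports rape by acquaintance", encounter_id="b-4", start=t),
        make_encounter(text="follow up for hypertension", encounter_id="b-2", start=t),
    ]
    alerts = run_batch(encs, versions, t + timedelta(minutes=5), PatientHistory())
    # exactly the 2 trigger-bearing encounters alert, in encounter_id order
    assert [a.encounter_id for a in alerts] == ["b-1", "b-4"]


def test_rape_keyword_vintage(make_encounter, versions):
    t = datetime(2020, 1, 15, 12, 0, tzinfo=UTC)
    enc = [make_encounter(text="pt reports rape by acquaintance", start=t)]
    assert run_batch(enc, versions, t, PatientHistory()) == []
    t2 = datetime(2020, 5, 15, 12, 0, tzinfo=UTC)
    enc2 = [make_encounter(text="pt reports rape by acquaintance", start=t2)]
    assert len(run_batch(enc2, versions, t2, PatientHistory())) == 1


def test_repeat_patient_realerts_with_followup_evidence(make_encounter, versions):
    history = PatientHistory()
    t1 = datetime(2020, 2, 1, 10, 0, tzinfo=UTC)
    first = make_encounter(text="concern for trafficking raised", patient_id="pat-rep", start=t1)
    alerts1 = run_batch([first], versions, t1, history)
    assert len(alerts1) == 1 and not alerts1[0].is_repeat

    t2 = t1 + timedelta(days=30)
    second = make_encounter(text="routine follow up, no concerns", patient_id="pat-rep", start=t2)
    alerts2 = run_batch([second], versions, t2, history)
    assert len(alerts2) == 1
    assert alerts2[0].is_repeat
    assert any(ev.pattern_raw == LONGITUDINAL_TAG for ev in alerts2[0].evidence)

    # disabling longitudinal follow-up suppresses the re-alert
    third = make_encounter(text="routine follow up, no concerns", patient_id="pat-rep", start=t2)
    quiet = run_batch([third], versions, t2, history, config=SentryConfig(longitudinal_followup=False))
    assert quiet == []


def test_rerun_does_not_duplicate_alerts(make_encounter, versions):
    t = datetime(2020, 2, 1, 10, 0, tzinfo=UTC)
    encs = [make_encounter(text="concern for trafficking raised", start=t)]
    history = PatientHistory()
    first = run_batch(encs, versions, t, history)
    second = run_batch(encs, versions, t, history)
    assert len(first) == 1 and second == []


def test_determinism_and_deterministic_alert_ids(make_encounter, versions):
    t = datetime(2020, 2, 1, 10, 0, tzinfo=UTC)
    encs = [
        make_encounter(text="concern for trafficking raised", encounter_id="d-1", start=t),
        make_encounter(text="pt is a runaway troubled teen", encounter_id="d-2", start=t),
    ]
    a = run_batch(encs, versions, t, PatientHistory())
    b = run_batch(encs, versions, t, PatientHistory())
    assert a == b
    assert all(x.alert_id == y.alert_id for x, y in zip(a, b))


def test_evidence_spans_rematch_their_pattern(make_encounter, versions):
    t = datetime(2020, 5, 1, 10, 0, tzinfo=UTC)
    enc = make_encounter(
        text="pt discloses Forced labor; concern for trafficking; history of adult abuse", start=t
    )
    [alert] = run_batch([enc], versions, t, PatientHistory())
    for ev in alert.evidence:
        if ev.source == EvidenceSource.NOTE_TEXT:
            assert compile_keyword(ev.pattern_raw).matches_text(ev.matched_text)


def test_alert_round_trip(tmp_path, make_encounter, versions):
    t = datetime(2020, 5, 1, 10, 0, tzinfo=UTC)
    enc = make_encounter(text="concern for trafficking raised", start=t)
    alerts = run_batch([enc], versions, t, PatientHistory())
    write_alerts(alerts, tmp_path / "a.jsonl")
    assert read_alerts(tmp_path / "a.jsonl") == alerts


def test_history_round_trip(tmp_path, make_encounter, versions):
    t = datetime(2020, 5, 1, 10, 0, tzinfo=UTC)
    history = PatientHistory()
    run_batch([make_encounter(text="concern for trafficking raised", start=t)], versions, t, history)
    history.save(tmp_path / "h.json")
    assert PatientHistory.load(tmp_path / "h.json") == history


def test_scan_stream_batches_by_window(make_encounter, versions):
    base = datetime(2020, 5, 1, 10, 0, tzinfo=UTC)
    encs = [
        make_encounter(text="concern for trafficking raised", encounter_id="s-1", start=base),
        make_encounter(text="pt reports rape", encounter_id="s-2", start=base + timedelta(minutes=40)),
    ]
    alerts, history = scan_stream(encs, versions, batch_minutes=15)
    assert len(alerts) == 2
    assert alerts[0].fired_at < alerts[1].fired_at
    assert history.alerted_encounters == {"s-1", "s-2"}


# ---------------------------------------------------------------------------
# retrospective scans


def test_retrospective_sensitivity_saturated(make_encounter, versions):
    t = datetime(2020, 2, 1, tzinfo=UTC)
    labeled = [
        make_encounter(text="victim of trafficking per social work", encounter_id=f"L{i}", start=t)
        for i in range(3)
    ]
    benign = [make_encounter(text="routine visit for cough", encounter_id=f"B{i}", start=t) for i in range(5)]
    report = retrospective_scan(versions, date(2020, 2, 1), labeled + benign, labels=[e.encounter_id for e in labeled])
    assert report.sensitivity == 1.0
    assert set(report.alerted_encounter_ids) == {"L0", "L1", "L2"}
    assert sum(report.pattern_hits.values()) >= report.n_alerts


def test_retrospective_empty_labels_undefined_sensitivity(make_encounter, versions):
    encs = [make_encounter(text="routine visit", start=datetime(2020, 2, 1, tzinfo=UTC))]
    report = retrospective_scan(versions, date(2020, 2, 1), encs, labels=[])
    assert report.sensitivity is None


def test_retrospective_unknown_labels_error(make_encounter, versions):
    encs = [make_encounter(encounter_id="known", start=datetime(2020, 2, 1, tzinfo=UTC))]
    with pytest.raises(ValueError, match="ghost"):
        retrospective_scan(versions, date(2020, 2, 1), encs, labels=["ghost"])


def test_retrospective_monotone_in_ruleset_date(versions):
    # Later vintages only add patterns for an all-female cohort, so the
    # earlier alerted set is contained in the later one.
    from ehrsentry.synthetic_data import CohortConfig, generate_cohort

    rs = assemble_ruleset_as_of(versions, date(2019, 8, 1))
    cfg = CohortConfig(
        start_date=date(2019, 8, 1),
        end_date=date(2019, 8, 11),
        daily_volume=30,
        trigger_prevalence=0.05,
        sex_mix={Sex.FEMALE: 1.0, Sex.MALE: 0.0, Sex.UNKNOWN: 0.0},
        seed=11,
    )
    encounters, _ = generate_cohort(cfg, rs)
    early = retrospective_scan(versions, date(2019, 8, 1), encounters)
    late = retrospective_scan(versions, date(2020, 8, 1), encounters)
    assert set(early.alerted_encounter_ids) <= set(late.alerted_encounter_ids)
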