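"""Trigger rules, routing, per-item scanning, and oracle equivalence."""

from __future__ import annotations

from datetime import date, datetime, time, timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from symwatch import (
    AlertRuleConfig,
    AssessmentEntry,
    Instrument,
    PatientRecord,
    Routing,
    RuleCode,
    evaluate_day,
    route_alert,
    scan_cohort,
    scan_patient,
)

from conftest import D0, days, entry

CFG = AlertRuleConfig()


def series(*scores, start=D0):
    """Build a date->score map; None marks a missing day."""
    return {
        start + timedelta(days=i): s
        for i, s in enumerate(scores)
        if s is not None
    }


def brute_force_day(s, day, cfg):
    """Naive restatement of the three trigger predicates for one day."""
    fired = set()
    d1, d2 = day - timedelta(days=1), day - timedelta(days=2)
    if s[day] >= cfg.severe_threshold:
        fired.add(RuleCode.SEVERE)
    if d1 in s and s[day] - s[d1] >= cfg.sudden_rise_delta:
        fired.add(RuleCode.SUDDEN_RISE)
    if (
        d1 in s
        and d2 in s
        and s[day] - s[d1] >= cfg.consecutive_rise_delta
        and s[d1] - s[d2] >= cfg.consecutive_rise_delta
    ):
        fired.add(RuleCode.CONSECUTIVE_RISE)
    return fired


class TestEvaluateDay:
    def test_two_consecutive_two_point_rises(self):
        s = series(2, 4, 6)
        assert evaluate_day(s, D0 + timedelta(days=2), CFG) == {
            RuleCode.CONSECUTIVE_RISE
        }

    def test_sudden_rise_and_severe_together(self):
        s = series(5, 8)
        assert evaluate_day(s, D0 + timedelta(days=1), CFG) == {
            RuleCode.SUDDEN_RISE,
            RuleCode.SEVERE,
        }

    def test_severe_needs_no_history(self):
        assert evaluate_day(series(8), D0, CFG) == {RuleCode.SEVERE}

    def test_flat_series_never_fires(self):
        s = series(*([0] * 10))
        for day in s:
            assert evaluate_day(s, day, CFG) == set()

    def test_gap_disables_delta_rules(self):
        s = series(2, None, 6)
        assert evaluate_day(s, D0 + timedelta(days=2), CFG) == set()

    def test_unobserved_day_is_an_error(self):
        with pytest.raises(ValueError, match="no observation"):
            evaluate_day(series(3), D0 + timedelta(days=1), CFG)

    @given(st.lists(st.one_of(st.none(), st.integers(0, 10)),
                    min_size=1, max_size=12))
    @settings(max_examples=200, deadline=None)
    def test_one_day_rise_of_three_fires_regardless_of_older_history(self, scores):
        """A >=3 jump over yesterday always fires SUDDEN_RISE under defaults."""
        s = series(*scores, 2, 5)
        day = D0 + timedelta(days=len(scores) + 1)
        assert RuleCode.SUDDEN_RISE in evaluate_day(s, day, CFG)


class TestRouting:
    WED = date(2021, 3, 3)
    SAT = date(2021, 3, 6)
    MON = date(2021, 3, 1)

    @pytest.mark.parametrize(
        "day,hhmm,expected",
        [
            (WED, (10, 0), Routing.NURSE_IN_HOURS),
            (SAT, (10, 0), Routing.PHYSICIAN_AFTER_HOURS),
            (MON, (17, 30), Routing.PHYSICIAN_AFTER_HOURS),
            (MON, (17, 0), Routing.PHYSICIAN_AFTER_HOURS),  # half-open window
            (MON, (8, 0), Routing.NURSE_IN_HOURS),
            (MON, (7, 59), Routing.PHYSICIAN_AFTER_HOURS),
        ],
    )
    def test_monitoring_window(self, day, hhmm, expected):
        ts = datetime.combine(day, time(*hhmm))
        assert route_alert(ts, CFG) is expected


def record_from(series_by_item, pid="A", hour=9, followup=60):
    entries = [
        entry(pid, d, inst, item, score, hour=hour)
        for (inst, item), s in series_by_item.items()
        for d, score in s.items()
    ]
    return PatientRecord(
        patient_id=pid, enrollment_date=D0, followup_days=followup,
        entries=sorted(entries, key=lambda e: (e.date, str(e.instrument), e.item_code)),
    )


class TestScanPatient:
    def test_single_spiking_item_yields_one_alert(self):
        record = record_from(
            {
                (Instrument.ESAS_R, "pain"): series(1, 9),
                (Instrument.ESAS_R, "nausea"): series(0, 0),
                (Instrument.DT, "distress"): series(0, 0),
            }
        )
        (alert,) = scan_patient(record, CFG)
        assert alert.fired_rules == {RuleCode.SUDDEN_RISE, RuleCode.SEVERE}
        assert alert.date == D0 + timedelta(days=1)
        assert alert.triggering_scores == (1, 9)
        assert alert.routing is Routing.NURSE_IN_HOURS  # Tuesday 09:00

    def test_quiet_record_yields_no_alerts(self):
        record = record_from(
            {
                (Instrument.ESAS_R, "pain"): series(7, 7, 6, 7, 7),
                (Instrument.DT, "distress"): series(3, 4, 3, 4, 3),
            }
        )
        assert scan_patient(record, CFG) == []

    def test_items_are_evaluated_independently(self):
        d3 = D0 + timedelta(days=2)
        record = record_from(
            {
                (Instrument.ESAS_R, "pain"): series(2, 4, 6),
                (Instrument.DT, "distress"): {d3: 8},
            }
        )
        alerts = scan_patient(record, CFG)
        assert [(a.date, a.instrument, a.item_code) for a in alerts] == [
            (d3, Instrument.DT, "distress"),
            (d3, Instrument.ESAS_R, "pain"),
        ]

    def test_other_symptom_is_scanned(self):
        record = record_from(
            {(Instrument.ESAS_R, "other:constipation"): series(1, 9)}
        )
        assert len(scan_patient(record, CFG)) == 1

    def test_missing_timestamp_routes_after_hours(self):
        d = date(2021, 3, 3)  # Wednesday
        record = PatientRecord(
            patient_id="A", enrollment_date=d, followup_days=10,
            entries=[
                AssessmentEntry(
                    patient_id="A", date=d, instrument=Instrument.DT,
                    item_code="distress", score=9, submitted_at=None,
                )
            ],
        )
        (alert,) = scan_patient(record, CFG)
        assert alert.routing is Routing.PHYSICIAN_AFTER_HOURS

    def test_severe_alert_survives_raising_that_days_score(self):
        """Score monotonicity: bumping a day's score never drops SEVERE."""
        base = [1, 5, 8, 3, 8, 8, 0, 9]
        rec = record_from({(Instrument.DT, "distress"): series(*base)})
        severe_days = {
            a.date for a in scan_patient(rec, CFG)
            if RuleCode.SEVERE in a.fired_rules
        }
        for i in range(len(base)):
            bumped = list(base)
            if bumped[i] == 10:
                continue
            bumped[i] += 1
            rec2 = record_from({(Instrument.DT, "distress"): series(*bumped)})
            severe2 = {
                a.date for a in scan_patient(rec2, CFG)
                if RuleCode.SEVERE in a.fired_rules
            }
            assert severe_days <= severe2


def random_series(rng, max_len=90):
    n = int(rng.integers(1, max_len + 1))
    scores = rng.integers(0, 11, size=n)
    present = rng.random(n) < 0.8
    present[int(rng.integers(0, n))] = True  # keep at least one observation
    return {
        D0 + timedelta(days=i): int(scores[i]) for i in range(n) if present[i]
    }


class TestOracleEquivalence:
    def test_scan_matches_brute_force_on_random_gapped_series(self):
        """Engine output equals a naive per-day restatement of the rules."""
        rng = np.random.default_rng(7)
        mismatches = 0
        for _ in range(300):
            s = random_series(rng)
            record = record_from({(Instrument.DT, "distress"): s})
            got = {
                a.date: a.fired_rules for a in scan_patient(record, CFG)
            }
            want = {
                d: frozenset(f)
                for d in s
                if (f := brute_force_day(s, d, CFG))
            }
            if got != want:
                mismatches += 1
        assert mismatches == 0


class TestLogInvariants:
    def test_alert_log_unique_per_patient_day_item(self, small_cohort):
        records, _ = small_cohort
        log = scan_cohort(records, CFG)
        keys = [(a.patient_id, a.date, a.instrument, a.item_code) for a in log]
        assert len(keys) == len(set(keys))

    def test_severe_alerts_consistent_with_threshold(self, small_cohort):
        records, _ = small_cohort
        for a in scan_cohort(records, CFG):
            if RuleCode.SEVERE in a.fired_rules:
                assert a.triggering_scores[-1] >= CFG.severe_threshold
            assert a.fired_rules  # never empty

    def test_identical_inputs_give_byte_identical_logs(self, small_cohort):
        records, _ = small_cohort
        a = scan_cohort(records, CFG).to_frame().to_csv(index=False)
        b = scan_cohort(list(records), CFG).to_frame().to_csv(index=False)
        assert a == b

    def test_raising_thresholds_never_adds_alerts(self, small_cohort):
        records, _ = small_cohort
        stricter = AlertRuleConfig(
            severe_threshold=9, consecutive_rise_delta=3, sudden_rise_delta=4
        )
        assert len(scan_cohort(records, stricter)) <= len(scan_cohort(records, CFG))


def test_config_rejects_inverted_monitoring_window():
    with pytest.raises(ValueError):
        AlertRuleConfig(monitoring_start=time(17), monitoring_end=time(8))
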