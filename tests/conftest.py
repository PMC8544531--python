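"""Shared fixtures: small hand-built cohorts and a fixed-seed simulated one."""

from __future__ import annotations

from datetime import date, datetime, timedelta

import pytest
from hypothesis import settings

from symwatch import AssessmentEntry, Instrument, SimParams, simulate_cohort

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def entry(
    pid: str,
    day: date,
    instrument,
    item: str,
    score,
    hour: int = 9,
) -> AssessmentEntry:
    """Terse entry constructor with a same-day submission timestamp."""
    return AssessmentEntry(
        patient_id=pid,
        date=day,
        instrument=instrument,
        item_code=item,
        score=score,
        submitted_at=datetime.combine(day, datetime.min.time())
        + timedelta(hours=hour),
    )


D0 = date(2021, 3, 1)  # a Monday


def days(n: int) -> list[date]:
    return [D0 + timedelta(days=i) for i in range(n)]


@pytest.fixture(scope="session")
def small_cohort():
    """A 4-patient, 30-day simulated cohort with full ground truth."""
    params = SimParams(n_patients=4, followup_days=30, seed=20210301)
    return simulate_cohort(params)
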