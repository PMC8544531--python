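"""Synthetic symptom-monitoring cohorts with known ground truth.

Real daily self-report streams from palliative-care patients are not
publicly depositable, so this module generates cohorts with the same
statistical structure the monitoring pipeline assumes, along with the
ground truth needed to test every downstream module:

* per-item integer scores following a bounded random walk on the 0-10
  scale, ``s(t+1) = clamp(round(s(t) + eps), 0, 10)`` with Gaussian daily
  noise — giving the day-to-day autocorrelation real symptom diaries show;
* sporadic multi-day **exacerbation episodes** that add a jump of several
  points to one item for a few days (the events the alert rules exist to
  catch), drawn independently per item-day;
* whole-day missingness: each patient-day is completed with probability
  ``adherence_p`` (default 0.8, matching observed completion of daily
  assessments), all three instruments dropped together since they form a
  single daily session — missing completely at random;
* submission timestamps drawn uniformly in the preferred 6 AM-8 PM window.

Generation is fully reproducible: patient ``i`` of a cohort depends only
on ``(seed, i)``, so cohorts are byte-identical across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .scales import ALL_ITEMS, AssessmentEntry, Instrument, PatientRecord

__all__ = [
    "SimParams",
    "ExacerbationEvent",
    "PatientTruth",
    "CohortTruth",
    "simulate_patient",
    "simulate_cohort",
]


class SimParams(BaseModel):
    """Cohort-simulation parameters.

    Defaults mirror a small pilot monitoring cohort: 13 active patients
    followed for 60 days (two months), 80% daily completion, mild
    baseline symptom burden with unit day-to-day noise, and roughly one
    exacerbation per item per month (rate 0.03 per item-day) jumping
    scores by 3-5 points for 2-5 days.
    """

    model_config = {"frozen": True}

    n_patients: int = Field(default=13, ge=0)
    followup_days: int = Field(default=60, gt=0)
    baseline_mean: float = Field(default=2.5, ge=0.0, le=10.0)
    daily_sd: float = Field(default=1.0, ge=0.0)
    exacerbation_rate: float = Field(default=0.03, ge=0.0, le=1.0)
    exacerbation_jump: tuple[int, int] = (3, 5)
    exacerbation_duration_days: tuple[int, int] = (2, 5)
    adherence_p: float = Field(default=0.8, gt=0.0, le=1.0)
    submit_window: tuple[time, time] = (time(6, 0), time(20, 0))
    enrollment_date: date = date(2021, 3, 1)
    seed: int = 0

    @model_validator(mode="after")
    def _ranges_ordered(self) -> "SimParams":
        for name in ("exacerbation_jump", "exacerbation_duration_days"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be an increasing positive range")
        if not self.submit_window[0] < self.submit_window[1]:
            raise ValueError("submit_window must be an increasing time range")
        return self


@dataclass(frozen=True)
class ExacerbationEvent:
    """One planted symptom flare: which item, when, how big, how long."""

    instrument: Instrument
    item_code: str
    onset: date
    duration_days: int
    jump: int


@dataclass
class PatientTruth:
    """Ground truth for one simulated patient."""

    patient_id: str
    events: list[ExacerbationEvent]
    completed: dict[date, bool]


@dataclass
class CohortTruth:
    """Ground truth for a whole simulated cohort."""

    params: SimParams
    patients: dict[str, PatientTruth] = field(default_factory=dict)

    @property
    def n_events(self) -> int:
        return sum(len(p.events) for p in self.patients.values())


def _patient_rng(params: SimParams, patient_index: int) -> np.random.Generator:
    # (seed, index) keys the stream so patients are independent and a
    # cohort is reproducible regardless of generation order
    return np.random.default_rng([params.seed, patient_index])


def simulate_patient(
    params: SimParams, patient_index: int
) -> tuple[PatientRecord, PatientTruth]:
    """Simulate one patient's full follow-up; reproducible from (seed, index)."""
    if patient_index < 0:
        raise ValueError("patient_index must be non-negative")
    rng = _patient_rng(params, patient_index)
    patient_id = f"P{patient_index + 1:02d}"
    days = [
        params.enrollment_date + timedelta(days=i)
        for i in range(params.followup_days)
    ]
    n_days = len(days)

    completed_mask = rng.random(n_days) < params.adherence_p
    # submission second within the preferred window, one per day
    w0 = params.submit_window[0]
    w1 = params.submit_window[1]
    start_s = w0.hour * 3600 + w0.minute * 60 + w0.second
    end_s = w1.hour * 3600 + w1.minute * 60 + w1.second
    submit_seconds = rng.integers(start_s, end_s, size=n_days)

    events: list[ExacerbationEvent] = []
    entries: list[AssessmentEntry] = []
    jump_lo, jump_hi = params.exacerbation_jump
    dur_lo, dur_hi = params.exacerbation_duration_days
    n_items = len(ALL_ITEMS)

    # bounded integer random walks on the latent (pre-flare) scale,
    # one row per item, stepped jointly day by day
    eps = rng.normal(0.0, params.daily_sd, size=(n_items, n_days))
    latent = np.empty((n_items, n_days), dtype=np.int64)
    latent[:, 0] = np.clip(
        np.round(params.baseline_mean + eps[:, 0]), 0, 10
    ).astype(np.int64)
    for t in range(1, n_days):
        latent[:, t] = np.clip(
            np.round(latent[:, t - 1] + eps[:, t]), 0, 10
        ).astype(np.int64)

    # flare onsets: independent Bernoulli per item-day
    onset_mask = rng.random((n_items, n_days)) < params.exacerbation_rate
    flare = np.zeros((n_items, n_days), dtype=np.int64)
    for i, t in zip(*np.nonzero(onset_mask)):
        jump = int(rng.integers(jump_lo, jump_hi + 1))
        duration = int(rng.integers(dur_lo, dur_hi + 1))
        instrument, item = ALL_ITEMS[int(i)]
        events.append(
            ExacerbationEvent(
                instrument=instrument,
                item_code=item,
                onset=days[int(t)],
                duration_days=duration,
                jump=jump,
            )
        )
        flare[i, t : t + duration] += jump

    observed = np.clip(latent + flare, 0, 10)
    submitted_at = [
        datetime.combine(days[t], time(0, 0)) + timedelta(seconds=int(submit_seconds[t]))
        for t in range(n_days)
    ]
    for i, (instrument, item) in enumerate(ALL_ITEMS):
        row = observed[i]
        for t in range(n_days):
            if not completed_mask[t]:
                continue
            entries.append(
                AssessmentEntry(
                    patient_id=patient_id,
                    date=days[t],
                    instrument=instrument,
                    item_code=item,
                    score=int(row[t]),
                    submitted_at=submitted_at[t],
                )
            )

    entries.sort(key=lambda e: (e.date, e.instrument.value, e.item_code))
    record = PatientRecord(
        patient_id=patient_id,
        enrollment_date=params.enrollment_date,
        followup_days=params.followup_days,
        entries=entries,
    )
    truth = PatientTruth(
        patient_id=patient_id,
        events=events,
        completed={days[t]: bool(completed_mask[t]) for t in range(n_days)},
    )
    return record, truth


def simulate_cohort(
    params: Optional[SimParams] = None,
) -> tuple[list[PatientRecord], CohortTruth]:
    """Simulate ``n_patients`` independent patients under one parameter set."""
    params = params or SimParams()
    records: list[PatientRecord] = []
    truth = CohortTruth(params=params)
    for i in range(params.n_patients):
        record, pt = simulate_patient(params, i)
        records.append(record)
        truth.patients[record.patient_id] = pt
    return records, truth
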