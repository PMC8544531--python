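"""Three-rule symptom alerting with monitoring-hours routing.

A patient-day-item is flagged when its daily 0-10 score satisfies any of
three trigger rules:

* ``CONSECUTIVE_RISE`` — an increase of at least ``consecutive_rise_delta``
  (default 2) points on each of ``consecutive_rise_days`` (default 2)
  consecutive days, i.e. three observed consecutive calendar days with two
  successive day-over-day rises of >= 2; the alert attaches to the final day.
* ``SUDDEN_RISE`` — an increase of at least ``sudden_rise_delta`` (default
  3) points over the previous day's score.
* ``SEVERE`` — any score of ``severe_threshold`` (default 8) or higher.

Every 0-10 item of every instrument is evaluated independently, including
the optional ESAS-r "other" symptom and each individual BPI item; alerts
fire on raw item scores, never on composites.  Missing days carry no score
information: a gap disables the delta rules for days that would need the
missing score (no interpolation or carry-forward).

Alerts raised while the nursing team is monitoring (weekdays, 8 AM-5 PM by
default, half-open window) route to ``NURSE_IN_HOURS``; alerts at any other
time — evenings, weekends — route to ``PHYSICIAN_AFTER_HOURS``.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, time, timedelta
from enum import Enum
from typing import Iterable, Mapping, Optional

import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .scales import Instrument, PatientRecord

__all__ = [
    "RuleCode",
    "Routing",
    "AlertRuleConfig",
    "Alert",
    "AlertLog",
    "evaluate_day",
    "route_alert",
    "scan_patient",
    "scan_cohort",
]


class RuleCode(str, Enum):
    CONSECUTIVE_RISE = "CONSECUTIVE_RISE"
    SUDDEN_RISE = "SUDDEN_RISE"
    SEVERE = "SEVERE"


class Routing(str, Enum):
    NURSE_IN_HOURS = "NURSE_IN_HOURS"
    PHYSICIAN_AFTER_HOURS = "PHYSICIAN_AFTER_HOURS"


class AlertRuleConfig(BaseModel):
    """Trigger thresholds and the nurse monitoring schedule.

    ``monitoring_days`` holds ISO weekday indices with Monday = 0; the
    default Monday-Friday schedule with an 8 AM-5 PM window reflects
    nurse-led weekday monitoring, with all other times handled by the
    physician team.  The monitoring window is half-open: an alert at
    exactly ``monitoring_end`` is after-hours.
    """

    model_config = {"frozen": True}

    consecutive_rise_delta: int = Field(default=2, gt=0)
    consecutive_rise_days: int = Field(default=2, gt=0)
    sudden_rise_delta: int = Field(default=3, gt=0)
    severe_threshold: int = Field(default=8, gt=0)
    monitoring_days: frozenset[int] = frozenset({0, 1, 2, 3, 4})
    monitoring_start: time = time(8, 0)
    monitoring_end: time = time(17, 0)

    @field_validator("monitoring_days")
    @classmethod
    def _weekdays_valid(cls, v: frozenset[int]) -> frozenset[int]:
        if not all(0 <= d <= 6 for d in v):
            raise ValueError("monitoring_days must be weekday indices 0-6 (Mon=0)")
        return v

    @model_validator(mode="after")
    def _window_ordered(self) -> "AlertRuleConfig":
        if not self.monitoring_start < self.monitoring_end:
            raise ValueError("monitoring_start must precede monitoring_end")
        return self


@dataclass(frozen=True)
class Alert:
    """One flagged (patient, date, instrument, item) with its fired rules."""

    patient_id: str
    date: date
    instrument: Instrument
    item_code: str
    fired_rules: frozenset[RuleCode]
    triggering_scores: tuple[int, ...]
    routing: Routing

    @property
    def alert_id(self) -> str:
        """Stable reference used to link clinical responses to alerts."""
        return f"{self.patient_id}:{self.date.isoformat()}:{self.instrument.value}:{self.item_code}"


@dataclass(frozen=True)
class AlertLog:
    """Ordered, de-duplicated alert collection plus the config that made it."""

    alerts: tuple[Alert, ...]
    config: AlertRuleConfig

    def __len__(self) -> int:
        return len(self.alerts)

    def __iter__(self):
        return iter(self.alerts)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "patient_id": a.patient_id,
                "date": a.date.isoformat(),
                "instrument": a.instrument.value,
                "item": a.item_code,
                "rules": "+".join(sorted(r.value for r in a.fired_rules)),
                "scores": ";".join(str(s) for s in a.triggering_scores),
                "routing": a.routing.value,
            }
            for a in self.alerts
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "patient_id", "date", "instrument", "item",
                "rules", "scores", "routing",
            ],
        )


def evaluate_day(
    series: Mapping[date, int],
    day: date,
    config: Optional[AlertRuleConfig] = None,
) -> set[RuleCode]:
    """Evaluate the three trigger rules for one patient-item on one day.

    ``series`` maps observed dates to integer scores for a single
    (patient, instrument, item).  Raises ``ValueError`` if ``day`` has no
    observation.  Days missing from ``series`` disable the rise rules
    that would need them.
    """
    config = config or AlertRuleConfig()
    if day not in series:
        raise ValueError(f"no observation for {day.isoformat()}")
    fired: set[RuleCode] = set()
    s0 = series[day]
    if s0 >= config.severe_threshold:
        fired.add(RuleCode.SEVERE)
    prev = series.get(day - timedelta(days=1))
    if prev is not None and s0 - prev >= config.sudden_rise_delta:
        fired.add(RuleCode.SUDDEN_RISE)
    # consecutive rise: `consecutive_rise_days` successive day-over-day
    # increases of >= delta, all on observed consecutive calendar days
    n = config.consecutive_rise_days
    window = [series.get(day - timedelta(days=k)) for k in range(n + 1)]
    if all(v is not None for v in window):
        if all(
            window[k] - window[k + 1] >= config.consecutive_rise_delta
            for k in range(n)
        ):
            fired.add(RuleCode.CONSECUTIVE_RISE)
    return fired


def route_alert(
    submitted_at: datetime, config: Optional[AlertRuleConfig] = None
) -> Routing:
    """Route an alert by when it was raised (clinic-local, naive time).

    Nurse-handled iff the weekday is a monitoring day and the time falls
    in the half-open window [monitoring_start, monitoring_end); otherwise
    the physician after-hours path.
    """
    config = config or AlertRuleConfig()
    in_hours = (
        submitted_at.weekday() in config.monitoring_days
        and config.monitoring_start <= submitted_at.time() < config.monitoring_end
    )
    return Routing.NURSE_IN_HOURS if in_hours else Routing.PHYSICIAN_AFTER_HOURS


def _triggering_scores(
    series: Mapping[date, int], day: date, fired: set[RuleCode],
    config: AlertRuleConfig,
) -> tuple[int, ...]:
    """The 1-3 daily scores that satisfied the fired rules (oldest first)."""
    if RuleCode.CONSECUTIVE_RISE in fired:
        span = config.consecutive_rise_days
    elif RuleCode.SUDDEN_RISE in fired:
        span = 1
    else:
        span = 0
    return tuple(
        series[day - timedelta(days=k)] for k in range(span, -1, -1)
    )


def scan_patient(
    record: PatientRecord, config: Optional[AlertRuleConfig] = None
) -> list[Alert]:
    """Emit one alert per (date, instrument, item) whose rules fire.

    Every scored item of all three instruments is evaluated
    independently on every observed day.  Routing derives from the day's
    submission timestamp; entries without one are treated as submitted
    at midnight (always after-hours).
    """
    config = config or AlertRuleConfig()
    alerts: list[Alert] = []
    for (instrument, item), entries in sorted(
        record.item_series().items(), key=lambda kv: (kv[0][0].value, kv[0][1])
    ):
        series = {d: int(e.score) for d, e in entries.items()}
        for day in sorted(series):
            fired = evaluate_day(series, day, config)
            if not fired:
                continue
            submitted = entries[day].submitted_at or datetime.combine(
                day, time(0, 0)
            )
            alerts.append(
                Alert(
                    patient_id=record.patient_id,
                    date=day,
                    instrument=instrument,
                    item_code=item,
                    fired_rules=frozenset(fired),
                    triggering_scores=_triggering_scores(series, day, fired, config),
                    routing=route_alert(submitted, config),
                )
            )
    alerts.sort(key=lambda a: (a.date, a.instrument.value, a.item_code))
    return alerts


def scan_cohort(
    records: Iterable[PatientRecord],
    config: Optional[AlertRuleConfig] = None,
) -> AlertLog:
    """Scan every patient and collect a deterministic, ordered alert log."""
    config = config or AlertRuleConfig()
    alerts: list[Alert] = []
    for record in sorted(records, key=lambda r: r.patient_id):
        alerts.extend(scan_patient(record, config))
    alerts.sort(
        key=lambda a: (a.patient_id, a.date, a.instrument.value, a.item_code)
    )
    return AlertLog(alerts=tuple(alerts), config=config)
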