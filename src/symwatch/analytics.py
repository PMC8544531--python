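"""Adherence, intervention and cost-avoidance analytics.

The quantities a remote-monitoring pilot reports about itself:

* **Adherence** — the fraction of expected patient-days on which a daily
  self-report session was completed (at least one validated entry that
  day).  The denominator is each patient's follow-up window, optionally
  intersected with an analysis window.
* **Intervention summary** — counts of clinical responses per category,
  the number of alerts that did or did not lead to an intervention, and
  the percentage of alerts requiring intervention (half-up, one decimal).
  Contacts not prompted by an alert (nurse- or patient-initiated calls)
  are tallied separately and never enter the alert denominator.
* **Cost avoidance** — estimated hospital expenditure prevented:
  per-day admission cost x average length of stay x avoided admissions,
  in currency units to two decimals (half-up).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Iterable, Optional, Sequence, Union

from pydantic import BaseModel, Field

from .alerts import Alert, AlertLog
from .scales import PatientRecord

__all__ = [
    "InterventionResponse",
    "InterventionRecord",
    "InterventionSummary",
    "CostModel",
    "AdherenceResult",
    "adherence_rate",
    "intervention_summary",
    "cost_avoidance",
]


class InterventionResponse(str, Enum):
    """Clinical response categories for alert follow-up and other contacts."""

    PHONE_ASSESSMENT = "PHONE_ASSESSMENT"
    URGENT_CLINIC_VISIT = "URGENT_CLINIC_VISIT"
    URGENT_HOME_VISIT = "URGENT_HOME_VISIT"
    EXPECTED_DEATH_SUPPORT = "EXPECTED_DEATH_SUPPORT"
    NO_INTERVENTION_NEEDED = "NO_INTERVENTION_NEEDED"
    NURSE_INITIATED_CALL = "NURSE_INITIATED_CALL"
    PATIENT_INITIATED_CALL = "PATIENT_INITIATED_CALL"


#: Responses that count as a clinical intervention when linked to an alert.
INTERVENTION_RESPONSES = frozenset(
    r for r in InterventionResponse if r != InterventionResponse.NO_INTERVENTION_NEEDED
)


@dataclass(frozen=True)
class InterventionRecord:
    """One clinical response; ``alert_id`` is None for unprompted contacts."""

    response: InterventionResponse
    date: date
    alert_id: Optional[str] = None


@dataclass
class AdherenceResult:
    """Pooled completion: observed patient-days over expected patient-days."""

    observed_days: int
    expected_days: int

    @property
    def rate(self) -> Optional[float]:
        """Completion fraction in [0, 1]; None when no days were expected."""
        if self.expected_days == 0:
            return None
        return self.observed_days / self.expected_days


def adherence_rate(
    records: Iterable[PatientRecord],
    window: Optional[tuple[date, date]] = None,
) -> AdherenceResult:
    """Pooled daily-completion rate across a cohort.

    A patient-day counts as completed when at least one validated entry
    exists on that day — a partial session still evidences a completed
    check-in.  Expected days are each patient's follow-up window
    (enrollment to enrollment + followup_days, half-open), intersected
    with ``window`` (inclusive start, inclusive end) when given.  The
    result is order-invariant in both patients and entries.
    """
    observed = 0
    expected = 0
    for record in records:
        days = record.expected_dates()
        if window is not None:
            lo, hi = window
            days = [d for d in days if lo <= d <= hi]
        day_set = set(days)
        expected += len(day_set)
        observed += len(record.observed_dates() & day_set)
    return AdherenceResult(observed_days=observed, expected_days=expected)


@dataclass
class InterventionSummary:
    """Alert-response accounting for a monitoring period."""

    n_alerts: int
    n_with_intervention: int
    n_without_intervention: int
    pct_requiring_intervention: Optional[float]
    linked_counts: dict[InterventionResponse, int] = field(default_factory=dict)
    unprompted_counts: dict[InterventionResponse, int] = field(default_factory=dict)

    @property
    def n_unprompted(self) -> int:
        return sum(self.unprompted_counts.values())


def _round_half_up(value: Decimal, places: str) -> Decimal:
    return value.quantize(Decimal(places), rounding=ROUND_HALF_UP)


def intervention_summary(
    alerts: Union[AlertLog, Sequence[Alert]],
    interventions: Iterable[InterventionRecord],
) -> InterventionSummary:
    """Summarise clinical responses against the alert log.

    Every ``alert_id`` must resolve to an alert in the log; dangling
    references raise ``ValueError`` listing the offenders.  The
    percentage requiring intervention is 100 x (alerts linked to a
    response other than NO_INTERVENTION_NEEDED) / (total alerts),
    rounded half-up to one decimal, and undefined (None) with zero
    alerts.  Unprompted contacts (``alert_id`` None) are tallied
    separately and never enter the denominator.
    """
    alert_list = list(alerts)
    known_ids = {a.alert_id for a in alert_list}
    interventions = list(interventions)

    dangling = sorted(
        {
            iv.alert_id
            for iv in interventions
            if iv.alert_id is not None and iv.alert_id not in known_ids
        }
    )
    if dangling:
        raise ValueError(
            "intervention records reference unknown alerts: " + ", ".join(dangling)
        )

    linked_counts: dict[InterventionResponse, int] = {}
    unprompted_counts: dict[InterventionResponse, int] = {}
    intervened_alerts: set[str] = set()
    for iv in interventions:
        if iv.alert_id is None:
            unprompted_counts[iv.response] = unprompted_counts.get(iv.response, 0) + 1
            continue
        linked_counts[iv.response] = linked_counts.get(iv.response, 0) + 1
        if iv.response in INTERVENTION_RESPONSES:
            intervened_alerts.add(iv.alert_id)

    n_alerts = len(alert_list)
    n_with = len(intervened_alerts)
    pct: Optional[float] = None
    if n_alerts > 0:
        pct = float(
            _round_half_up(Decimal(100 * n_with) / Decimal(n_alerts), "0.1")
        )
    return InterventionSummary(
        n_alerts=n_alerts,
        n_with_intervention=n_with,
        n_without_intervention=n_alerts - n_with,
        pct_requiring_intervention=pct,
        linked_counts=linked_counts,
        unprompted_counts=unprompted_counts,
    )


class CostModel(BaseModel):
    """Cost-avoidance inputs: admission cost/day, mean stay, avoided count."""

    model_config = {"frozen": True}

    cost_per_day: float = Field(default=850.00, ge=0.0)
    avg_length_of_stay_days: float = Field(default=14.61, ge=0.0)
    avoided_admissions: int = Field(default=5, ge=0)


def cost_avoidance(model: CostModel) -> Decimal:
    """Estimated expenditure prevented, to two decimals (half-up).

    cost_per_day x avg_length_of_stay_days x avoided_admissions.
    """
    total = (
        Decimal(str(model.cost_per_day))
        * Decimal(str(model.avg_length_of_stay_days))
        * Decimal(model.avoided_admissions)
    )
    return _round_half_up(total, "0.01")
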