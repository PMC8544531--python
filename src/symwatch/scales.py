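"""Validated self-report symptom scales and assessment validation.

Three instruments are modelled, each scored on an 11-point (0-10) integer
scale:

* **ESAS-r** (Edmonton Symptom Assessment System, revised): nine fixed
  symptom items rated from 0 (not at all) to 10 (worst possible), plus an
  optional patient-named "Other" symptom (e.g. constipation), encoded here
  as ``other:<label>``.
* **DT** (Distress Thermometer): a single distress item from 0 (no
  distress) to 10 (extreme distress).  A score of 4 or more screens as
  potentially high distress; the screen is an annotation, not an alert.
* **BPI** (Brief Pain Inventory, short form): four pain-severity items
  (worst, least, average, now) and seven pain-interference items.
  Severity and interference composites are arithmetic means, following the
  standard BPI scoring convention (severity requires all four items;
  interference requires at least four of the seven).

This module owns the atomic data model — one :class:`AssessmentEntry` per
patient, calendar day, instrument and item — and the validation step that
turns raw, possibly messy input into clean per-patient records with an
explicit rejection report.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, datetime, timedelta
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "Instrument",
    "ScaleDefinition",
    "AssessmentEntry",
    "PatientRecord",
    "RejectedEntry",
    "SCALE_DEFINITIONS",
    "ESAS_R_ITEMS",
    "DT_ITEMS",
    "BPI_SEVERITY_ITEMS",
    "BPI_INTERFERENCE_ITEMS",
    "ALL_ITEMS",
    "DT_SCREEN_CUTOFF",
    "validate_entries",
    "bpi_composites",
    "distress_screen",
]


class Instrument(str, Enum):
    """The three daily self-report instruments."""

    ESAS_R = "ESAS_R"
    DT = "DT"
    BPI = "BPI"


ESAS_R_ITEMS: tuple[str, ...] = (
    "pain",
    "tiredness",
    "drowsiness",
    "nausea",
    "lack_of_appetite",
    "shortness_of_breath",
    "depression",
    "anxiety",
    "wellbeing",
)

DT_ITEMS: tuple[str, ...] = ("distress",)

BPI_SEVERITY_ITEMS: tuple[str, ...] = (
    "pain_worst",
    "pain_least",
    "pain_average",
    "pain_now",
)

BPI_INTERFERENCE_ITEMS: tuple[str, ...] = (
    "general_activity",
    "mood",
    "walking_ability",
    "normal_work",
    "relations_with_others",
    "sleep",
    "enjoyment_of_life",
)

BPI_ITEMS: tuple[str, ...] = BPI_SEVERITY_ITEMS + BPI_INTERFERENCE_ITEMS

#: DT scores at or above this value screen as elevated distress.
DT_SCREEN_CUTOFF = 4

#: Prefix for the optional patient-named ESAS-r symptom.
OTHER_ITEM_PREFIX = "other:"


@dataclass(frozen=True)
class ScaleDefinition:
    """Static definition of one instrument: items, range, conventions."""

    instrument: Instrument
    item_codes: tuple[str, ...]
    score_min: int = 0
    score_max: int = 10
    allows_other_item: bool = False
    screen_cutoff: Optional[int] = None

    def knows_item(self, item_code: str) -> bool:
        if item_code in self.item_codes:
            return True
        return self.allows_other_item and item_code.startswith(OTHER_ITEM_PREFIX)


SCALE_DEFINITIONS: dict[Instrument, ScaleDefinition] = {
    Instrument.ESAS_R: ScaleDefinition(
        Instrument.ESAS_R, ESAS_R_ITEMS, allows_other_item=True
    ),
    Instrument.DT: ScaleDefinition(
        Instrument.DT, DT_ITEMS, screen_cutoff=DT_SCREEN_CUTOFF
    ),
    Instrument.BPI: ScaleDefinition(Instrument.BPI, BPI_ITEMS),
}

#: Every fixed (instrument, item) pair across the three instruments.
ALL_ITEMS: tuple[tuple[Instrument, str], ...] = tuple(
    (inst, item)
    for inst, defn in SCALE_DEFINITIONS.items()
    for item in defn.item_codes
)


@dataclass(frozen=True)
class AssessmentEntry:
    """One patient-day-instrument-item score — the atomic observation.

    ``score`` is an integer 0-10 after validation; raw (pre-validation)
    entries may carry any value, which is what :func:`validate_entries`
    screens.  ``submitted_at`` is the clinic-local submission timestamp
    and may be absent.
    """

    patient_id: str
    date: date
    instrument: Instrument | str
    item_code: str
    score: object
    submitted_at: Optional[datetime] = None


@dataclass
class PatientRecord:
    """A patient's dated assessment series across all three instruments."""

    patient_id: str
    enrollment_date: date
    followup_days: int = 60
    entries: list[AssessmentEntry] = field(default_factory=list)

    @property
    def followup_end(self) -> date:
        """First date *outside* follow-up (half-open window)."""
        return self.enrollment_date + timedelta(days=self.followup_days)

    def expected_dates(self) -> list[date]:
        return [
            self.enrollment_date + timedelta(days=i)
            for i in range(self.followup_days)
        ]

    def observed_dates(self) -> set[date]:
        return {e.date for e in self.entries}

    def item_series(self) -> dict[tuple[Instrument, str], dict[date, AssessmentEntry]]:
        """Per-(instrument, item) date-indexed entry maps."""
        out: dict[tuple[Instrument, str], dict[date, AssessmentEntry]] = {}
        for e in self.entries:
            out.setdefault((Instrument(e.instrument), e.item_code), {})[e.date] = e
        return out

    def entries_on(self, day: date, instrument: Optional[Instrument] = None
                   ) -> list[AssessmentEntry]:
        return [
            e for e in self.entries
            if e.date == day
            and (instrument is None or Instrument(e.instrument) == instrument)
        ]


@dataclass(frozen=True)
class RejectedEntry:
    """A rejected raw entry with a machine-readable reason code."""

    entry: AssessmentEntry
    reason: str


# Rejection reason codes
REASON_UNKNOWN_INSTRUMENT = "unknown_instrument"
REASON_UNKNOWN_ITEM = "unknown_item"
REASON_SCORE_NOT_INTEGER = "score_not_integer"
REASON_SCORE_OUT_OF_RANGE = "score_out_of_range"
REASON_OUTSIDE_FOLLOWUP = "outside_followup"
REASON_SUPERSEDED = "superseded_duplicate"


def _screen_entry(entry: AssessmentEntry,
                  definitions: Mapping[Instrument, ScaleDefinition]
                  ) -> Optional[str]:
    """Return a rejection reason for a single entry, or None if clean."""
    try:
        inst = Instrument(entry.instrument)
    except ValueError:
        return REASON_UNKNOWN_INSTRUMENT
    defn = definitions.get(inst)
    if defn is None:
        return REASON_UNKNOWN_INSTRUMENT
    if not defn.knows_item(entry.item_code):
        return REASON_UNKNOWN_ITEM
    score = entry.score
    # integers only; integral floats (e.g. 5.0 from JSON) are accepted,
    # fractional values are rejected rather than rounded
    if isinstance(score, bool) or not isinstance(score, (int, float)):
        return REASON_SCORE_NOT_INTEGER
    if isinstance(score, float) and not score.is_integer():
        return REASON_SCORE_NOT_INTEGER
    if not defn.score_min <= int(score) <= defn.score_max:
        return REASON_SCORE_OUT_OF_RANGE
    return None


def validate_entries(
    raw_entries: Iterable[AssessmentEntry],
    definitions: Mapping[Instrument, ScaleDefinition] = SCALE_DEFINITIONS,
    *,
    enrollment_dates: Optional[Mapping[str, date]] = None,
    followup_days: int = 60,
) -> tuple[list[PatientRecord], list[RejectedEntry]]:
    """Validate raw entries into clean per-patient records.

    Screens every entry against its instrument definition (known
    instrument and item, integer score within 0-10), resolves duplicate
    (patient, date, instrument, item) submissions by keeping the entry
    with the latest ``submitted_at`` (ties broken by input order, last
    wins; missing timestamps sort earliest), and drops entries outside
    the patient's follow-up window.

    Parameters
    ----------
    raw_entries
        Entries in input order; may contain duplicates and invalid rows.
    definitions
        Instrument definitions; defaults to the three built-in scales.
    enrollment_dates
        Optional per-patient enrollment dates.  When absent for a
        patient, enrollment is inferred as that patient's earliest
        screened-valid entry date.
    followup_days
        Length of the follow-up window (default 60 days, two months).

    Returns
    -------
    (records, rejections)
        Records sorted by patient id, each satisfying the record
        invariants (unique item per day, dates inside follow-up); every
        rejected input entry appears exactly once in ``rejections`` with
        a reason code.  No entry is silently dropped: accepted + rejected
        counts always equal the input count.
    """
    raw = list(raw_entries)
    rejections: list[RejectedEntry] = []
    screened: list[AssessmentEntry] = []
    for entry in raw:
        reason = _screen_entry(entry, definitions)
        if reason is not None:
            rejections.append(RejectedEntry(entry, reason))
        else:
            inst = Instrument(entry.instrument)
            score = int(entry.score)  # normalise integral floats
            if entry.instrument is not inst or entry.score is not score:
                entry = replace(entry, instrument=inst, score=score)
            screened.append(entry)

    # enrollment windows (inferred from earliest valid date when not given)
    enroll: dict[str, date] = dict(enrollment_dates or {})
    for e in screened:
        if e.patient_id not in enroll:
            enroll[e.patient_id] = e.date
        elif enrollment_dates is None or e.patient_id not in (enrollment_dates or {}):
            enroll[e.patient_id] = min(enroll[e.patient_id], e.date)

    in_window: list[AssessmentEntry] = []
    for e in screened:
        start = enroll[e.patient_id]
        if start <= e.date < start + timedelta(days=followup_days):
            in_window.append(e)
        else:
            rejections.append(RejectedEntry(e, REASON_OUTSIDE_FOLLOWUP))

    # duplicate resolution: latest submitted_at wins, ties -> last in input
    best: dict[tuple, tuple[int, AssessmentEntry]] = {}
    superseded: list[AssessmentEntry] = []
    for pos, e in enumerate(in_window):
        key = (e.patient_id, e.date, e.instrument, e.item_code)
        if key not in best:
            best[key] = (pos, e)
            continue
        old_pos, old = best[key]
        old_ts = old.submitted_at or datetime.min
        new_ts = e.submitted_at or datetime.min
        if new_ts >= old_ts:
            superseded.append(old)
            best[key] = (pos, e)
        else:
            superseded.append(e)
    rejections.extend(RejectedEntry(e, REASON_SUPERSEDED) for e in superseded)

    by_patient: dict[str, list[AssessmentEntry]] = {}
    for _, e in sorted(best.values(), key=lambda pe: pe[0]):
        by_patient.setdefault(e.patient_id, []).append(e)

    records = [
        PatientRecord(
            patient_id=pid,
            enrollment_date=enroll[pid],
            followup_days=followup_days,
            entries=sorted(
                entries, key=lambda e: (e.date, str(e.instrument), e.item_code)
            ),
        )
        for pid, entries in sorted(by_patient.items())
    ]
    return records, rejections


def bpi_composites(
    entries: Sequence[AssessmentEntry],
) -> tuple[Optional[float], Optional[float]]:
    """Standard BPI severity and interference composites for one patient-day.

    Severity is the mean of the four severity items (worst, least,
    average, now) and is defined only when all four are answered.
    Interference is the mean of the answered interference items and is
    defined when at least four of the seven are answered.  Undefined
    composites are returned as ``None``.
    """
    scores = {
        e.item_code: int(e.score)
        for e in entries
        if Instrument(e.instrument) == Instrument.BPI
    }
    sev = [scores[i] for i in BPI_SEVERITY_ITEMS if i in scores]
    interf = [scores[i] for i in BPI_INTERFERENCE_ITEMS if i in scores]
    severity = sum(sev) / 4.0 if len(sev) == 4 else None
    interference = sum(interf) / len(interf) if len(interf) >= 4 else None
    return severity, interference


def distress_screen(dt_score: int) -> bool:
    """True iff a Distress Thermometer score screens as elevated (>= 4).

    This is a screening annotation only; alerting is governed solely by
    the trigger rules in :mod:`symwatch.alerts`.
    """
    return int(dt_score) >= DT_SCREEN_CUTOFF
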