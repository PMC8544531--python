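"""Clinician-facing monitoring snapshot.

The triage view a monitoring nurse works from: for a given date, which
patients have active alerts, each patient's per-item scores over the
trailing five calendar days (gaps shown, never imputed — a missing day is
itself clinically informative), the distress-screen flag, and the BPI
composites.  Patients flagged on the snapshot date sort to the top.

Snapshots render to plain text, CSV, or a minimal standalone HTML page;
all three carry identical data, and the CSV round-trips losslessly.
"""

from __future__ import annotations

import csv
import html as _html
import io as _io
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Iterable, Optional

from .alerts import Alert, AlertLog
from .scales import (
    Instrument,
    PatientRecord,
    bpi_composites,
    distress_screen,
)

__all__ = [
    "ItemWindow",
    "PatientRow",
    "DashboardSnapshot",
    "build_snapshot",
    "render_report",
    "parse_snapshot_csv",
]

WINDOW_DAYS = 5  # trailing calendar days shown per item, including as_of

CSV_COLUMNS = [
    "patient_id", "instrument", "item",
    "d-4", "d-3", "d-2", "d-1", "d-0",
    "active_rules", "routing", "distress_screen",
]


@dataclass(frozen=True)
class ItemWindow:
    """One item's trailing 5-day scores, oldest first; None marks a gap."""

    instrument: Instrument
    item_code: str
    scores: tuple[Optional[int], ...]


@dataclass
class PatientRow:
    patient_id: str
    active_alerts: list[Alert]
    items: list[ItemWindow]
    distress_elevated: Optional[bool]
    bpi_severity: Optional[float]
    bpi_interference: Optional[float]

    @property
    def is_flagged(self) -> bool:
        return len(self.active_alerts) > 0


@dataclass
class DashboardSnapshot:
    as_of: date
    rows: list[PatientRow] = field(default_factory=list)


def _window_dates(as_of: date) -> list[date]:
    return [as_of - timedelta(days=k) for k in range(WINDOW_DAYS - 1, -1, -1)]


def build_snapshot(
    records: Iterable[PatientRecord],
    alert_log: AlertLog,
    as_of: date,
) -> DashboardSnapshot:
    """Build the monitoring snapshot for one date.

    One row per enrolled patient (enrollment on or before ``as_of``);
    patients with at least one alert dated ``as_of`` sort first, then by
    patient id.  Each row carries the trailing 5-calendar-day window for
    every item the patient has ever reported, the distress screen (most
    recent DT score inside the window), and the day's BPI composites.
    """
    alerts_today: dict[str, list[Alert]] = {}
    for a in alert_log:
        if a.date == as_of:
            alerts_today.setdefault(a.patient_id, []).append(a)

    dates = _window_dates(as_of)
    rows: list[PatientRow] = []
    for record in sorted(records, key=lambda r: r.patient_id):
        if record.enrollment_date > as_of:
            continue
        series = record.item_series()
        items = [
            ItemWindow(
                instrument=inst,
                item_code=item,
                scores=tuple(
                    int(entries[d].score) if d in entries else None for d in dates
                ),
            )
            for (inst, item), entries in sorted(
                series.items(), key=lambda kv: (kv[0][0].value, kv[0][1])
            )
        ]
        dt_entries = series.get((Instrument.DT, "distress"), {})
        dt_recent = [d for d in dates if d in dt_entries]
        distress = (
            distress_screen(int(dt_entries[dt_recent[-1]].score))
            if dt_recent
            else None
        )
        severity, interference = bpi_composites(
            record.entries_on(as_of, Instrument.BPI)
        )
        rows.append(
            PatientRow(
                patient_id=record.patient_id,
                active_alerts=sorted(
                    alerts_today.get(record.patient_id, []),
                    key=lambda a: (a.instrument.value, a.item_code),
                ),
                items=items,
                distress_elevated=distress,
                bpi_severity=severity,
                bpi_interference=interference,
            )
        )
    rows.sort(key=lambda r: (not r.is_flagged, r.patient_id))
    return DashboardSnapshot(as_of=as_of, rows=rows)


def _alert_index(row: PatientRow) -> dict[tuple[Instrument, str], Alert]:
    return {(a.instrument, a.item_code): a for a in row.active_alerts}


def _csv_cells(snapshot: DashboardSnapshot) -> list[list[str]]:
    out: list[list[str]] = []
    for row in snapshot.rows:
        alerts = _alert_index(row)
        distress = "" if row.distress_elevated is None else str(row.distress_elevated)
        for item in row.items:
            alert = alerts.get((item.instrument, item.item_code))
            out.append(
                [
                    row.patient_id,
                    item.instrument.value,
                    item.item_code,
                    *["" if s is None else str(s) for s in item.scores],
                    "+".join(sorted(r.value for r in alert.fired_rules))
                    if alert
                    else "",
                    alert.routing.value if alert else "",
                    distress,
                ]
            )
    return out


def _render_csv(snapshot: DashboardSnapshot) -> str:
    buf = _io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(CSV_COLUMNS)
    writer.writerows(_csv_cells(snapshot))
    return buf.getvalue()


def _render_text(snapshot: DashboardSnapshot) -> str:
    lines = [f"Monitoring snapshot — {snapshot.as_of.isoformat()}"]
    lines.append(f"{len(snapshot.rows)} patient(s); "
                 f"{sum(r.is_flagged for r in snapshot.rows)} flagged")
    for row in snapshot.rows:
        flag = " [ALERT]" if row.is_flagged else ""
        lines.append("")
        lines.append(f"Patient {row.patient_id}{flag}")
        if row.distress_elevated is not None:
            lines.append(f"  distress screen elevated: {row.distress_elevated}")
        if row.bpi_severity is not None:
            lines.append(f"  BPI severity {row.bpi_severity:.2f}")
        if row.bpi_interference is not None:
            lines.append(f"  BPI interference {row.bpi_interference:.2f}")
        for a in row.active_alerts:
            rules = "+".join(sorted(r.value for r in a.fired_rules))
            lines.append(
                f"  ALERT {a.instrument.value}/{a.item_code}: {rules}"
                f" (scores {','.join(map(str, a.triggering_scores))})"
                f" -> {a.routing.value}"
            )
        for item in row.items:
            cells = " ".join("." if s is None else str(s) for s in item.scores)
            lines.append(f"  {item.instrument.value:6s} {item.item_code:22s} {cells}")
    return "\n".join(lines) + "\n"


_HTML_PAGE = """<!DOCTYPE html>
<html><head><meta charset="utf-8">
<title>Monitoring snapshot {as_of}</title>
<style>
body {{ font-family: sans-serif; }}
table {{ border-collapse: collapse; }}
td, th {{ border: 1px solid #999; padding: 2px 6px; }}
tr.flagged {{ background: #ffe0e0; }}
</style></head>
<body>
<h1>Monitoring snapshot — {as_of}</h1>
<table>
<tr>{header}</tr>
{body}
</table>
</body></html>
"""


def _render_html(snapshot: DashboardSnapshot) -> str:
    flagged = {r.patient_id for r in snapshot.rows if r.is_flagged}
    header = "".join(f"<th>{_html.escape(c)}</th>" for c in CSV_COLUMNS)
    body_rows = []
    for cells in _csv_cells(snapshot):
        cls = ' class="flagged"' if cells[0] in flagged and cells[8] else ""
        tds = "".join(f"<td>{_html.escape(c)}</td>" for c in cells)
        body_rows.append(f"<tr{cls}>{tds}</tr>")
    return _HTML_PAGE.format(
        as_of=snapshot.as_of.isoformat(), header=header, body="\n".join(body_rows)
    )


def render_report(snapshot: DashboardSnapshot, format: str = "text") -> str:
    """Render a snapshot to ``text``, ``csv``, or ``html``.

    Rendering is pure: the same snapshot always yields identical bytes.
    """
    renderers = {"text": _render_text, "csv": _render_csv, "html": _render_html}
    try:
        return renderers[format](snapshot)
    except KeyError:
        raise ValueError(
            f"unknown format {format!r}; expected one of {sorted(renderers)}"
        ) from None


def parse_snapshot_csv(text: str) -> list[dict[str, str]]:
    """Read a rendered snapshot CSV back into row dicts (round-trip aid)."""
    reader = csv.DictReader(_io.StringIO(text))
    if reader.fieldnames != CSV_COLUMNS:
        raise ValueError(f"unexpected snapshot header: {reader.fieldnames}")
    return list(reader)
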