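"""File formats, run configuration, and output writing.

Assessment interchange is a long-format table, one row per
patient-day-instrument-item score, as CSV (header exactly
``patient_id,date,submitted_at,instrument,item,score``) or an equivalent
JSON array of objects.  Dates are strict ISO-8601 — no locale inference,
since silently misparsed dates are the classic longitudinal-data failure.
Malformed rows are collected into a parse report with line numbers, never
silently skipped; typed-but-invalid values (out-of-range scores, unknown
items) pass through parsing and are handled by scale validation.

Run configuration is a single YAML or TOML file with sections mirroring
the typed configs (``alert``, ``sim``, ``cost``, ``paths``), so a run is
reproducible from one artifact.
"""

from __future__ import annotations

import csv
import datetime as _dt
import json
import tomllib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import yaml
from pydantic import BaseModel, Field

from .alerts import AlertLog, AlertRuleConfig
from .analytics import (
    AdherenceResult,
    CostModel,
    InterventionRecord,
    InterventionResponse,
    InterventionSummary,
)
from .dashboard import DashboardSnapshot, render_report
from .scales import AssessmentEntry, RejectedEntry
from .simulate import CohortTruth, SimParams

__all__ = [
    "ParseIssue",
    "RunConfig",
    "ASSESSMENT_COLUMNS",
    "read_assessments",
    "write_assessments",
    "write_rejections",
    "read_interventions",
    "load_config",
    "write_outputs",
    "write_truth",
]

ASSESSMENT_COLUMNS = ["patient_id", "date", "submitted_at", "instrument", "item", "score"]
INTERVENTION_COLUMNS = ["alert_id", "response", "date"]


@dataclass(frozen=True)
class ParseIssue:
    """One malformed input row: where it was and why it failed."""

    line: int
    message: str
    raw: str


class FormatError(ValueError):
    """Input file does not match the expected schema."""


def _parse_row(
    row: dict, line: int
) -> tuple[Optional[AssessmentEntry], Optional[ParseIssue]]:
    raw = ",".join("" if row.get(c) is None else str(row.get(c)) for c in ASSESSMENT_COLUMNS)
    try:
        day = _dt.date.fromisoformat(str(row["date"]))
    except (ValueError, TypeError):
        return None, ParseIssue(line, f"invalid date {row.get('date')!r}", raw)
    submitted_raw = row.get("submitted_at")
    submitted: Optional[_dt.datetime] = None
    if submitted_raw not in (None, ""):
        try:
            submitted = _dt.datetime.fromisoformat(str(submitted_raw))
        except ValueError:
            return None, ParseIssue(
                line, f"invalid submitted_at {submitted_raw!r}", raw
            )
    score_raw = row.get("score")
    score: object
    if isinstance(score_raw, (int, float)) and not isinstance(score_raw, bool):
        score = score_raw
    else:
        text = str(score_raw if score_raw is not None else "").strip()
        try:
            score = int(text)
        except ValueError:
            try:
                # fractional values parse here and are rejected downstream
                score = float(text)
            except ValueError:
                return None, ParseIssue(line, f"non-numeric score {score_raw!r}", raw)
    return (
        AssessmentEntry(
            patient_id=str(row["patient_id"]),
            date=day,
            instrument=str(row["instrument"]),
            item_code=str(row["item"]),
            score=score,
            submitted_at=submitted,
        ),
        None,
    )


def read_assessments(
    path: Union[str, Path], format: Optional[str] = None
) -> tuple[list[AssessmentEntry], list[ParseIssue]]:
    """Read raw assessment entries from CSV or JSON.

    The format is inferred from the suffix when not given.  Returns the
    typed entries plus a parse report; a wrong CSV header raises
    :class:`FormatError` naming the missing columns.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    entries: list[AssessmentEntry] = []
    issues: list[ParseIssue] = []
    if fmt == "csv":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                raise FormatError(f"{path}: empty file, expected header "
                                  f"{','.join(ASSESSMENT_COLUMNS)}")
            missing = [c for c in ASSESSMENT_COLUMNS if c not in reader.fieldnames]
            if missing:
                raise FormatError(
                    f"{path}: missing column(s) {', '.join(missing)}"
                )
            for line, row in enumerate(reader, start=2):
                entry, issue = _parse_row(row, line)
                if issue:
                    issues.append(issue)
                else:
                    entries.append(entry)
    elif fmt == "json":
        with open(path) as fh:
            data = json.load(fh)
        if not isinstance(data, list):
            raise FormatError(f"{path}: expected a JSON array of objects")
        for i, row in enumerate(data, start=1):
            if not isinstance(row, dict) or not {"patient_id", "date", "instrument",
                                                 "item", "score"} <= row.keys():
                issues.append(ParseIssue(i, "missing required keys", json.dumps(row)))
                continue
            entry, issue = _parse_row(row, i)
            if issue:
                issues.append(issue)
            else:
                entries.append(entry)
    else:
        raise ValueError(f"unknown format {format!r}; expected csv or json")
    return entries, issues


def _entry_row(e: AssessmentEntry) -> dict:
    return {
        "patient_id": e.patient_id,
        "date": e.date.isoformat(),
        "submitted_at": e.submitted_at.isoformat() if e.submitted_at else "",
        "instrument": getattr(e.instrument, "value", str(e.instrument)),
        "item": e.item_code,
        "score": e.score,
    }


def write_assessments(
    entries: Iterable[AssessmentEntry],
    path: Union[str, Path],
    format: Optional[str] = None,
) -> int:
    """Write entries in the canonical long format; returns the row count."""
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    rows = [_entry_row(e) for e in entries]
    if fmt == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=ASSESSMENT_COLUMNS,
                                    lineterminator="\n")
            writer.writeheader()
            writer.writerows(rows)
    elif fmt == "json":
        with open(path, "w") as fh:
            json.dump(rows, fh, indent=1)
            fh.write("\n")
    else:
        raise ValueError(f"unknown format {format!r}; expected csv or json")
    return len(rows)


def write_rejections(
    rejections: Sequence[RejectedEntry], path: Union[str, Path]
) -> int:
    """Rejection report: the original row plus a machine-readable reason."""
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=ASSESSMENT_COLUMNS + ["reason"], lineterminator="\n"
        )
        writer.writeheader()
        for rej in rejections:
            writer.writerow({**_entry_row(rej.entry), "reason": rej.reason})
    return len(rejections)


def read_interventions(path: Union[str, Path]) -> list[InterventionRecord]:
    """Read an intervention log (``alert_id,response,date`` CSV).

    An empty ``alert_id`` marks an unprompted contact.
    """
    records: list[InterventionRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in INTERVENTION_COLUMNS
                   if not reader.fieldnames or c not in reader.fieldnames]
        if missing:
            raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
        for line, row in enumerate(reader, start=2):
            try:
                response = InterventionResponse(row["response"])
            except ValueError:
                raise FormatError(
                    f"{path}:{line}: unknown response {row['response']!r}"
                ) from None
            records.append(
                InterventionRecord(
                    alert_id=row["alert_id"] or None,
                    response=response,
                    date=_dt.date.fromisoformat(row["date"]),
                )
            )
    return records


class PathsConfig(BaseModel):
    assessments: Optional[Path] = None
    interventions: Optional[Path] = None
    out_dir: Path = Path("symwatch_out")


class RunConfig(BaseModel):
    """One-file run configuration mirroring the typed configs."""

    alert: AlertRuleConfig = Field(default_factory=AlertRuleConfig)
    sim: SimParams = Field(default_factory=SimParams)
    cost: CostModel = Field(default_factory=CostModel)
    paths: PathsConfig = Field(default_factory=PathsConfig)
    log_level: str = "INFO"


def load_config(path: Union[str, Path, None]) -> RunConfig:
    """Load a YAML (.yml/.yaml) or TOML (.toml) run configuration."""
    if path is None:
        return RunConfig()
    path = Path(path)
    if path.suffix.lower() == ".toml":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    else:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)


def _summary_payload(
    adherence: Optional[AdherenceResult],
    interventions: Optional[InterventionSummary],
    cost: Optional[object],
    n_alerts: int,
) -> dict:
    payload: dict = {"n_alerts": n_alerts}
    if adherence is not None:
        payload["adherence"] = {
            "observed_days": adherence.observed_days,
            "expected_days": adherence.expected_days,
            "rate": adherence.rate,
        }
    if interventions is not None:
        payload["interventions"] = {
            "n_alerts": interventions.n_alerts,
            "n_with_intervention": interventions.n_with_intervention,
            "n_without_intervention": interventions.n_without_intervention,
            "pct_requiring_intervention": interventions.pct_requiring_intervention,
            "linked_counts": {
                k.value: v for k, v in sorted(interventions.linked_counts.items())
            },
            "unprompted_counts": {
                k.value: v for k, v in sorted(interventions.unprompted_counts.items())
            },
        }
    if cost is not None:
        payload["cost_avoidance"] = float(cost)
    return payload


def write_outputs(
    out_dir: Union[str, Path],
    *,
    alert_log: AlertLog,
    snapshot: DashboardSnapshot,
    adherence: Optional[AdherenceResult] = None,
    interventions: Optional[InterventionSummary] = None,
    cost: Optional[object] = None,
) -> dict:
    """Write the full output set to ``out_dir`` and return the manifest.

    Filenames are fixed; re-running with identical inputs overwrites the
    directory with byte-identical content.  The manifest lists every
    file with its data row count and flags whether an intervention log
    was supplied.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    files: dict[str, int] = {}

    frame = alert_log.to_frame()
    frame.to_csv(out / "alerts.csv", index=False, lineterminator="\n")
    files["alerts.csv"] = len(frame)
    with open(out / "alerts.json", "w") as fh:
        json.dump(frame.to_dict(orient="records"), fh, indent=1)
        fh.write("\n")
    files["alerts.json"] = len(frame)

    summary = _summary_payload(adherence, interventions, cost, len(alert_log))
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    files["summary.json"] = 1

    flat_rows = _flatten("", summary)
    with open(out / "summary.csv", "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["metric", "value"])
        writer.writerows(flat_rows)
    files["summary.csv"] = len(flat_rows)

    for fmt, name in (("csv", "snapshot.csv"), ("text", "snapshot.txt"),
                      ("html", "snapshot.html")):
        text = render_report(snapshot, fmt)
        (out / name).write_text(text)
        files[name] = sum(len(r.items) for r in snapshot.rows)

    manifest = {
        "files": files,
        "interventions": "provided" if interventions is not None else "none",
        "n_patients": len(snapshot.rows),
        "n_alerts": len(alert_log),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


def _flatten(prefix: str, obj: object) -> list[list]:
    if isinstance(obj, dict):
        rows: list[list] = []
        for k, v in obj.items():
            key = f"{prefix}.{k}" if prefix else str(k)
            rows.extend(_flatten(key, v))
        return rows
    return [[prefix, "" if obj is None else obj]]


def write_truth(truth: CohortTruth, path: Union[str, Path]) -> None:
    """Serialise simulation ground truth (events + completion flags) to JSON."""
    payload = {
        "params": json.loads(truth.params.model_dump_json()),
        "patients": {
            pid: {
                "events": [
                    {
                        "instrument": ev.instrument.value,
                        "item": ev.item_code,
                        "onset": ev.onset.isoformat(),
                        "duration_days": ev.duration_days,
                        "jump": ev.jump,
                    }
                    for ev in pt.events
                ],
                "completed": {
                    d.isoformat(): flag for d, flag in sorted(pt.completed.items())
                },
            }
            for pid, pt in sorted(truth.patients.items())
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
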