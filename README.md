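# symwatch

Remote symptom self-report monitoring for community palliative care —
the engine behind a daily check-in programme in which patients rate
their symptoms on three validated 0–10 scales and a rule engine flags
worsening or severe symptoms for clinical review.

## Who this is for

Teams building or studying patient-reported-outcome (PRO) monitoring:
the package provides the complete, tested computational core — scale
definitions and score validation, the alert algorithm, routing by
monitoring hours, programme analytics, and a reproducible cohort
simulator — without any clinical service stack.

## The model

**Instruments.** Each day a patient completes three instruments, every
item scored as an integer $s \in \{0,\dots,10\}$:

* **ESAS-r** — nine symptoms (pain, tiredness, drowsiness, nausea, lack
  of appetite, shortness of breath, depression, anxiety, wellbeing) plus
  an optional patient-named "other" symptom;
* **DT** — a single distress item; $s \ge 4$ screens as elevated
  distress (an annotation, not an alert);
* **BPI** (short form) — four pain-severity and seven interference
  items, with standard composites: severity $= \bar{s}_{\text{sev}}$
  over all 4 items, interference $= \bar{s}_{\text{int}}$ over answered
  items when at least 4 of 7 are answered.

**Alert rules.** For each patient, item and day $t$ with observed score
$s_t$, an alert fires when any of:

1. `CONSECUTIVE_RISE`: $s_t - s_{t-1} \ge 2$ **and** $s_{t-1} - s_{t-2} \ge 2$
   (a 2-point rise on each of 2 consecutive days);
2. `SUDDEN_RISE`: $s_t - s_{t-1} \ge 3$;
3. `SEVERE`: $s_t \ge 8$.

Missing days disable the rules that would need them — no imputation.
Alerts in the weekday monitoring window (Mon–Fri, 08:00–17:00,
half-open) route to the nursing team; all others to the physician
after-hours path.

**Analytics.** Adherence = observed patient-days / expected
patient-days. The intervention rate is the percentage of alerts whose
logged clinical response was an actual intervention. Cost avoidance =
cost/day × mean length of stay × avoided admissions.

## Worked example

```bash
python examples/03_adherence_interventions_cost.py
```

prints (deterministic, fixed seed):

```
adherence:                80.0%
alerts:                   335
requiring intervention:   112 (33.4%)
cost avoidance (CAD):     62,092.50
```

A 5-patient, 30-day simulated cohort completed 80.0% of its expected
daily check-ins; the three-rule scan raised 335 item-level alerts, of
which 112 (33.4%) had a logged clinical intervention; and avoiding five
admissions at CAD 850.00/day for a 14.61-day average stay saves
CAD 62,092.50. The other examples cover simulation
(`01_simulate_cohort.py`), the rule engine on a hand-built record
(`02_alert_scan.py`), and the clinician triage snapshot
(`04_dashboard_snapshot.py`).

The same pipeline is available as a thin CLI:

```bash
symwatch simulate --out out/            # cohort.csv + truth.json
symwatch alerts   --input out/cohort.csv --out out/
symwatch report   --input out/cohort.csv --out out/report/
symwatch cost --cost-per-day 850 --length-of-stay 14.61 --avoided-admissions 5
```

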