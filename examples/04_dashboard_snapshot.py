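"""Build the clinician-facing snapshot for one monitoring day.

Simulates a small cohort, scans it for alerts, picks the busiest alert
day, and renders the triage view: flagged patients first, each item's
trailing five days of scores with gaps shown as dots.
"""

from collections import Counter

from symwatch import (
    SimParams,
    build_snapshot,
    render_report,
    scan_cohort,
    simulate_cohort,
)

records, _ = simulate_cohort(SimParams(n_patients=3, followup_days=21, seed=12))
log = scan_cohort(records)

busiest_day, n = Counter(a.date for a in log).most_common(1)[0]
snapshot = build_snapshot(records, log, busiest_day)

print(f"snapshot for {busiest_day} ({n} alerts that day)")
print()
text = render_report(snapshot, "text")
print("\n".join(text.splitlines()[:28]))
print("...")
# Flagged patients sort to the top; each ALERT line shows the fired
# rules, the 1-3 daily scores that satisfied them, and the routing.
# The per-item rows show the trailing 5 calendar days (dot = no
# submission that day — gaps are shown, never imputed).
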