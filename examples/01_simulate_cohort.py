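"""Simulate a monitoring cohort and inspect what was generated.

Generates 13 patients followed for 60 days with 80% daily completion,
then prints cohort-level counts: entries, planted exacerbation events,
and the realised completion rate (which should sit near 0.80).
"""

from symwatch import SimParams, adherence_rate, simulate_cohort

params = SimParams(seed=42)
records, truth = simulate_cohort(params)

n_entries = sum(len(r.entries) for r in records)
result = adherence_rate(records)

print(f"patients:            {len(records)}")
print(f"assessment entries:  {n_entries}")
print(f"planted flares:      {truth.n_events}")
print(f"observed days:       {result.observed_days} / {result.expected_days}")
print(f"completion rate:     {result.rate:.3f}")
# The completion rate is the fraction of expected patient-days with at
# least one submitted assessment; flares are the multi-day symptom jumps
# the alert rules are meant to catch.
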