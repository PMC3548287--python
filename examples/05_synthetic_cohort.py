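"""Generate the full synthetic study cohort and summarise its exposures.

Draws the default 8-subject × 7-day cohort (4 men at 70 kg, 4 women at
60 kg, ~7.6 voids per person-day, 0–4 lognormal dose events per day with a
nighttime share, 20% multiplicative measurement noise, LOD censoring) and
prints the design counts plus ground-truth intake summaries.
"""

import numpy as np

from dehprecon.dose_recon import cohort_stats, daily_summary, is_night, person_day_intakes
from dehprecon.synthetic_cohort import CohortConfig, generate

cohort = generate(CohortConfig(seed=0))
n_voids = sum(len(v) for v in cohort.voids.values())
n_events = sum(len(e) for e in cohort.true_events.values())
print(f"subjects: {len(cohort.subjects)}  person-days: {len(cohort.subjects) * 7}")
print(f"voids: {n_voids} (study design: 427)  true events: {n_events}")

rows = []
for s in cohort.subjects:
    daily = person_day_intakes(cohort.true_events[s.id], 7)
    rows.append((s.id, s.sex, daily.mean(), daily.max()))
print("\nsubject  sex  mean daily intake  max day  (µg/kg-day)")
for sid, sex, mean, mx in rows:
    print(f"{sid:>7s}  {sex:>3s}  {mean:17.1f}  {mx:7.1f}")

all_events = [e for evs in cohort.true_events.values() for e in evs]
night = [e for e in all_events if is_night(e.time)]
total = sum(e.dose for e in all_events)
print(f"\nnighttime (2200-0500) events: {len(night)}/{len(all_events)}, "
      f"{100 * sum(e.dose for e in night) / total:.0f}% of total intake")
print("\nThe generator reproduces the study's design counts so that every")
print("stage of the analysis is testable without any external data.")
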