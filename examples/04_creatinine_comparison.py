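"""Creatinine-corrected spot-sample intakes vs reconstructed daily doses.

Simulates a subject with one sizeable exposure event per day, back-
calculates a daily intake from every single void by creatinine correction,
and compares the spread of those single-sample estimates with the true
daily intake.
"""

import numpy as np

from dehprecon import default_specs
from dehprecon.dose_recon import person_day_intakes
from dehprecon.intake_compare import SpotSample, compare_daily, spot_intake, synthetic_creatinine
from dehprecon.synthetic_cohort import single_subject

specs = default_specs()
subject, voids, _, truth = single_subject(
    seed=1, events_per_day=1, dose_median=15, dose_sigma=0.5,
    dose_min=5, dose_max=40, noise_cv=0.0,
)

estimates, prev = [], 0.0
for v in voids:
    creat = synthetic_creatinine(max(v.time - prev, 1.0), v.volume, subject)
    prev = v.time
    conc = np.where(np.isfinite(v.conc), v.conc, 0.0)
    estimates.append(spot_intake(SpotSample(v.time, conc, creat), subject, specs))

true_daily = person_day_intakes(truth, 7)
table = compare_daily(estimates, true_daily)
print(table.round(2).to_string(index=False))

all_mean = np.mean([e.sum_of_four for e in estimates])
print(f"\nmean of all spot estimates : {all_mean:.1f} µg/kg-day")
print(f"true mean daily intake     : {true_daily.mean():.1f} µg/kg-day")
print("\nSingle-void estimates swing several-fold within a day (spot_maxmin_ratio)")
print("because a spot sample reflects where in the excretion curve it was taken,")
print("while averaging over all voids of the week lands close to the truth.")
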