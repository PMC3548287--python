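"""Forward simulation: predict urinary metabolite concentrations at voids.

A 70-kg subject takes a single 10 µg/kg DEHP bolus at 08:00 and voids every
three hours.  The script prints the predicted concentration of each of the
four urinary metabolites at every void, then the two calibration-defining
quantities: the terminal MEHP half-life and the 72-h cumulative molar
fraction.
"""

import math

import numpy as np

from dehprecon import (
    DoseEvent,
    Subject,
    cumulative_molar_fraction,
    default_specs,
    simulate,
)
from dehprecon.constants import METABOLITES

subject = Subject(id="demo", sex="M")  # 70 kg by study convention
specs = default_specs()
dose = DoseEvent(time=8 * 60.0, dose=10.0)  # 10 µg/kg at 0800
voids = [(8 * 60.0 + 180.0 * k, 0.25) for k in range(1, 12)]  # 0.25 L every 3 h

pred = simulate(subject, [dose], voids, specs)
print("clock_hr  " + "  ".join(f"{m:>7s}" for m in METABOLITES) + "   (µg/L)")
for p in pred:
    row = "  ".join(f"{c:7.1f}" for c in p.conc)
    print(f"{p.time / 60.0:7.2f}   {row}")

# log-linear fit of hourly MEHP excretion gives the elimination half-life
hourly = simulate(subject, [DoseEvent(time=0.0, dose=10.0)],
                  [(60.0 * h, 0.1) for h in range(1, 49)], specs)
t = np.array([p.time / 60.0 for p in hourly])
m = np.array([p.mass[0] for p in hourly])
sel = (t >= 6) & (t <= 24)
slope = np.polyfit(t[sel], np.log(m[sel]), 1)[0]
print(f"\nterminal MEHP half-life: {math.log(2.0) / -slope:.3f} hr (calibrated: 5 hr)")

frac = cumulative_molar_fraction(subject, DoseEvent(time=0.0, dose=10.0), specs[0], 72.0)
print(f"72-h cumulative MEHP molar fraction: {100 * frac:.2f}% (calibrated: 5.9%)")
print("\nConcentrations spike at the first post-dose void and decay with each")
print("metabolite's elimination rate; all of the dose-destined metabolite mass")
print("eventually appears in urine, whatever the void schedule.")
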