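"""Sensitivity analyses: dose spreading and bolus time shifts.

Takes a single calibrated 10 µg/kg bolus at 1000 h and asks how much the
predicted void concentrations change if the same mass had instead arrived
spread over 2, 8 or 24 hours, or as a bolus shifted ±2 h.
"""

from dehprecon import DoseEvent, Subject, default_specs, simulate
from dehprecon.sensitivity import series_difference, shift_doses, spread_doses

subject = Subject(id="demo", sex="M")
specs = default_specs()
events = [DoseEvent(time=600.0, dose=10.0)]  # 1000 h
voids = [
    (420, 0.3), (540, 0.25), (720, 0.3), (840, 0.25), (1020, 0.3),
    (1200, 0.3), (1380, 0.3), (1620, 0.4), (1860, 0.3), (2160, 0.4),
]
base = simulate(subject, events, voids, specs)

print("perturbation        max rel diff   mean rel diff")
for h in (2, 8, 24):
    pert = simulate(subject, spread_doses(events, h), voids, specs)
    d = series_difference(base, pert)["overall"]
    print(f"spread over {h:2d} h    {d['max_rel']:12.4f}   {d['mean_rel']:13.4f}")
for off in (-120.0, 120.0):
    pert = simulate(subject, shift_doses(events, off), voids, specs)
    d = series_difference(base, pert)["overall"]
    print(f"shift {off:+5.0f} min     {d['max_rel']:12.4f}   {d['mean_rel']:13.4f}")

print("\nA 2-h spread is virtually indistinguishable from the bolus (no void")
print("falls inside the spread window, so almost the same mass reaches the")
print("bladder before each void); 8-h and 24-h spreads overlap voids and")
print("change the series markedly, as does moving the bolus by two hours.")
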