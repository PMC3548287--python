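"""Dose reconstruction: recover exposure events from void concentrations.

Builds a noise-free synthetic subject with two well-separated exposure
events per day for a week, runs the automated reconstruction, and compares
every recovered event with the ground truth.  On noise-free data recovery
is exact to the 15-min search grid.
"""

from dehprecon import FitConfig, reconstruct_subject
from dehprecon.constants import METABOLITES
from dehprecon.synthetic_cohort import single_subject

subject, voids, diary, truth = single_subject(seed=2, noise_cv=0.0)
config = FitConfig(lod={m: 0.0 for m in METABOLITES})
result = reconstruct_subject(voids, diary, subject, config=config)

print(f"true events: {len(truth)}   recovered: {len(result.events)}\n")
print("   true time (hr)  true dose   fitted time  fitted dose")
for e in truth:
    best = min(result.events, key=lambda f: abs(f.time - e.time))
    print(f"   {e.time / 60.0:13.2f}  {e.dose:9.2f}   {best.time / 60.0:11.2f}  {best.dose:11.2f}")

weekly_true = sum(e.dose for e in truth)
weekly_fit = sum(e.dose for e in result.events)
print(f"\nweekly intake: true {weekly_true:.1f}, reconstructed {weekly_fit:.1f} µg/kg")
print("observed-vs-predicted correlation per metabolite:")
for m, r in result.correlations.items():
    print(f"   {m}: r = {r:.4f}")
print("\nEach fitted event should sit on the true time to within one 15-min")
print("grid step with magnitude within a few percent; correlations near 1")
print("mean the re-simulated series reproduces the observations.")
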