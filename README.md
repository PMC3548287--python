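# dehprecon

Reconstruction of di(2-ethylhexyl) phthalate (DEHP) exposure doses from
urinary biomarker time series.

DEHP, a ubiquitous plasticizer, hydrolyses in the body to MEHP and is
further oxidised to MEHHP, MEOHP and MECPP; all four metabolites are
excreted in urine within a day or two. When a study records the **time,
full volume and metabolite concentrations of every void** over a week,
the exposure history that produced those concentrations can be
reconstructed: each concentration spike implies a recent intake whose time
and magnitude can be fitted with a pharmacokinetic model. `dehprecon` is a
library (plus a thin CLI) for exposure scientists and biostatisticians who
want to run, test or extend that kind of dose-reconstruction analysis —
including the inverse fitting the original analyses did by trial and
error, here fully automated.

## Model

Per metabolite *m*, an oral bolus of *D* µg DEHP per kg body weight routes
a fixed molar fraction into urine through a first-order chain:

```
input mass   M_m = f_m · (D · BW / MW_DEHP) · MW_m        [µg of metabolite]
appearance   dA/dt = −k_a A            (absorption/formation, k_a ≈ 1.2 h⁻¹)
body pool    dP/dt =  k_a A − k_m P    (urinary elimination k_m = ln2 / t½)
bladder      dB/dt =  k_m P,   void at t_i: concentration = B(t_i)/V_i, B → 0
```

There is no loss pathway, so mass is conserved exactly: everything dosed
eventually appears in urine. Updates use the exact exponential (Bateman)
solution on a 15-min grid, so the discrete simulation matches the closed
form to floating-point accuracy. The calibration fixes f_MEHP = 0.059 and
t½(MEHP) = 5 h; the secondary metabolites (MEHHP/MEOHP/MECPP) use
reference constants f = 0.233/0.150/0.185 and t½ = 10/10/12 h, all
config-overridable.

The inverse problem — *detect* concentration rises between consecutive
voids, *fit* one bolus (time × magnitude) per window by minimising a
weighted squared error on log1p concentrations (MEHP down-weighted), then
*prune* events below 1 µg/kg — is solved by a deterministic pipeline of
sequential window fits, residual-detection passes, coordinate and pairwise
refinement, and a nonnegative-least-squares global re-initialisation that
exploits the model's linearity in dose.

Also included: the sensitivity analyses (doses spread over 2/8/24 h,
boluses shifted ±2 h), the creatinine-correction back-calculation of daily
intake from spot samples, and a synthetic 8-subject × 7-day cohort
generator that reproduces the study design (≈427 voids over 56
person-days, 0–4 dose events/day of 1–60 µg/kg including nighttime events,
lognormal noise, LOD censoring) so everything is testable without any
external data.

## Worked example

`python examples/02_dose_reconstruction.py` builds a noise-free synthetic
subject with two well-separated exposure events per day for a week and
reconstructs them:

```
true events: 14   recovered: 14

   true time (hr)  true dose   fitted time  fitted dose
           11.50      16.78         11.50        16.78
           20.25       3.00         20.25         3.00
           36.50      19.67         36.50        19.67
           ...
          162.50       3.00        162.50         3.00

weekly intake: true 138.1, reconstructed 138.1 µg/kg
observed-vs-predicted correlation per metabolite:
   MEHP: r = 1.0000
   MEHHP: r = 1.0000
   MEOHP: r = 1.0000
   MECPP: r = 1.0000
```

Every event lands on the true 15-min grid time with the true magnitude:
on noise-free data the weighted loss has its unique zero at the generating
event set, and the optimiser finds it. With 20% multiplicative measurement
noise the same pipeline still matches ≳80% of events to within ±2 h and
recovers weekly intake to within a few percent (see
`tests/test_acceptance.py`).

The other examples cover forward simulation (`01`), the spread/shift
sensitivity analyses (`03`), creatinine spot-sample comparison (`04`) and
the full synthetic cohort (`05`). The same capabilities are exposed as a
CLI: `dehprecon synth|simulate|reconstruct|creatinine|sensitivity --help`.

## Layout

```
src/dehprecon/
  constants.py        molecular weights of DEHP and its four metabolites
  pk_forward.py       exact-update compartmental forward simulator
  dose_recon.py       window detection, event fitting, pruning, summaries
  sensitivity.py      dose spreading / time shifting / series differences
  intake_compare.py   creatinine-corrected spot-sample intake estimation
  synthetic_cohort.py study-design cohort generator
  io.py, cli.py       delimited-text formats, YAML config, umbrella CLI
```

See `docs/methods.md` for the modelling assumptions, parameter defaults
and their provenance, numerical choices, and known limitations.
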