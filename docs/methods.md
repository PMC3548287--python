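# Methods

## The forward model

Each of the four urinary DEHP metabolites (MEHP, MEHHP, MEOHP, MECPP) is
modelled independently as a linear first-order chain. A bolus of `D` µg
DEHP per kg body weight contributes, on a molar basis, a fraction `f_m` of
the dose to metabolite `m`'s urinary output; expressed as metabolite mass
the chain input is `f_m · (D·BW/MW_DEHP) · MW_m` µg. That mass enters an
appearance pool (absorption plus metabolic formation, lumped into one rate
`k_a`), flows into a body pool destined for urine, and drains into the
bladder at the metabolite's elimination rate `k_m`. A void empties the
bladder completely; the predicted concentration is bladder mass divided by
the recorded void volume. Void volume is always an input — urine
production is not modelled.

Two structural consequences are load-bearing for everything downstream:

* **Conservation.** There is no non-urinary loss, so total input mass
  equals excreted plus resident mass exactly, for any schedule.
* **Linearity.** Pool dynamics and bladder emptying are linear operators,
  so predicted concentrations are homogeneous of degree 1 in dose and
  additive over events. The inverse machinery leans on this: the response
  to a unit dose at a candidate time is computed once and scaled.

Between events (dose inputs, voids, delayed releases) the state is
advanced with the exact exponential (Bateman) solution, including the
degenerate `k_a = k_m` branch and the instantaneous-appearance limit
`k_a = ∞`. There is no integration error; the 15-min grid is a convention
for event placement, not a solver step.

### Parameters

| parameter | default | units | provenance |
|---|---|---|---|
| f_MEHP | 0.059 | – | calibration constant |
| t½ MEHP | 5 | h | calibration constant |
| f_MEHHP / f_MEOHP / f_MECPP | 0.233 / 0.150 / 0.185 | – | single-person self-dosing calibration literature; config-overridable |
| t½ MEHHP / MEOHP / MECPP | 10 / 10 / 12 | h | same |
| k_a | 1.2 | h⁻¹ | chosen so peak urinary excretion falls ~2 h post dose |
| g_m (second phase) | 0 (off) | – | qualitative observation only; when enabled, a delayed bolus of `g_m` times the first-phase mass at lag `tau_m` (default 24 h) |
| body weight | 70 (M) / 60 (F) | kg | study convention |
| grid step | 15 | min | spread-dose sub-interval |

Molecular weights are formula masses from standard atomic weights
(DEHP C24H38O4 = 390.564; MEHP C16H22O4 = 278.348; MEHHP C16H22O5 =
294.347; MEOHP C16H20O5 = 292.331; MECPP C16H20O6 = 308.330 g/mol), each
cross-checked in tests against independently hand-computed values.

The secondary-metabolite constants are *reference* values, not fitted
here; they live in the configuration layer (`io.default_config`), not in
the model equations, and a different calibration can be swapped in from a
YAML file without touching code.

## The inverse problem

Reconstruction asks: which sparse set of (time, magnitude) bolus events
best explains the observed void concentrations? The loss is a weighted sum
of squared differences of `log1p` concentrations over all voids and
metabolites, with weights MEHP 0.25 and 1.0 for the three oxidative
metabolites — a quantitative encoding of fitting the secondary metabolites
at the monoester's expense, motivated by MEHP's known over-prediction.
Below-LOD observations are imputed at LOD/√2; missing cells are excluded.

The pipeline, deterministic given data and configuration:

1. **Detection.** A candidate window opens between consecutive voids when
   at least 2 metabolites rise ≥2-fold and ≥10 µg/L (both config-exposed;
   the study's rise rule was illustrative, not numeric). Rises continuing
   directly from a triggering void are treated as ongoing absorption of
   the same episode. Optionally the first void can anchor a study-start
   window (`anchor_first_void`, default off so a monotone decaying series
   yields no windows).
2. **Sequential fitting.** Windows are fitted in time order: a grid search
   over event time (15-min resolution) crossed with bounded continuous
   optimisation of log-magnitude; earlier fitted events join the baseline.
   The loss is truncated at the next detected window so signal from later,
   unfitted exposures does not bias the current fit. Ties break toward the
   smaller dose, then the earlier time (parsimony).
3. **Residual passes.** Detection repeats on the residual (observed −
   predicted), with window opens walked back to the last residual-explained
   void. This finds doses that produce no raw rise because they ride on a
   larger neighbour's decay. With a zero prediction, pass 1 reduces
   exactly to the raw rule.
4. **Global refinement.** Alternating sweeps of (a) per-event refits over
   widened windows, with deletion when an event no longer reduces the
   loss; (b) joint pair refits of time-adjacent events (vectorised coarse
   dose grids over local joint time moves, then precise polish), which
   breaks the stalls coordinate descent hits when two nearby events
   compensate for each other; (c) greedy matching-pursuit additions
   scanning every grid time. A weighted nonnegative-least-squares solve on
   the *linear* concentration scale over all candidate times
   re-initialises the event set when it improves the fit: the decaying
   exponential unit responses form a Chebyshev-type system, so sparse
   nonnegative representations are essentially unique, and NNLS reliably
   lands on (near-)exact supports that window-by-window search can miss.
   All of this is the "joint refinement" stage; setting
   `refine_sweeps = 0` and `max_rescue_events = 0` restores the plain
   sequential window procedure.
5. **Pruning.** Events below 1 µg/kg (configurable) are removed and
   reported separately — small apparent exposures may be second-phase
   metabolism rather than new intake. Raising the threshold can only
   reduce event count and intake (tested property).

On noise-free synthetic data the loss has its unique zero at the
generating event set, and the pipeline recovers every well-separated event
(≥6 h apart, ≥3 µg/kg) exactly to the search grid and within optimiser
tolerance in magnitude. With 20% multiplicative noise, recovery degrades
gracefully (≈80–100% of events within ±2 h; weekly intake within ~10%).

### Summaries

Daily intakes attribute each event to the local calendar date of its
time. Exposure-range bins are 0, (0,5], (5,10], (10,20], >20 µg/kg-day.
Cohort statistics average per-subject daily means and per-subject daily
medians. The hourly profile assigns each event's dose to its clock hour
and divides by person-days, so the 24 entries sum to the cohort mean
daily intake. Nighttime is the half-open clock window [2200, 0500); diary
concordance uses a closed ±60 min window around food/beverage entries.

## Sensitivity analyses

`spread_doses` replaces each bolus with equal 15-min sub-boluses over 2 or
8 h centred on the event time (half the window before, half after); 24-h
spreading pools a calendar day's events and delivers them evenly over that
day's 96 grid steps. Daily dose is conserved exactly. Sub-boluses are
delivered at the *centres* of their 15-min slices: delivery at slice
starts would advance the mean delivery time by half a step, a first-order
bias (~8% per-void differences) that would swamp the genuine second-order
spread effect. With centred delivery, a 2-h spread with no void inside the
spread window changes per-void predictions by ≲1% (the void nearest the
window dominates); 8-h and 24-h spreads overlap voids and differ markedly,
so the mean relative difference increases strictly through 2 → 8 → 24 h.
The max relative difference saturates near 1 for the wider spreads (voids
where one series is near zero), which is why the ordering is stated on the
mean. `shift_doses` translates all events by a fixed offset (±120 min in
the standard analysis), clamping at the study bounds rather than wrapping.
`series_difference` floors denominators at 1 µg/L to avoid 0/0; it is
symmetric and zero iff the series are identical.

## Creatinine comparison

The spot-sample back-calculation is
`DI_m = (C_m/C_creat) · (CE/1000) · (MW_DEHP/MW_m) / f_m` µg/kg-day, with
the sum-of-four estimate formed from summed molar concentrations divided
by Σf_m. CE defaults to 23 (men) / 18 (women) mg creatinine per kg-day —
standard reference values, config-exposed. For closed-loop testing,
synthetic creatinine concentrations assume excretion at exactly CE over
each inter-void interval, which makes the time-weighted mean of spot
estimates converge to the true intake under steady dosing (tested).

A model finding worth recording: for exposures drawn *uniformly* over the
nighttime window [2200, 0500), daytime-only (0700–1900) spot sampling
shows **no** systematic underestimate of true intake under these kinetics
(50 seeds: −1.3% ± 7.4%, sign split 50/50) — early-morning doses' peak
excretion falls inside the daytime window. The underestimate appears
robustly (−12% ± 2.6%, 30/30 seeds) when nocturnal intake is
bedtime-dominated, e.g. the pattern of one ~20 µg/kg event near 2330 and a
~10 µg/kg event near 0245; the tests use that pattern via
`single_subject(night_clock_hr=..., night_doses=...)`.

## The synthetic cohort generator

`synthetic_cohort.generate` emulates the full-void study design: 8
subjects (4 M / 4 F) × 7 days; one wake-time void (~0645) plus
Poisson(6.9) daytime-weighted extras per day, snapped to the grid (≈427
voids per cohort, matching the design count within sampling error); void
volumes lognormal (median 0.25 L, CV 0.4, clipped to 0.03–1 L); 0–4 dose
events per day with probabilities (0.07, 0.35, 0.43, 0.11, 0.04) chosen to
match the reported pattern of mostly 0–2 events with occasional 3–4;
magnitudes lognormal (median 4 µg/kg, σ_log = 1) clipped to 0.5–60 µg/kg;
30% of events at night with magnitudes scaled ×0.65 so night carries
~20% of intake; two-thirds of daytime events anchored within ±60 min of a
generated diary food/beverage entry; concentrations simulated through the
forward model, then multiplied by median-preserving lognormal noise
(CV 0.2) and censored below per-metabolite LODs (0.5 µg/L).

`single_subject` is the controlled variant for recovery and comparison
studies: a fixed number of well-separated events per day, a wake *and* a
bedtime void so every exposure is followed by at least one observed void
(an event after the subject's final void is unobservable in principle),
and optional fixed nocturnal patterns.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: between-person kinetic variability (one
parameter set for all subjects, as in the original application),
within-person circadian variation in creatinine excretion, correlated or
non-lognormal assay error, diary misreporting, and exposure routes with
genuinely continuous uptake (e.g. inhalation). Recovery results on
synthetic data are a consistency check of the inverse machinery, not a
validation of the kinetic model against human data.

## Numerical choices and degenerate inputs

* Event and void times snap down to the 15-min grid; two voids on one grid
  node leave the second with zero concentration (tested idempotence).
* Dose magnitudes are searched in [0.05, 150] µg/kg on a log scale
  (bounded Brent, `xatol = 1e-8`); fits indistinguishable from the lower
  bound snap to it and are subsequently pruned.
* Loss ties (≤1e-10 relative) break toward smaller dose, then earlier
  time.
* Reconstruction contains no random draws; rerunning on identical inputs
  reproduces identical events bit for bit.
* Validation is eager and collective: malformed rows are reported together
  with line numbers; unknown configuration keys are rejected by name.

## Problem sizes

The test suite and acceptance checks run on a single subject-week
(~60 voids, 14 events) for recovery, a 100-schedule closed-form oracle
sweep, 500 conservation/linearity property instances, and one default
cohort draw — sizes chosen so the full suite completes in well under a
minute of compute per heavy test while still exercising every code path.

## Known limitations

* The two-compartment chain is empirical; it reproduces the printed
  calibration facts (5-h MEHP half-life, 5.9% molar fraction) but is not a
  physiological (PBPK) description, and refitting the kinetic constants to
  experimental datasets is out of scope (a config hook exists).
* Second-phase metabolism is a single delayed-bolus approximation of a
  qualitatively described phenomenon, off by default.
* Reconstructed doses carry no formal uncertainty quantification; the
  sensitivity analyses bound specific perturbations only.
* Identifiability degrades for events in long void-free gaps (e.g.
  overnight): time and magnitude trade off within the gap, and only the
  joint optimisation stages resolve the near-degeneracy on clean data.
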