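"""Forward pharmacokinetic simulation of urinary DEHP-metabolite excretion.

The model is a simple empirical two-compartment chain per metabolite: an
oral bolus of the parent compound (DEHP, in µg per kg body weight) places a
fixed molar fraction ``f_m`` of the dose, expressed as metabolite mass, into
an appearance pool that feeds a body pool at first-order rate ``k_a``; the
body pool drains into the bladder at the metabolite's first-order urinary
elimination rate ``k_m``.  A void empties the bladder completely and the
predicted concentration is bladder mass divided by void volume.  There is no
loss pathway: all input mass eventually reaches urine, so totals are exactly
conserved whatever the void schedule.

Updates between events use the exact exponential (Bateman) solution, not a
numerical integrator, so the discrete simulation agrees with the closed-form
single-exponential bladder accumulation to floating-point accuracy.

Times are minutes from local midnight of study day 1; masses are µg of each
analyte; concentrations µg/L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import METABOLITES, MW_DEHP, MW_METABOLITE

__all__ = [
    "MetaboliteSpec",
    "Subject",
    "DoseEvent",
    "VoidRecord",
    "PredictedVoid",
    "SimulationState",
    "SimConfig",
    "default_specs",
    "dose_input_mass",
    "expand_spread",
    "step",
    "simulate",
    "cumulative_molar_fraction",
]


@dataclass(frozen=True)
class MetaboliteSpec:
    """Kinetic and stoichiometric constants for one urinary metabolite.

    Parameters
    ----------
    name:
        One of MEHP, MEHHP, MEOHP, MECPP.
    f_m:
        Molar excretion fraction: fraction of a DEHP dose, on a molar
        basis, ultimately excreted in urine as this metabolite.
    k_m:
        First-order urinary elimination rate, per hour.
    mw:
        Molecular weight, g/mol.
    k_a:
        First-order appearance (absorption/formation) rate, per hour;
        ``math.inf`` means instantaneous appearance.
    g_m:
        Second-phase fraction: an optional delayed re-release of
        ``g_m`` times the first-phase mass, modelling the small resurgence
        of excretion ~1 day after dosing.  Default 0 (off).
    tau_m:
        Second-phase lag in hours.
    """

    name: str
    f_m: float
    k_m: float
    mw: float
    k_a: float = math.inf
    g_m: float = 0.0
    tau_m: float = 24.0

    def __post_init__(self) -> None:
        if not 0.0 < self.f_m < 1.0:
            raise ValueError(f"{self.name}: f_m must be in (0, 1), got {self.f_m}")
        if self.k_m <= 0.0:
            raise ValueError(f"{self.name}: k_m must be positive")
        if self.mw <= 0.0:
            raise ValueError(f"{self.name}: molecular weight must be positive")
        if math.isfinite(self.k_a) and self.k_a <= self.k_m:
            raise ValueError(
                f"{self.name}: k_a must exceed k_m so the terminal phase is "
                "governed by urinary elimination"
            )
        if not 0.0 <= self.g_m < 1.0:
            raise ValueError(f"{self.name}: g_m must be in [0, 1)")
        if self.tau_m < 0.0:
            raise ValueError(f"{self.name}: tau_m must be non-negative")

    @property
    def half_life_hr(self) -> float:
        return math.log(2.0) / self.k_m


# Default appearance rate: peak urinary excretion ~2 h after an oral bolus.
DEFAULT_K_A = 1.2

# MEHP's molar fraction (5.9%) and 5-h half-life are the two constants the
# calibration fixes; the secondary-metabolite fractions and half-lives are
# transcribed from the single-person self-dosing calibration literature and
# are configuration entries, not model structure.
_DEFAULTS = {
    "MEHP": dict(f_m=0.059, half_life_hr=5.0),
    "MEHHP": dict(f_m=0.233, half_life_hr=10.0),
    "MEOHP": dict(f_m=0.150, half_life_hr=10.0),
    "MECPP": dict(f_m=0.185, half_life_hr=12.0),
}


def default_specs(
    k_a: float = DEFAULT_K_A,
    second_phase: bool = False,
    g_m: float = 0.15,
    tau_m: float = 24.0,
    overrides: dict | None = None,
) -> tuple[MetaboliteSpec, ...]:
    """The four default metabolite specs, in canonical order.

    ``overrides`` maps metabolite name to a dict of field replacements,
    e.g. ``{"MECPP": {"f_m": 0.2}}``.
    """
    specs = []
    for name in METABOLITES:
        d = _DEFAULTS[name]
        spec = MetaboliteSpec(
            name=name,
            f_m=d["f_m"],
            k_m=math.log(2.0) / d["half_life_hr"],
            mw=MW_METABOLITE[name],
            k_a=k_a,
            g_m=g_m if second_phase else 0.0,
            tau_m=tau_m,
        )
        if overrides and name in overrides:
            spec = replace(spec, **overrides[name])
        specs.append(spec)
    return tuple(specs)


@dataclass(frozen=True)
class Subject:
    id: str
    sex: str = "M"
    body_weight: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.body_weight is None:
            # study convention: 70 kg for men, 60 kg for women
            object.__setattr__(self, "body_weight", 70.0 if self.sex == "M" else 60.0)
        if self.body_weight <= 0:
            raise ValueError("body_weight must be positive")


@dataclass(frozen=True)
class DoseEvent:
    """One exposure event.

    ``time`` is minutes from study start, ``dose`` µg DEHP per kg body
    weight, ``spread`` the duration in minutes over which the dose is
    delivered as equal 15-min sub-boluses centred on ``time`` (half the
    window before, half after); 0 means a single-step bolus.
    """

    time: float
    dose: float
    spread: float = 0.0

    def __post_init__(self) -> None:
        if self.dose <= 0.0:
            raise ValueError("dose must be positive")
        if self.time < 0.0:
            raise ValueError("event time must be non-negative")
        if self.spread < 0.0:
            raise ValueError("spread must be non-negative")


@dataclass(frozen=True)
class VoidRecord:
    """One observed urination: time (min), full volume (L) and measured
    concentrations (µg/L) aligned with :data:`~dehprecon.constants.METABOLITES`;
    NaN marks a missing measurement, ``below_lod`` flags censored values."""

    time: float
    volume: float
    conc: np.ndarray
    below_lod: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError("void volume must be positive")


@dataclass(frozen=True)
class PredictedVoid:
    """Model prediction at one void: excreted mass (µg) and concentration
    (µg/L) per metabolite, concentration = mass / volume exactly."""

    time: float
    volume: float
    mass: np.ndarray
    conc: np.ndarray


@dataclass
class SimConfig:
    grid_step_min: float = 15.0

    def __post_init__(self) -> None:
        if self.grid_step_min <= 0:
            raise ValueError("grid step must be positive")

    def snap(self, t: float) -> float:
        """Snap a time to the grid, rounding down."""
        return math.floor(t / self.grid_step_min) * self.grid_step_min


@dataclass
class SimulationState:
    """Per-metabolite masses on the simulation grid: appearance pool ``A``,
    body pool ``P`` (destined for urine), bladder ``B`` and cumulative
    voided mass, each a length-4 array; plus pending delayed (second-phase)
    inputs as (release time, mass vector) pairs."""

    t: float
    A: np.ndarray
    P: np.ndarray
    B: np.ndarray
    voided: np.ndarray
    pending: list[tuple[float, np.ndarray]] = field(default_factory=list)

    @classmethod
    def initial(cls, n: int = 4, t: float = 0.0) -> "SimulationState":
        z = lambda: np.zeros(n)
        return cls(t=t, A=z(), P=z(), B=z(), voided=z())

    @property
    def total(self) -> np.ndarray:
        pend = sum((m for _, m in self.pending), np.zeros_like(self.A))
        return self.A + self.P + self.B + self.voided + pend


def dose_input_mass(dose: float, subject: Subject, spec: MetaboliteSpec) -> float:
    """First-phase metabolite mass (µg) ultimately excreted from a dose.

    A dose of ``dose`` µg DEHP/kg delivers ``dose × body_weight / MW_DEHP``
    µmol of parent, of which the molar fraction ``f_m`` appears in urine as
    the metabolite; converting back through the metabolite's molecular
    weight gives mass.  The second phase, when enabled, adds ``g_m`` times
    this amount after the lag.
    """
    if dose < 0:
        raise ValueError("dose must be non-negative")
    return spec.f_m * (dose * subject.body_weight / MW_DEHP) * spec.mw


def _advance(state: SimulationState, dt_min: float, k_a: np.ndarray, k_m: np.ndarray) -> None:
    """Exact in-place update of A → P → B over ``dt_min`` with no inputs."""
    if dt_min == 0.0:
        return
    dt = dt_min / 60.0  # rates are per hour
    em = np.exp(-k_m * dt)
    P_new = state.P * em
    A_new = np.zeros_like(state.A)
    for i in range(len(k_a)):
        ka, km, a = k_a[i], k_m[i], state.A[i]
        if a == 0.0:
            continue
        if math.isinf(ka):
            # instantaneous appearance: A should never hold mass
            P_new[i] += a * em[i]
        else:
            ea = math.exp(-ka * dt)
            A_new[i] = a * ea
            if abs(ka - km) > 1e-12 * km:
                P_new[i] += a * ka / (ka - km) * (em[i] - ea)
            else:  # degenerate Bateman limit k_a == k_m
                P_new[i] += a * km * dt * em[i]
    # no loss pathway: whatever left A and P entered the bladder
    state.B = state.B + (state.A + state.P - A_new - P_new)
    state.A = A_new
    state.P = P_new
    state.t += dt_min


def step(
    state: SimulationState,
    dt: float,
    inputs: np.ndarray,
    specs: tuple[MetaboliteSpec, ...],
) -> SimulationState:
    """Advance the state by ``dt`` minutes after adding per-metabolite input
    masses (µg) at the current time.  Returns a new state.

    The update is the exact exponential solution of the first-order chain,
    so any positive ``dt`` is admissible; callers normally use the grid step.
    """
    k_a = np.array([s.k_a for s in specs])
    k_m = np.array([s.k_m for s in specs])
    new = SimulationState(
        t=state.t,
        A=state.A.copy(),
        P=state.P.copy(),
        B=state.B.copy(),
        voided=state.voided.copy(),
        pending=list(state.pending),
    )
    _apply_inputs(new, np.asarray(inputs, dtype=float), k_a)
    _advance(new, dt, k_a, k_m)
    return new


def _apply_inputs(state: SimulationState, inputs: np.ndarray, k_a: np.ndarray) -> None:
    finite = np.isfinite(k_a)
    state.A = state.A + np.where(finite, inputs, 0.0)
    state.P = state.P + np.where(finite, 0.0, inputs)


def expand_spread(event: DoseEvent, grid_step_min: float = 15.0) -> list[DoseEvent]:
    """Expand a spread dose into its equal 15-min sub-boluses.

    Half the spread window precedes the nominal time and half follows it; a
    spread of 0 returns the event itself.  Sub-bolus doses sum exactly to
    the original dose.  Each sub-bolus is delivered at the centre of its
    15-min slice so the impulse train is exactly centred on the nominal
    time (slice-start delivery would advance the mean delivery time by half
    a step, a first-order artefact that would dominate the comparison with
    the unspread bolus).
    """
    if event.spread == 0.0:
        return [event]
    n = int(round(event.spread / grid_step_min))
    if n < 1 or abs(n * grid_step_min - event.spread) > 1e-9:
        raise ValueError("spread must be a positive multiple of the grid step")
    start = event.time - event.spread / 2.0
    times = [start + (i + 0.5) * grid_step_min for i in range(n)]
    return [DoseEvent(time=max(t, 0.0), dose=event.dose / n, spread=0.0) for t in times]


def simulate(
    subject: Subject,
    doses: list[DoseEvent],
    voids: list[tuple[float, float]] | list[VoidRecord],
    specs: tuple[MetaboliteSpec, ...] = None,
    config: SimConfig | None = None,
) -> list[PredictedVoid]:
    """Predict void concentrations for a dose schedule.

    ``voids`` is a time-sorted list of (time_min, volume_L) pairs or
    :class:`VoidRecord` objects.  Dose and void times snap down to the
    simulation grid; at each void the bladder mass is emitted as
    concentration (mass/volume) and the bladder is emptied.
    """
    if specs is None:
        specs = default_specs()
    config = config or SimConfig()
    pairs = [(v.time, v.volume) for v in voids] if voids and isinstance(voids[0], VoidRecord) else list(voids)
    times = [t for t, _ in pairs]
    if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("voids must be sorted by time")
    if any(vol <= 0 for _, vol in pairs):
        raise ValueError("void volumes must be positive")

    k_a = np.array([s.k_a for s in specs])
    k_m = np.array([s.k_m for s in specs])

    # build the input timeline: snapped sub-boluses, plus delayed second-phase
    # releases at dose time + tau_m
    inputs: dict[float, np.ndarray] = {}

    def add_input(t: float, mass: np.ndarray) -> None:
        t = max(t, 0.0)
        if t in inputs:
            inputs[t] = inputs[t] + mass
        else:
            inputs[t] = mass.copy()

    for ev in doses:
        # the nominal event time snaps down to the grid; spread sub-boluses
        # keep their centred (possibly half-step) offsets
        snapped = DoseEvent(time=config.snap(ev.time), dose=ev.dose, spread=ev.spread)
        for sub in expand_spread(snapped, config.grid_step_min):
            first = np.array([dose_input_mass(sub.dose, subject, s) for s in specs])
            add_input(sub.time, first)
            for i, s in enumerate(specs):
                if s.g_m > 0.0:
                    delayed = np.zeros(len(specs))
                    delayed[i] = s.g_m * first[i]
                    add_input(sub.time + s.tau_m * 60.0, delayed)

    void_nodes = [(config.snap(t), vol) for t, vol in pairs]
    horizon = void_nodes[-1][0] if void_nodes else 0.0
    node_times = sorted(
        {0.0, horizon}
        | {t for t in inputs if t <= horizon}
        | {t for t, _ in void_nodes}
    )

    state = SimulationState.initial(len(specs))
    predicted: list[PredictedVoid] = []
    vi = 0
    for t in node_times:
        _advance(state, t - state.t, k_a, k_m)
        if t in inputs:
            _apply_inputs(state, inputs[t], k_a)
        while vi < len(void_nodes) and void_nodes[vi][0] == t:
            _, vol = void_nodes[vi]
            mass = state.B.copy()
            state.voided = state.voided + mass
            state.B = np.zeros_like(state.B)
            predicted.append(
                PredictedVoid(time=pairs[vi][0], volume=vol, mass=mass, conc=mass / vol)
            )
            vi += 1
    return predicted


def cumulative_molar_fraction(
    subject: Subject,
    dose_event: DoseEvent,
    spec: MetaboliteSpec,
    horizon_hr: float,
    config: SimConfig | None = None,
) -> float:
    """Fraction of the dose, on a molar basis, excreted as the metabolite
    within ``horizon_hr`` hours of the event.  Approaches ``f_m`` (times
    ``1 + g_m`` with the second phase on) as the horizon grows."""
    if horizon_hr <= 0:
        raise ValueError("horizon must be positive")
    if dose_event.dose == 0:
        raise ValueError("molar fraction undefined for a zero dose")
    end = dose_event.time + horizon_hr * 60.0
    pred = simulate(subject, [dose_event], [(end, 1.0)], (spec,), config)
    excreted_umol = pred[0].mass[0] / spec.mw
    dose_umol = dose_event.dose * subject.body_weight / MW_DEHP
    return float(excreted_umol / dose_umol)
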