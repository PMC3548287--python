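"""Synthetic biomonitoring cohort with the statistical structure of the
8-subject × 7-day full-void study design.

The generator emulates: four men at 70 kg and four women at 60 kg observed
for seven days; roughly 7.6 voids per person-day (a fixed morning void plus
daytime-weighted extras) for ≈ 427 voids across the 56 person-days;
0–4 exposure events per day with magnitudes lognormal over ~1–60 µg/kg;
~30% of events at night (2200–0500) with somewhat smaller doses so night
accounts for ~20% of intake; about two-thirds of daytime events anchored to
within ±60 min of a diary food/beverage entry; multiplicative lognormal
measurement noise and limit-of-detection censoring on the simulated
concentrations.  Ground-truth events are returned for recovery studies.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np

from .constants import METABOLITES
from .dose_recon import DiaryEntry
from .pk_forward import (
    DoseEvent,
    SimConfig,
    Subject,
    VoidRecord,
    default_specs,
    simulate,
)

__all__ = ["CohortConfig", "Cohort", "generate", "single_subject", "write_fixture"]

MIN_PER_DAY = 1440.0


class ConfigurationError(ValueError):
    pass


@dataclass
class CohortConfig:
    n_subjects: int = 8
    n_male: int = 4
    n_days: int = 7
    # voids: one wake-time void plus Poisson extras, daytime weighted
    voids_extra_mean: float = 6.9
    wake_mean_hr: float = 6.75
    wake_sd_hr: float = 0.5
    volume_median_l: float = 0.25
    volume_cv: float = 0.4
    # exposure events
    events_per_day_probs: tuple = (0.07, 0.35, 0.43, 0.11, 0.04)
    dose_median: float = 4.0
    dose_sigma: float = 1.0
    dose_min: float = 0.5
    dose_max: float = 60.0
    night_prob: float = 0.3
    night_dose_scale: float = 0.65
    diary_anchor_frac: float = 2.0 / 3.0
    # observation model
    noise_cv: float = 0.2
    lod: dict = field(default_factory=lambda: {m: 0.5 for m in METABOLITES})
    grid_step_min: float = 15.0
    second_phase: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        probs = np.asarray(self.events_per_day_probs, dtype=float)
        if np.any(probs < 0) or np.any(probs > 1) or abs(probs.sum() - 1.0) > 1e-9:
            raise ConfigurationError("events_per_day_probs must be a probability vector")
        if len(probs) - 1 > MIN_PER_DAY / self.grid_step_min:
            raise ConfigurationError("more events per day than grid steps")
        for name in (
            "voids_extra_mean", "volume_median_l", "volume_cv",
            "dose_median", "dose_sigma", "dose_min", "dose_max",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("night_prob", "diary_anchor_frac"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be non-negative")
        if not 0 < self.n_male <= self.n_subjects:
            raise ConfigurationError("n_male must be in (0, n_subjects]")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class Cohort:
    subjects: list
    voids: dict  # subject id -> list[VoidRecord], observed concentrations
    diary: dict  # subject id -> list[DiaryEntry]
    true_events: dict  # subject id -> list[DoseEvent]
    config: CohortConfig


def _snap(t: float, step: float) -> float:
    return math.floor(t / step) * step


def _lognormal_sigma(cv: float) -> float:
    return math.sqrt(math.log(1.0 + cv * cv))


def _draw_diary(rng: np.random.Generator, day_start: float, wake_min: float) -> list:
    # diary timestamps carry whole-minute precision, like real diaries
    def entry(offset_min: float, cat: str, desc: str) -> DiaryEntry:
        return DiaryEntry(day_start + round(offset_min), cat, desc)

    entries = [
        entry(wake_min + 30.0 + rng.normal(0, 15), "food", "breakfast"),
        entry(12.5 * 60.0 + rng.normal(0, 40), "food", "lunch"),
        entry(18.5 * 60.0 + rng.normal(0, 40), "food", "dinner"),
    ]
    if rng.random() < 0.6:
        entries.append(entry(9.5 * 60.0 + rng.normal(0, 30), "beverage", "coffee"))
    if rng.random() < 0.4:
        entries.append(entry(15.5 * 60.0 + rng.normal(0, 30), "food", "snack"))
    if rng.random() < 0.3:
        entries.append(entry(8.0 * 60.0 + rng.normal(0, 30), "driving", "commute"))
    return sorted(entries, key=lambda d: d.time)


def _night_clock_min(rng: np.random.Generator) -> float:
    # uniform over the 7-h window [2200, 0500), wrapped into the same day
    u = rng.uniform(0.0, 7.0 * 60.0)
    return (22.0 * 60.0 + u) % MIN_PER_DAY


def _observe(
    subject: Subject,
    void_times: list,
    volumes: list,
    events: list,
    specs,
    cfg_noise_cv: float,
    lod: np.ndarray,
    sim_config: SimConfig,
    rng: np.random.Generator,
) -> list:
    """Simulate true concentrations, apply noise and LOD censoring."""
    pairs = list(zip(void_times, volumes))
    pred = simulate(subject, events, pairs, specs, sim_config)
    records = []
    sigma = _lognormal_sigma(cfg_noise_cv) if cfg_noise_cv > 0 else 0.0
    for p in pred:
        conc = p.conc.copy()
        if sigma > 0:
            conc = conc * rng.lognormal(0.0, sigma, size=conc.shape)
        below = conc < lod
        conc = np.where(below, np.nan, conc)
        records.append(
            VoidRecord(time=p.time, volume=p.volume, conc=conc, below_lod=below)
        )
    return records


def generate(config: CohortConfig | None = None, specs=None) -> Cohort:
    """Generate the full synthetic cohort; reproducible given the seed."""
    config = config or CohortConfig()
    specs = specs or default_specs(second_phase=config.second_phase)
    rng = np.random.default_rng(config.seed)
    sim_config = SimConfig(grid_step_min=config.grid_step_min)
    vol_sigma = _lognormal_sigma(config.volume_cv)
    lod = np.array([float(config.lod.get(m, 0.0)) for m in METABOLITES])
    n_ev_support = np.arange(len(config.events_per_day_probs))

    subjects, voids, diary, true_events = [], {}, {}, {}
    for si in range(config.n_subjects):
        sex = "M" if si < config.n_male else "F"
        subj = Subject(id=f"S{si + 1}", sex=sex)
        subjects.append(subj)
        times, vols, entries, events = [], [], [], []
        for day in range(config.n_days):
            day_start = day * MIN_PER_DAY
            wake = rng.normal(config.wake_mean_hr, config.wake_sd_hr) * 60.0
            wake = float(np.clip(wake, 5.0 * 60.0, 8.5 * 60.0))
            day_times = {_snap(day_start + wake, config.grid_step_min)}
            for _ in range(rng.poisson(config.voids_extra_mean)):
                if rng.random() < 0.9:
                    clock = rng.uniform(wake, 23.5 * 60.0)
                else:
                    clock = rng.uniform(0.0, wake)
                day_times.add(_snap(day_start + clock, config.grid_step_min))
            day_times = sorted(day_times)
            times.extend(day_times)
            vols.extend(
                float(np.clip(v, 0.03, 1.0))
                for v in rng.lognormal(math.log(config.volume_median_l), vol_sigma, len(day_times))
            )
            day_diary = _draw_diary(rng, day_start, wake)
            entries.extend(day_diary)
            food = [d for d in day_diary if d.category in ("food", "beverage")]
            n_ev = int(rng.choice(n_ev_support, p=config.events_per_day_probs))
            for _ in range(n_ev):
                night = rng.random() < config.night_prob
                if night:
                    clock = _night_clock_min(rng)
                elif food and rng.random() < config.diary_anchor_frac:
                    anchor = food[int(rng.integers(len(food)))]
                    clock = (anchor.time - day_start) + rng.uniform(-60.0, 60.0)
                else:
                    clock = rng.uniform(5.0 * 60.0, 22.0 * 60.0)
                clock = float(np.clip(clock, 0.0, MIN_PER_DAY - config.grid_step_min))
                dose = rng.lognormal(math.log(config.dose_median), config.dose_sigma)
                if night:
                    dose *= config.night_dose_scale
                dose = float(np.clip(dose, config.dose_min, config.dose_max))
                events.append(
                    DoseEvent(time=_snap(day_start + clock, config.grid_step_min), dose=dose)
                )
        events.sort(key=lambda e: e.time)
        voids[subj.id] = _observe(
            subj, times, vols, events, specs, config.noise_cv, lod, sim_config, rng
        )
        diary[subj.id] = entries
        true_events[subj.id] = events
    return Cohort(subjects=subjects, voids=voids, diary=diary, true_events=true_events, config=config)


def single_subject(
    seed: int = 0,
    n_days: int = 7,
    events_per_day: int = 2,
    min_gap_hr: float = 6.0,
    dose_median: float = 6.0,
    dose_sigma: float = 0.5,
    dose_min: float = 3.0,
    dose_max: float = 30.0,
    night_only: bool = False,
    night_clock_hr: tuple | None = None,
    night_doses: tuple | None = None,
    noise_cv: float = 0.0,
    voids_extra: int = 7,
    lod: float = 0.0,
    specs=None,
    grid_step_min: float = 15.0,
    subject: Subject | None = None,
):
    """A single synthetic subject for recovery and sensitivity studies:
    a fixed number of well-separated events per day (clock window 0700–2130,
    or 2200–0500 when ``night_only``), a morning void plus uniform daytime
    extras, optional multiplicative noise.

    Returns ``(subject, voids, diary, true_events)``; the diary anchors one
    food entry to each daytime event (so concordance is testable) plus the
    three conventional meals.

    With ``night_clock_hr`` (hours past midnight, values > 24 wrap into the
    small hours) the nightly events follow that fixed clock pattern with
    ±30 min jitter instead of uniform draws — e.g. ``(23.5, 26.75)`` with
    ``night_doses=(20, 10)`` mirrors a bedtime-dominated exposure pattern;
    ``night_doses`` fixes the corresponding magnitudes.
    """
    rng = np.random.default_rng(seed)
    specs = specs or default_specs()
    subject = subject or Subject(id="S1", sex="M")
    sim_config = SimConfig(grid_step_min=grid_step_min)

    times, vols, events, entries = [], [], [], []
    for day in range(n_days):
        day_start = day * MIN_PER_DAY
        # fixed wake-time and bedtime voids guarantee every daytime exposure
        # is followed by at least one observed void
        day_times = {
            _snap(day_start + 6.75 * 60.0 + rng.uniform(-15, 15), grid_step_min),
            _snap(day_start + 23.5 * 60.0 + rng.uniform(-15, 15), grid_step_min),
        }
        for _ in range(max(voids_extra - 1, 0)):
            day_times.add(_snap(day_start + rng.uniform(7.5 * 60.0, 23.25 * 60.0), grid_step_min))
        day_times = sorted(day_times)
        times.extend(day_times)
        vols.extend(float(v) for v in rng.uniform(0.12, 0.45, len(day_times)))

        if night_only and night_clock_hr is not None:
            clocks = np.array(night_clock_hr) + rng.uniform(-0.5, 0.5, len(night_clock_hr))
        else:
            if night_only:
                lo, hi = 22.0, 29.0  # wraps past midnight
            else:
                lo, hi = 7.0, 21.5
            for _ in range(1000):
                clocks = np.sort(rng.uniform(lo, hi, events_per_day))
                if events_per_day < 2 or np.min(np.diff(clocks)) >= min_gap_hr:
                    break
        meals = [
            DiaryEntry(day_start + 7.25 * 60.0, "food", "breakfast"),
            DiaryEntry(day_start + 12.5 * 60.0, "food", "lunch"),
            DiaryEntry(day_start + 18.5 * 60.0, "food", "dinner"),
        ]
        entries.extend(meals)
        for k, c in enumerate(clocks):
            clock_min = (c % 24.0) * 60.0
            if night_doses is not None and night_only:
                dose = float(night_doses[k % len(night_doses)])
            else:
                dose = float(
                    np.clip(rng.lognormal(math.log(dose_median), dose_sigma), dose_min, dose_max)
                )
            t = _snap(day_start + clock_min, grid_step_min)
            events.append(DoseEvent(time=t, dose=dose))
            if not night_only:
                entries.append(DiaryEntry(t + round(rng.uniform(-45, 45)), "food", "snack"))
    events.sort(key=lambda e: e.time)
    entries.sort(key=lambda d: d.time)

    lod_vec = np.full(len(specs), float(lod))
    voids = _observe(subject, times, vols, events, specs, noise_cv, lod_vec, sim_config, rng)
    return subject, voids, entries, events


def write_fixture(cohort: Cohort, out_dir) -> dict:
    """Write the cohort as the delimited-text fixture files (voids, diary,
    true events) plus a manifest with the seed and config hash."""
    from pathlib import Path

    from . import io as dio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    start = dio.DEFAULT_STUDY_START
    dio.write_voids(cohort.voids, out / "voids.csv", start)
    dio.write_diary(cohort.diary, out / "diary.csv", start)
    dio.write_events(cohort.true_events, out / "events.csv", start)
    manifest = {
        "seed": cohort.config.seed,
        "config_hash": cohort.config.hash(),
        "n_subjects": len(cohort.subjects),
        "n_voids": sum(len(v) for v in cohort.voids.values()),
        "study_start": start.isoformat(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
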