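"""Delimited-text readers/writers and configuration handling.

File formats (all comma-delimited, ISO 8601 local datetimes — the study's
clock-time semantics, e.g. the 2200–0500 nighttime window, are local):

* voids:  subject_id, datetime, volume_L, conc_MEHP, conc_MEHHP,
  conc_MEOHP, conc_MECPP — blank means not measured, the token ``<LOD``
  marks a censored value;
* diary:  subject_id, datetime, category, description;
* events: subject_id, datetime, dose_ug_per_kg, spread_min.

Internally all times are minutes from local midnight of the first study
day.  Readers validate eagerly and report every offending row with its line
number; configuration files reject unknown keys (fail fast on typos).
"""

from __future__ import annotations

import csv
import dataclasses
import math
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import yaml

from .constants import METABOLITES
from .dose_recon import DiaryEntry, FitConfig
from .pk_forward import DoseEvent, MetaboliteSpec, SimConfig, VoidRecord, default_specs
from .synthetic_cohort import CohortConfig

__all__ = [
    "ValidationError",
    "read_voids",
    "write_voids",
    "read_diary",
    "write_diary",
    "read_events",
    "write_events",
    "read_config",
    "write_config",
    "default_config",
    "specs_from_config",
    "fit_from_config",
    "sim_from_config",
    "cohort_from_config",
]

DEFAULT_STUDY_START = datetime(2005, 10, 31)  # local midnight of day 1

VOID_COLUMNS = ["subject_id", "datetime", "volume_L"] + [f"conc_{m}" for m in METABOLITES]
DIARY_COLUMNS = ["subject_id", "datetime", "category", "description"]
EVENT_COLUMNS = ["subject_id", "datetime", "dose_ug_per_kg", "spread_min"]
DIARY_CATEGORIES = ("food", "beverage", "driving", "other")
LOD_TOKEN = "<LOD"


class ValidationError(ValueError):
    """Input validation failure; ``problems`` lists row-level messages."""

    def __init__(self, message: str, problems: list | None = None):
        self.problems = problems or []
        detail = "".join(f"\n  {p}" for p in self.problems)
        super().__init__(message + detail)


def _parse_dt(text: str) -> datetime:
    return datetime.fromisoformat(text.strip())


def _minutes(dt: datetime, start: datetime) -> float:
    return (dt - start).total_seconds() / 60.0


def _check_header(reader: csv.DictReader, required: list, path) -> None:
    have = reader.fieldnames or []
    missing = [c for c in required if c not in have]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")


def _infer_start(rows_dts: list[datetime]) -> datetime:
    first = min(rows_dts)
    return datetime(first.year, first.month, first.day)


def read_voids(path) -> tuple[dict, datetime]:
    """Parse a void file into time-sorted :class:`VoidRecord` lists per
    subject; returns ``(records_by_subject, study_start)`` where study start
    is local midnight of the earliest date in the file."""
    path = Path(path)
    problems: list[str] = []
    raw = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader, VOID_COLUMNS, path)
        for ln, row in enumerate(reader, start=2):
            try:
                dt = _parse_dt(row["datetime"])
            except ValueError:
                problems.append(f"line {ln}: unparseable datetime {row['datetime']!r}")
                continue
            try:
                vol = float(row["volume_L"])
            except ValueError:
                problems.append(f"line {ln}: unparseable volume {row['volume_L']!r}")
                continue
            if vol <= 0:
                problems.append(f"line {ln}: non-positive volume {vol}")
                continue
            conc = np.full(len(METABOLITES), np.nan)
            below = np.zeros(len(METABOLITES), dtype=bool)
            bad = False
            for j, m in enumerate(METABOLITES):
                cell = (row.get(f"conc_{m}") or "").strip()
                if cell == "":
                    continue
                if cell == LOD_TOKEN:
                    below[j] = True
                    continue
                try:
                    val = float(cell)
                except ValueError:
                    problems.append(f"line {ln}: unparseable concentration {cell!r} for {m}")
                    bad = True
                    break
                if val < 0:
                    problems.append(f"line {ln}: negative concentration for {m}")
                    bad = True
                    break
                conc[j] = val
            if not bad:
                raw.append((row["subject_id"].strip(), dt, vol, conc, below))
    if problems:
        raise ValidationError(f"{path}: invalid void rows", problems)
    if not raw:
        return {}, DEFAULT_STUDY_START
    start = _infer_start([r[1] for r in raw])
    by_subject: dict[str, list[VoidRecord]] = {}
    for sid, dt, vol, conc, below in raw:
        by_subject.setdefault(sid, []).append(
            VoidRecord(time=_minutes(dt, start), volume=vol, conc=conc, below_lod=below)
        )
    for recs in by_subject.values():
        recs.sort(key=lambda v: v.time)
    return by_subject, start


def write_voids(voids_by_subject: dict, path, start: datetime = DEFAULT_STUDY_START) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(VOID_COLUMNS)
        for sid in voids_by_subject:
            for v in voids_by_subject[sid]:
                cells = []
                for j in range(len(METABOLITES)):
                    if v.below_lod is not None and v.below_lod[j]:
                        cells.append(LOD_TOKEN)
                    elif math.isnan(v.conc[j]):
                        cells.append("")
                    else:
                        cells.append(repr(float(v.conc[j])))
                w.writerow(
                    [sid, (start + timedelta(minutes=v.time)).isoformat(), repr(float(v.volume))]
                    + cells
                )


def read_diary(path) -> tuple[dict, datetime]:
    path = Path(path)
    problems, raw = [], []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader, DIARY_COLUMNS, path)
        for ln, row in enumerate(reader, start=2):
            try:
                dt = _parse_dt(row["datetime"])
            except ValueError:
                problems.append(f"line {ln}: unparseable datetime {row['datetime']!r}")
                continue
            cat = row["category"].strip()
            if cat not in DIARY_CATEGORIES:
                problems.append(f"line {ln}: unknown category {cat!r}")
                continue
            raw.append((row["subject_id"].strip(), dt, cat, (row.get("description") or "").strip()))
    if problems:
        raise ValidationError(f"{path}: invalid diary rows", problems)
    if not raw:
        return {}, DEFAULT_STUDY_START
    start = _infer_start([r[1] for r in raw])
    out: dict[str, list[DiaryEntry]] = {}
    for sid, dt, cat, desc in raw:
        out.setdefault(sid, []).append(DiaryEntry(time=_minutes(dt, start), category=cat, description=desc))
    for entries in out.values():
        entries.sort(key=lambda d: d.time)
    return out, start


def write_diary(diary_by_subject: dict, path, start: datetime = DEFAULT_STUDY_START) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(DIARY_COLUMNS)
        for sid in diary_by_subject:
            for d in diary_by_subject[sid]:
                w.writerow([sid, (start + timedelta(minutes=d.time)).isoformat(), d.category, d.description])


def read_events(path) -> tuple[dict, datetime]:
    path = Path(path)
    problems, raw = [], []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader, EVENT_COLUMNS, path)
        for ln, row in enumerate(reader, start=2):
            try:
                dt = _parse_dt(row["datetime"])
                dose = float(row["dose_ug_per_kg"])
                spread = float(row.get("spread_min") or 0.0)
            except ValueError as exc:
                problems.append(f"line {ln}: {exc}")
                continue
            if dose <= 0:
                problems.append(f"line {ln}: non-positive dose {dose}")
                continue
            raw.append((row["subject_id"].strip(), dt, dose, spread))
    if problems:
        raise ValidationError(f"{path}: invalid event rows", problems)
    if not raw:
        return {}, DEFAULT_STUDY_START
    start = _infer_start([r[1] for r in raw])
    out: dict[str, list[DoseEvent]] = {}
    for sid, dt, dose, spread in raw:
        out.setdefault(sid, []).append(DoseEvent(time=_minutes(dt, start), dose=dose, spread=spread))
    for evs in out.values():
        evs.sort(key=lambda e: e.time)
    return out, start


def write_events(events_by_subject: dict, path, start: datetime = DEFAULT_STUDY_START) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(EVENT_COLUMNS)
        for sid in events_by_subject:
            for e in events_by_subject[sid]:
                w.writerow(
                    [sid, (start + timedelta(minutes=e.time)).isoformat(), repr(float(e.dose)), repr(float(e.spread))]
                )


# ---------------------------------------------------------------------------
# configuration


def _metabolite_defaults() -> dict:
    out = {}
    for spec in default_specs():
        out[spec.name] = {
            "f_m": spec.f_m,
            "half_life_hr": spec.half_life_hr,
            "k_a": spec.k_a,
            "g_m": spec.g_m,
            "tau_m": spec.tau_m,
        }
    return out


def default_config() -> dict:
    """The full default configuration tree.

    Metabolite constants: MEHP's molar fraction (0.059) and 5-h half-life
    are the calibration's printed constants; the secondary-metabolite
    fractions and half-lives are reference values transcribed from the
    single-person self-dosing calibration literature and should be
    overridden if a different calibration is adopted.
    """
    return {
        "metabolites": _metabolite_defaults(),
        "simulation": {"grid_step_min": 15.0, "second_phase": False},
        "fit": {f.name: _plain(getattr(FitConfig(), f.name)) for f in dataclasses.fields(FitConfig)},
        "cohort": {f.name: _plain(getattr(CohortConfig(), f.name)) for f in dataclasses.fields(CohortConfig)},
        "seed": 0,
    }


def _plain(v):
    if isinstance(v, tuple):
        return list(v)
    if isinstance(v, dict):
        return dict(v)
    return v


def _merge_checked(defaults: dict, user: dict, path: str, problems: list) -> dict:
    out = dict(defaults)
    for key, val in (user or {}).items():
        if key not in defaults:
            problems.append(f"unknown config key {path}{key!r}")
            continue
        if isinstance(defaults[key], dict) and isinstance(val, dict):
            out[key] = _merge_checked(defaults[key], val, f"{path}{key}.", problems)
        else:
            out[key] = _plain(val)
    return out


def read_config(path) -> dict:
    """Load a YAML configuration, validate keys, and fill defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValidationError(f"{path}: config root must be a mapping")
    problems: list[str] = []
    cfg = _merge_checked(default_config(), user, "", problems)
    if problems:
        raise ValidationError(f"{path}: invalid configuration", problems)
    return cfg


def write_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def specs_from_config(cfg: dict) -> tuple:
    second = bool(cfg["simulation"]["second_phase"])
    specs = []
    from .constants import MW_METABOLITE

    for name in METABOLITES:
        m = cfg["metabolites"][name]
        k_a = m.get("k_a", math.inf)
        specs.append(
            MetaboliteSpec(
                name=name,
                f_m=float(m["f_m"]),
                k_m=math.log(2.0) / float(m["half_life_hr"]),
                mw=MW_METABOLITE[name],
                k_a=float(k_a) if k_a is not None else math.inf,
                g_m=float(m.get("g_m", 0.0)) if second else 0.0,
                tau_m=float(m.get("tau_m", 24.0)),
            )
        )
    return tuple(specs)


def sim_from_config(cfg: dict) -> SimConfig:
    return SimConfig(grid_step_min=float(cfg["simulation"]["grid_step_min"]))


def fit_from_config(cfg: dict) -> FitConfig:
    kw = dict(cfg["fit"])
    kw["dose_bounds"] = tuple(kw["dose_bounds"])
    return FitConfig(**kw)


def cohort_from_config(cfg: dict, seed: int | None = None) -> CohortConfig:
    kw = dict(cfg["cohort"])
    kw["events_per_day_probs"] = tuple(kw["events_per_day_probs"])
    if seed is not None:
        kw["seed"] = int(seed)
    return CohortConfig(**kw)
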