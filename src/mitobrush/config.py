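"""Structured configuration files (YAML dialect, strictly validated).

A full configuration has four sections plus an optional fifth::

    build:       # BottlebrushConfig fields
      n_beads: 1200
      bp_per_bead: 2000
      loop_len_range_bp: [60000, 120000]
      n_bridges: auto          # or an integer
      box_size: auto           # cubic edge in bead diameters, or auto
      centromere_span: null    # [lo, hi) bead interval -> sister chromatids
      seed: 0
    forcefield:  # ForceFieldParams fields (all optional)
      A: 4.0
      eps_weak: 3.0
      eps_strong: 8.0
    engine:      # EngineParams fields
      dt: 0.01
    schedule:    # Schedule fields
      phase1_steps: 2000
      phase2_steps: 60000
      snapshot_every: 2000
    pulling:     # optional PullingProtocol
      force_magnitude: 20.0

Unknown sections or keys are hard errors; every violated invariant is
collected so one load reports all problems at once.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

import yaml

from .engine import EngineParams, PullingProtocol, Schedule
from .errors import ConfigError, ValidationError
from .forcefield import ForceFieldParams
from .state import BottlebrushConfig, CoarseGrainingMap


@dataclass(frozen=True)
class FullConfig:
    build: BottlebrushConfig
    forcefield: ForceFieldParams
    engine: EngineParams
    schedule: Schedule
    pulling: Optional[PullingProtocol] = None


_SECTION_FIELDS = {
    "build": {"n_beads", "bp_per_bead", "sigma_nm", "loop_len_range_bp", "n_bridges",
              "box_size", "centromere_span", "seed"},
    "forcefield": {f.name for f in dataclasses.fields(ForceFieldParams)},
    "engine": {f.name for f in dataclasses.fields(EngineParams)},
    "schedule": {f.name for f in dataclasses.fields(Schedule)} - {"pulling"},
    "pulling": {f.name for f in dataclasses.fields(PullingProtocol)},
}


def _check_keys(section: str, data: dict, problems: list) -> dict:
    if data is None:
        return {}
    if not isinstance(data, dict):
        problems.append(f"section '{section}' must be a mapping")
        return {}
    unknown = set(data) - _SECTION_FIELDS[section]
    if unknown:
        problems.append(f"unknown key(s) in '{section}': {sorted(unknown)}")
    return {k: v for k, v in data.items() if k in _SECTION_FIELDS[section]}


def _build_section(kw: dict, problems: list) -> Optional[BottlebrushConfig]:
    kw = dict(kw)
    cg_kw = {}
    if "bp_per_bead" in kw:
        cg_kw["bp_per_bead"] = kw.pop("bp_per_bead")
    if "sigma_nm" in kw:
        cg_kw["sigma_nm"] = kw.pop("sigma_nm")
    if "n_beads" not in kw:
        problems.append("build.n_beads is required")
        return None
    for key in ("loop_len_range_bp", "centromere_span"):
        if kw.get(key) is not None:
            kw[key] = tuple(kw[key])
    for key in ("box_size", "n_bridges"):
        if kw.get(key) == "auto":
            kw[key] = None if key == "box_size" else "auto"
    try:
        return BottlebrushConfig(cg=CoarseGrainingMap(**cg_kw), **kw)
    except (ConfigError, TypeError) as err:
        problems.append(f"build: {err}")
        return None


def config_from_dict(raw: dict) -> FullConfig:
    problems: list[str] = []
    if not isinstance(raw, dict):
        raise ValidationError(["top level must be a mapping of sections"])
    unknown_sections = set(raw) - set(_SECTION_FIELDS)
    if unknown_sections:
        problems.append(f"unknown section(s): {sorted(unknown_sections)}")
    if "build" not in raw:
        problems.append("missing required section 'build'")

    build = _build_section(_check_keys("build", raw.get("build"), problems), problems) \
        if "build" in raw else None

    def make(cls, section):
        kw = _check_keys(section, raw.get(section), problems)
        if section == "pulling":
            if raw.get(section) is None:
                return None
            if kw.get("end_regions") is not None:
                kw["end_regions"] = tuple(tuple(r) for r in kw["end_regions"])
        try:
            return cls(**kw)
        except (ConfigError, TypeError) as err:
            problems.append(f"{section}: {err}")
            return None

    ff = make(ForceFieldParams, "forcefield")
    eng = make(EngineParams, "engine")
    sched = make(Schedule, "schedule")
    pull = make(PullingProtocol, "pulling")
    if problems:
        raise ValidationError(problems)
    return FullConfig(build=build, forcefield=ff, engine=eng, schedule=sched, pulling=pull)


def load_config(path) -> FullConfig:
    """Load and strictly validate a YAML configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return config_from_dict(raw if raw is not None else {})


def config_to_dict(cfg: FullConfig) -> dict:
    b = cfg.build
    out = {
        "build": {
            "n_beads": b.n_beads,
            "bp_per_bead": b.cg.bp_per_bead,
            "loop_len_range_bp": list(b.loop_len_range_bp),
            "n_bridges": b.n_bridges,
            "box_size": "auto" if b.box_size is None else b.box_size,
            "centromere_span": None if b.centromere_span is None else list(b.centromere_span),
            "seed": b.seed,
        },
        "forcefield": dataclasses.asdict(cfg.forcefield),
        "engine": dataclasses.asdict(cfg.engine),
        "schedule": {k: v for k, v in dataclasses.asdict(cfg.schedule).items() if k != "pulling"},
    }
    if b.cg.sigma_nm is not None:
        out["build"]["sigma_nm"] = b.cg.sigma_nm
    if cfg.pulling is not None:
        d = dataclasses.asdict(cfg.pulling)
        if d["end_regions"] is not None:
            d["end_regions"] = [list(r) for r in d["end_regions"]]
        out["pulling"] = d
    return out


def dump_config(cfg: FullConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)


def default_config(n_beads: int = 1200, **build_kw) -> FullConfig:
    """Wild-type desk-scale defaults."""
    return FullConfig(
        build=BottlebrushConfig(n_beads=n_beads, **build_kw),
        forcefield=ForceFieldParams(),
        engine=EngineParams(),
        schedule=Schedule(),
    )
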