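"""Plain-text configuration files and hierarchical seed derivation.

Config files are flat ``key = value`` text (``#`` comments allowed); values
are coerced to int, float or bool where possible. Keys are split between the
landscape generator, the simulation parameters and the study design by the
corresponding builder functions, so one file can configure a whole study.

Seeds for every run are derived from a single master seed plus a structured
key (stage name, landscape, scenario, replicate, ...) through
``numpy.random.SeedSequence`` so any single run is independently
reproducible without sharing stream state across runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np

from .ibm import SimConfig
from .landscape import LandscapeParams

__all__ = ["read_config", "sim_config_from", "landscape_params_from", "derive_seed", "config_hash"]

_STAGES = (
    "landscape",
    "pool",
    "scenarios",
    "burnin",
    "run",
    "fit",
    "global_draw",
)


def _coerce(raw: str):
    raw = raw.strip()
    low = raw.lower()
    if low in ("true", "false"):
        return low == "true"
    for cast in (int, float):
        try:
            return cast(raw)
        except ValueError:
            continue
    return raw


def read_config(path) -> dict:
    """Parse a flat key=value text config file."""
    out = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, _, val = line.partition("=")
        out[key.strip()] = _coerce(val)
    return out


def _pick(d: dict, cls) -> dict:
    names = {f.name for f in dataclasses.fields(cls)}
    return {k: v for k, v in d.items() if k in names}


def sim_config_from(d: dict, **overrides) -> SimConfig:
    kw = _pick(d, SimConfig)
    kw.update(overrides)
    if "change_duration" not in kw and "duration" in d:
        kw["change_duration"] = d["duration"]
    return SimConfig(**kw)


def landscape_params_from(d: dict, **overrides) -> LandscapeParams:
    kw = _pick(d, LandscapeParams)
    kw.update(overrides)
    return LandscapeParams(**kw)


def derive_seed(master_seed: int, stage: str, *key: int) -> int:
    """Deterministic per-run seed from the master seed and a structured key."""
    if stage not in _STAGES:
        raise ValueError(f"unknown seeding stage {stage!r}")
    ss = np.random.SeedSequence(
        entropy=int(master_seed), spawn_key=(_STAGES.index(stage), *map(int, key))
    )
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def config_hash(obj) -> str:
    """Short stable hash of a configuration object for provenance records."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
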