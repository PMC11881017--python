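"""Serialization: landscapes and grids as CSV, tables as TSV, state checkpoints.

Grids travel as plain CSV (row-major) with generation parameters embedded in
``# key=value`` header comments, or as compressed ``.npz`` containers for
bulk use. Burned-in simulation states checkpoint via pickle so one burn-in
can be shared across the many scenarios of a landscape.
"""

from __future__ import annotations

import json
import pickle
from pathlib import Path

import numpy as np
import pandas as pd

from .landscape import EnvironmentalLandscape, LandscapeParams
from .scenarios import LossScenario

__all__ = [
    "landscape_to_csv",
    "landscape_from_csv",
    "loss_map_to_csv",
    "loss_map_from_csv",
    "grids_to_npz",
    "scenario_table",
    "write_tsv",
    "save_state",
    "load_state",
    "write_manifest",
]


def _write_grid_csv(path, grid: np.ndarray, meta: dict) -> None:
    with open(path, "w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}={val}\n")
        np.savetxt(fh, grid, delimiter=",")


def _read_grid_csv(path):
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
            body_start = i + 1
        else:
            break
    grid = np.loadtxt(lines[body_start:], delimiter=",")
    return grid, meta


def landscape_to_csv(landscape: EnvironmentalLandscape, path) -> None:
    p = landscape.params
    meta = {
        "mu_e": p.mu_e,
        "sigma_e": p.sigma_e,
        "l_e": p.l_e,
        "amplitude_a": p.amplitude_a,
        "resolution": p.resolution,
        "seed": p.seed,
        "gearys_c": landscape.gearys_c,
    }
    _write_grid_csv(path, landscape.grid, meta)


def landscape_from_csv(path) -> EnvironmentalLandscape:
    grid, meta = _read_grid_csv(path)
    params = LandscapeParams(
        mu_e=float(meta.get("mu_e", 0.0)),
        sigma_e=float(meta.get("sigma_e", 1.0)),
        l_e=float(meta.get("l_e", 0.1)),
        amplitude_a=float(meta.get("amplitude_a", 1.0)),
        resolution=int(meta.get("resolution", grid.shape[0])),
        seed=int(meta.get("seed", 0)),
    )
    return EnvironmentalLandscape(
        grid=grid, params=params, gearys_c=float(meta.get("gearys_c", "nan"))
    )


def loss_map_to_csv(scenario: LossScenario, path) -> None:
    meta = {"l_hl": scenario.l_hl, "p_l": scenario.p_l, "seed": scenario.seed}
    _write_grid_csv(path, scenario.loss_grid, meta)


def loss_map_from_csv(path) -> LossScenario:
    grid, meta = _read_grid_csv(path)
    return LossScenario(
        loss_grid=grid.astype(np.int8),
        l_hl=float(meta.get("l_hl", "nan")),
        p_l=float(meta.get("p_l", "nan")),
        seed=int(meta.get("seed", -1)),
    )


def grids_to_npz(path, **named_grids) -> None:
    """Compressed binary container for one or more grids."""
    np.savez_compressed(path, **named_grids)


def scenario_table(scenarios, properties, landscape_id: int = 0) -> pd.DataFrame:
    """Tidy per-scenario table of loss parameters and realized properties."""
    rows = []
    for sid, (sc, pr) in enumerate(zip(scenarios, properties)):
        rows.append(
            {
                "landscape_id": landscape_id,
                "scenario_id": sid,
                "seed": sc.seed,
                "l_hl": sc.l_hl,
                "p_l": sc.p_l,
                "delta_Be": pr.delta_Be,
                "delta_mu_e": pr.delta_mu_e,
                "B1": pr.B1,
                "B2": pr.B2,
                "fraction_lost": pr.fraction_lost,
            }
        )
    return pd.DataFrame(rows)


def write_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def save_state(state, path) -> None:
    """Checkpoint a simulation state (binary pickle container)."""
    with open(path, "wb") as fh:
        pickle.dump(state, fh)


def load_state(path):
    with open(path, "rb") as fh:
        return pickle.load(fh)


def write_manifest(path, **entries) -> None:
    """Run-provenance manifest (seeds, config, sizes) as JSON."""
    Path(path).write_text(json.dumps(entries, indent=2, default=str) + "\n")
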