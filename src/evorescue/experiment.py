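"""Study orchestration: main-effects, interaction and sensitivity designs.

A :class:`StudyDesign` fixes the shape of a study — how many environmental
landscapes, how many habitat-loss scenarios per landscape property, how many
replicate populations — plus the simulation configuration and a master seed
from which every run's seed is derived hierarchically, so any single
(landscape, scenario, replicate) cell is independently reproducible.

The main design mirrors the core experiment: for each landscape, scenario
sets are selected per property (``delta_Be``, ``delta_mu_e``, ``l_hl``) by
weighted density sampling; each scenario runs with warming (``delta_e``) and
as a no-change control (``delta_e = 0``); outcomes are aggregated to
persistence proportions and each property gets a hierarchical random-slope
logit fit. The interaction design swaps the scenario selection for the
pairwise low/high-band sets and fits fixed-effect interaction models; the
sensitivity modes re-run a reduced main design over parameter grids (local)
or random parameter draws within bounds (global), reporting slope-sign
stability.

Defaults are desk-scale. The study shape of the original full experiment
(50 landscapes, 50 scenarios per property, 100 replicates, 10,000-generation
burn-in, 100,000 candidate scenarios) is available as :data:`FULL_PROFILE`;
it is a cluster-sized workload and not meant for a single workstation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import config_hash, derive_seed
from .ibm import SimConfig, run_burn_in, run_scenario
from .inference import (
    FixedPersistenceModel,
    HierarchicalPersistenceModel,
    InteractionPersistenceModel,
    slope_comparison,
)
from .landscape import LandscapeParams, generate_landscape
from .outcomes import aggregate_persistence, records_to_frame, score_trajectory
from .scenarios import PROPERTY_NAMES, _candidate_pool, interaction_design, sample_scenarios

__all__ = ["StudyDesign", "FULL_PROFILE", "run_main_design", "run_interaction_design", "run_sensitivity"]


@dataclass(frozen=True)
class StudyDesign:
    """Shape and parameters of one study."""

    n_landscapes: int = 5
    n_scenarios_per_property: int = 15
    n_replicates: int = 20
    n_replicates_control: int | None = None  # default: same as n_replicates
    properties: tuple = PROPERTY_NAMES
    n_candidates: int = 2000
    band_sd: float = 0.25  # non-focal constraint band, in pooled SDs
    p_l: float = 2.0 / 3.0
    mu_e: float = 0.0
    sigma_e: float = 1.0
    l_e: float = 0.1
    resolution: int = 128
    delta_e: float = 3.0
    master_seed: int = 0
    cfg: SimConfig = field(default_factory=lambda: SimConfig(K=500, burn_in=1500))
    fit_models: bool = True
    fit_check: bool = False  # report diagnostics without raising, by default
    fit_kwargs: dict = field(default_factory=dict)
    n_jobs: int = 1

    @property
    def n_control(self) -> int:
        return self.n_replicates if self.n_replicates_control is None else self.n_replicates_control


FULL_PROFILE = StudyDesign(
    n_landscapes=50,
    n_scenarios_per_property=50,
    n_replicates=100,
    n_candidates=100_000,
    cfg=SimConfig(K=1000, burn_in=10_000),
)


def _landscape_for(design: StudyDesign, lid: int):
    params = LandscapeParams(
        mu_e=design.mu_e,
        sigma_e=design.sigma_e,
        l_e=design.l_e,
        resolution=design.resolution,
        seed=derive_seed(design.master_seed, "landscape", lid),
    )
    return generate_landscape(params)


def _burn_in_states(design: StudyDesign, landscape, lid: int) -> list:
    """One burn-in per (landscape, replicate), shared across its scenarios."""
    n_states = max(design.n_replicates, design.n_control)
    return [
        run_burn_in(landscape, design.cfg, seed=derive_seed(design.master_seed, "burnin", lid, r))
        for r in range(n_states)
    ]


def _simulate_scenario_set(
    design: StudyDesign,
    landscape,
    lid: int,
    states: list,
    scenario_sets: dict,
    set_offset: int = 0,
):
    """Run all (scenario, replicate, arm) cells of a landscape; score outcomes."""
    records = []
    for set_idx, (set_name, (scens, props)) in enumerate(scenario_sets.items()):
        for sid, (sc, pr) in enumerate(zip(scens, props)):
            scenario_key = (set_offset + set_idx) * 10_000 + sid
            for arm, delta_e, n_rep in (
                ("change", design.delta_e, design.n_replicates),
                ("control", 0.0, design.n_control),
            ):
                for r in range(n_rep):
                    seed = derive_seed(
                        design.master_seed, "run", lid, scenario_key, r, 0 if arm == "change" else 1
                    )
                    traj = run_scenario(states[r], sc, design.cfg, seed=seed, delta_e=delta_e)
                    rec = score_trajectory(
                        traj, landscape_id=lid, scenario_id=scenario_key, replicate=r, properties=pr
                    )
                    records.append((set_name, arm, rec))
    return records


def _records_frame(tagged_records) -> pd.DataFrame:
    df = records_to_frame([rec for _, _, rec in tagged_records])
    df.insert(0, "set_name", [s for s, _, _ in tagged_records])
    df.insert(1, "arm", [a for _, a, _ in tagged_records])
    return df


def _one_main_landscape(design: StudyDesign, lid: int):
    landscape = _landscape_for(design, lid)
    pool = _candidate_pool(
        landscape, design.n_candidates, design.p_l, derive_seed(design.master_seed, "pool", lid)
    )
    scenario_sets = {}
    for prop in design.properties:
        scenario_sets[prop] = sample_scenarios(
            landscape,
            design.n_candidates,
            design.n_scenarios_per_property,
            focal=prop,
            seed=derive_seed(design.master_seed, "scenarios", lid, design.properties.index(prop)),
            p_l=design.p_l,
            band_sd=design.band_sd,
            candidates=pool,
        )
    states = _burn_in_states(design, landscape, lid)
    return _simulate_scenario_set(design, landscape, lid, states, scenario_sets)


def run_main_design(design: StudyDesign) -> dict:
    """Execute the main-effects study; returns tables and per-property fits.

    Returns a dict with ``records`` (one row per replicate run),
    ``aggregated`` (persistence proportions per scenario and arm), ``fits``
    (property -> fitted hierarchical results, when >= 3 landscapes), a
    ``posterior`` summary table, and a ``manifest`` of provenance metadata.
    """
    if design.n_jobs != 1:
        from joblib import Parallel, delayed

        per_landscape = Parallel(n_jobs=design.n_jobs)(
            delayed(_one_main_landscape)(design, lid) for lid in range(design.n_landscapes)
        )
    else:
        per_landscape = [_one_main_landscape(design, lid) for lid in range(design.n_landscapes)]
    tagged = [t for chunk in per_landscape for t in chunk]
    records = _records_frame(tagged)
    agg = aggregate_persistence(records, keys=["set_name", "arm", "landscape_id", "scenario_id"])
    fits, posterior_rows = {}, []
    if design.fit_models and design.n_landscapes >= 3:
        for prop in design.properties:
            sub = agg[(agg.set_name == prop) & (agg.arm == "change")]
            model = HierarchicalPersistenceModel.from_frame(sub, prop)
            res = model.fit(
                seed=derive_seed(design.master_seed, "fit", design.properties.index(prop)),
                **design.fit_kwargs,
                check=False,
            )
            if design.fit_check:
                res.check()
            fits[prop] = res
            summ = res.summary()
            summ.insert(0, "property", prop)
            posterior_rows.append(summ)
    posterior = pd.concat(posterior_rows, ignore_index=True) if posterior_rows else pd.DataFrame()
    manifest = {
        "design": design.__dict__ | {"cfg": design.cfg.__dict__},
        "config_hash": config_hash(design.cfg),
        "n_runs": len(records),
    }
    return {"records": records, "aggregated": agg, "fits": fits, "posterior": posterior, "manifest": manifest}


def run_interaction_design(design: StudyDesign, pairs=None) -> dict:
    """Pairwise two-way interaction study.

    For every ordered property pair (V1, V2) — six pairs over the three
    properties — two scenario sets pin V2 near its 25th / 75th percentile
    while V1 varies freely, plus a control set where only V1 varies. Each
    pair gets a fixed-effects interaction fit (pooled across bands) and a
    per-condition slope comparison against the control.
    """
    pairs = list(pairs) if pairs is not None else list(itertools.permutations(design.properties, 2))
    all_tagged = []
    set_registry = {}
    for lid in range(design.n_landscapes):
        landscape = _landscape_for(design, lid)
        pool = _candidate_pool(
            landscape, design.n_candidates, design.p_l, derive_seed(design.master_seed, "pool", lid)
        )
        scenario_sets = {}
        for pi, (v1, v2) in enumerate(pairs):
            bands = interaction_design(
                pool,
                v1,
                v2,
                n_select=design.n_scenarios_per_property,
                seed=derive_seed(design.master_seed, "scenarios", lid, 100 + pi),
                mean_band_sd=design.band_sd,
            )
            scenario_sets[f"{v1}|{v2}|p25"] = bands["p25"]
            scenario_sets[f"{v1}|{v2}|p75"] = bands["p75"]
        for vi, v1 in enumerate(design.properties):
            scenario_sets[f"{v1}|control"] = sample_scenarios(
                landscape,
                design.n_candidates,
                design.n_scenarios_per_property,
                focal=v1,
                seed=derive_seed(design.master_seed, "scenarios", lid, 200 + vi),
                p_l=design.p_l,
                candidates=pool,
            )
        set_registry[lid] = list(scenario_sets)
        states = _burn_in_states(design, landscape, lid)
        all_tagged.extend(
            _simulate_scenario_set(design, landscape, lid, states, scenario_sets, set_offset=0)
        )
    records = _records_frame(all_tagged)
    agg = aggregate_persistence(records, keys=["set_name", "arm", "landscape_id", "scenario_id"])
    fits, comparisons = {}, {}
    if design.fit_models:
        for pi, (v1, v2) in enumerate(pairs):
            rows = agg[
                agg.set_name.isin([f"{v1}|{v2}|p25", f"{v1}|{v2}|p75"]) & (agg.arm == "change")
            ]
            model = InteractionPersistenceModel.from_frame(rows, v1, v2)
            res = model.fit(
                seed=derive_seed(design.master_seed, "fit", 100 + pi),
                **design.fit_kwargs,
                check=False,
            )
            if design.fit_check:
                res.check()
            fits[(v1, v2)] = res
            # per-condition slopes on the control's V1 scale
            ctrl_rows = agg[(agg.set_name == f"{v1}|control") & (agg.arm == "change")]
            ctrl_model = FixedPersistenceModel(
                ctrl_rows["persisted"], ctrl_rows["trials"], ctrl_rows[v1], name=v1
            )
            st = ctrl_model.standardizers[v1]
            cond_fits = {"control": ctrl_model.fit(seed=derive_seed(design.master_seed, "fit", 300 + pi), check=False)}
            for band_i, band in enumerate(("p25", "p75")):
                band_rows = agg[(agg.set_name == f"{v1}|{v2}|{band}") & (agg.arm == "change")]
                bm = FixedPersistenceModel(
                    band_rows["persisted"], band_rows["trials"], band_rows[v1], name=v1, standardizer=st
                )
                cond_fits[band] = bm.fit(
                    seed=derive_seed(design.master_seed, "fit", 400 + 2 * pi + band_i), check=False
                )
            comparisons[(v1, v2)] = slope_comparison(cond_fits)
    manifest = {
        "design": design.__dict__ | {"cfg": design.cfg.__dict__},
        "pairs": [f"{a}|{b}" for a, b in pairs],
        "n_sets": {lid: len(v) for lid, v in set_registry.items()},
        "n_runs": len(records),
    }
    return {
        "records": records,
        "aggregated": agg,
        "fits": fits,
        "comparisons": comparisons,
        "manifest": manifest,
    }


def _slope_sign_rows(result: dict, label_cols: dict) -> list:
    rows = []
    for prop, res in result["fits"].items():
        mean = float(res._flat("beta1").mean())
        rows.append(
            dict(
                label_cols,
                property=prop if isinstance(prop, str) else "|".join(prop),
                slope_mean=mean,
                slope_sign=int(np.sign(mean)),
            )
        )
    return rows


def run_sensitivity(design: StudyDesign, mode: str, grid=None, bounds=None, n_draws: int = 8) -> dict:
    """Parameter-sensitivity sweeps over reduced main designs.

    ``mode="local"``: ``grid`` maps parameter name -> iterable of values;
    each (parameter, value) re-runs the main design with that single value
    changed. ``mode="global"``: ``bounds`` maps parameter name -> (lo, hi);
    ``n_draws`` random joint draws are evaluated. Returns per-setting fits
    and a slope-sign stability table.
    """
    rows, results = [], {}
    if mode == "local":
        if not grid:
            raise ValueError("local sensitivity requires a parameter grid")
        for param, values in grid.items():
            for value in values:
                sub = _with_param(design, param, value)
                res = run_main_design(sub)
                results[(param, value)] = res
                rows.extend(_slope_sign_rows(res, {"mode": "local", "parameter": param, "value": value}))
    elif mode == "global":
        if not bounds:
            raise ValueError("global sensitivity requires parameter bounds")
        rng = np.random.default_rng(derive_seed(design.master_seed, "global_draw", 0))
        for draw in range(n_draws):
            sampled = {p: float(rng.uniform(lo, hi)) for p, (lo, hi) in bounds.items()}
            sub = design
            for p, v in sampled.items():
                sub = _with_param(sub, p, v)
            res = run_main_design(sub)
            results[draw] = res
            for p, v in sampled.items():
                rows.extend(
                    _slope_sign_rows(res, {"mode": "global", "draw": draw, "parameter": p, "value": v})
                )
    else:
        raise ValueError("mode must be 'local' or 'global'")
    return {"results": results, "sign_table": pd.DataFrame(rows)}


def _with_param(design: StudyDesign, param: str, value) -> StudyDesign:
    """New design with one parameter replaced, wherever it lives."""
    if hasattr(design.cfg, param):
        cast = int if isinstance(getattr(design.cfg, param), int) else float
        return replace(design, cfg=replace(design.cfg, **{param: cast(value)}))
    if hasattr(design, param):
        return replace(design, **{param: value})
    raise ValueError(f"unknown parameter {param!r}")
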