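"""Reduce simulation trajectories to per-replicate outcome metrics.

For each (landscape, scenario, replicate) run the trajectory is scored into
a single record: whether the population persisted to the final census
(100 generations after the end of the 100-generation warming ramp), the
first-passage time to extinction when it did not, the final population size
and segregating-allele count as fractions of their pre-loss values, the mean
per-individual per-generation displacement over the post-loss period
(non-movers contribute zero), and the final phenotypic variance. Persistence
proportions aggregated over replicates feed the binomial likelihood of the
downstream hierarchical models.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = [
    "OutcomeRecord",
    "score_trajectory",
    "records_to_frame",
    "aggregate_persistence",
    "plot_trajectories",
]


@dataclass
class OutcomeRecord:
    """One replicate's outcome metrics plus its scenario's properties."""

    landscape_id: int
    scenario_id: int
    replicate: int
    persisted: bool
    t_extinct: float  # generations after loss; NaN when censored (persisted)
    delta_n_i: float  # final / pre-loss population size
    delta_n_a: float  # final / pre-loss segregating-allele count
    mu_d: float  # mean displacement per individual-generation, post-loss
    var_pheno: float  # phenotypic variance at the final census
    delta_Be: float = np.nan
    delta_mu_e: float = np.nan
    l_hl: float = np.nan
    delta_e: float = np.nan


def score_trajectory(
    trajectory: pd.DataFrame,
    landscape_id: int = 0,
    scenario_id: int = 0,
    replicate: int = 0,
    properties=None,
) -> OutcomeRecord:
    """Score one :func:`evorescue.ibm.run_scenario` trajectory.

    ``persisted`` is population size > 0 at the final scheduled census;
    ``t_extinct`` is the first post-loss generation with size zero (censored
    as NaN when the population persists). Size and allele ratios use the
    pre-loss census stored in ``trajectory.attrs``.
    """
    attrs = trajectory.attrs
    if "pre_loss" not in attrs:
        raise ValueError("trajectory lacks the pre-loss census (malformed input)")
    pre = attrs["pre_loss"]
    horizon = attrs.get("horizon", int(trajectory["generation"].max()))
    final = trajectory.iloc[-1]
    extinct = final["n_alive"] == 0
    persisted = (not extinct) and final["generation"] == horizon
    t_extinct = float(final["generation"]) if extinct else np.nan
    n_pre = pre["n_alive"]
    a_pre = pre["n_alleles"]
    # displacement averaged over post-loss individual-generations
    alive = trajectory["n_alive"].to_numpy(dtype=float)
    disp = trajectory["mean_displacement"].to_numpy(dtype=float)
    weights = alive  # per-generation mean weighted by individuals present
    mu_d = float((disp * weights).sum() / weights.sum()) if weights.sum() > 0 else 0.0
    rec = OutcomeRecord(
        landscape_id=landscape_id,
        scenario_id=scenario_id,
        replicate=replicate,
        persisted=bool(persisted),
        t_extinct=t_extinct,
        delta_n_i=float(final["n_alive"] / n_pre) if n_pre else np.nan,
        delta_n_a=float(final["n_alleles"] / a_pre) if a_pre else np.nan,
        mu_d=mu_d,
        var_pheno=float(final["var_phenotype"]),
        delta_e=float(attrs.get("delta_e", np.nan)),
    )
    if properties is not None:
        rec.delta_Be = properties.delta_Be
        rec.delta_mu_e = properties.delta_mu_e
        rec.l_hl = properties.l_hl
    return rec


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


def aggregate_persistence(records, keys=("landscape_id", "scenario_id")) -> pd.DataFrame:
    """Persistence proportion per group, with trial counts for the binomial fit.

    Scenario properties (and delta_e) are carried through as group-constant
    columns when present.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if df.empty:
        raise ValueError("no outcome records to aggregate")
    keys = list(keys)
    agg = df.groupby(keys, as_index=False).agg(
        persisted=("persisted", "sum"), trials=("persisted", "size")
    )
    agg["p_persist"] = agg["persisted"] / agg["trials"]
    carry = [c for c in ("delta_Be", "delta_mu_e", "l_hl", "delta_e") if c in df.columns]
    if carry:
        const = df.groupby(keys, as_index=False)[carry].first()
        agg = agg.merge(const, on=keys)
    return agg


def plot_trajectories(trajectories, column: str = "n_alive", ax=None):
    """Diagnostic spaghetti plot of per-run census series (one line per run)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for traj in trajectories:
        ax.plot(traj["generation"], traj[column], alpha=0.5, lw=1)
    ax.set_xlabel("generations since habitat loss")
    ax.set_ylabel(column)
    return ax
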