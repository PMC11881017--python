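"""Spatially explicit, non-Wright-Fisher individual-based model.

Diploid hermaphroditic individuals live on the unit torus, locally adapted to
an autocorrelated environmental landscape. Each generation every individual,
in this fixed order: (1) attempts to reproduce with its nearest neighbor
within the perception radius 3*sigma_p, producing Poisson(lambda_0)
offspring placed at its own position; (2) performs one habitat-choice step
(a uniform candidate displacement within sigma_p per axis, accepted only if
fitness there is higher), newborns included; (3) survives with probability
w_i, the product of a local-density competition factor and a Gaussian
phenotype-environment matching factor; (4) ages, with a hard cap of 10
generations. Survival probability is

    w_i = min(1, (2 pi sigma_p^2 K / C_i) * exp(-((P_i - e) sigma_b)^2 / (2 sigma_f^2)))

where C_i is the Gaussian-kernel competition load summed over neighbors
within 3*sigma_p, K the landscape-wide carrying capacity, P_i the additive
polygenic phenotype, e the (possibly warmed) local environmental value, and
sigma_b a selection ramp that rises from sigma_b0 to 1 over the burn-in so
local adaptation can establish before full selection applies.

Mutation occurs only during the burn-in; afterwards populations can respond
to habitat loss and warming only through movement and standing genetic
variation (no de-novo rescue mutations).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import genome as gn
from .landscape import EnvironmentalLandscape, WarmingSchedule, torus_distance
from .scenarios import LossScenario

__all__ = [
    "SimConfig",
    "SimState",
    "BurnInExtinctionError",
    "competition_kernel",
    "total_competition",
    "total_competition_bruteforce",
    "sigma_b_schedule",
    "matching_component",
    "fitness",
    "select_mate",
    "step_generation",
    "init_population",
    "run_burn_in",
    "apply_habitat_loss",
    "run_scenario",
]

_TIE_EPS = 1e-12


class BurnInExtinctionError(RuntimeError):
    """Population went extinct during burn-in (mis-calibrated configuration)."""


@dataclass(frozen=True)
class SimConfig:
    """All individual-based-model parameters.

    Defaults are the desk-calibrated study conditions: a landscape-wide
    carrying capacity ``K`` enforced through local density dependence at
    perception scale ``sigma_p``, Gaussian phenotype-environment matching of
    width ``sigma_f``, QTL effect-size SD ``sigma_qtl``, and per-site
    mutation rate ``mu_rate * p_qtl`` active only during burn-in.
    """

    K: int = 1000
    sigma_p: float = 0.02
    sigma_f: float = 0.5
    sigma_qtl: float = 0.1
    mu_rate: float = 1e-7
    p_qtl: float = 1.0
    lambda_0: float = 0.45
    max_age: int = 10
    burn_in: int = 10_000
    sigma_b0: float = 0.1
    delta_e: float = 3.0
    change_duration: int = 100
    post_change: int = 100
    n_linkage_groups: int = 20  # 10 QTL-bearing simulated + 10 neutral, untracked
    n_qtl_groups: int = 10
    sites_per_group: int = 50_000
    recomb_rate: float = 1e-8
    habitat_choice_fitness: str = "full"  # or "match_only"
    seed: int = 0

    def __post_init__(self):
        if self.sigma_p <= 0:
            raise ValueError("sigma_p must be positive")
        if self.sigma_f <= 0:
            raise ValueError("sigma_f must be positive")
        for name in ("sigma_qtl", "mu_rate", "p_qtl", "lambda_0", "recomb_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.habitat_choice_fitness not in ("full", "match_only"):
            raise ValueError("habitat_choice_fitness must be 'full' or 'match_only'")

    @property
    def interaction_radius(self) -> float:
        return 3.0 * self.sigma_p

    @property
    def mutation_rate_per_site(self) -> float:
        return self.mu_rate * self.p_qtl


@dataclass
class SimState:
    """The evolving population plus its environment and bookkeeping."""

    cfg: SimConfig
    landscape: EnvironmentalLandscape
    rng: np.random.Generator
    registry: gn.AlleleRegistry
    x: np.ndarray
    y: np.ndarray
    age: np.ndarray
    ids: np.ndarray
    phenotype: np.ndarray
    genomes: list
    allele_ids: list
    generation: int = 0
    next_id: int = 0
    scenario: LossScenario | None = None
    schedule: WarmingSchedule | None = None
    last_mean_displacement: float = 0.0

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def sigma_b(self) -> float:
        return sigma_b_schedule(self.generation, self.cfg.burn_in, self.cfg.sigma_b0)

    def positions(self) -> np.ndarray:
        return np.column_stack((self.x, self.y))

    def env_values(self, x=None, y=None) -> np.ndarray:
        """Warmed environmental values at coordinates (default: everyone)."""
        if x is None:
            x, y = self.x, self.y
        vals = self.landscape.values_at(x, y)
        if self.schedule is not None:
            vals = vals + self.schedule.offset(self.generation)
        return vals

    def clone(self, seed: int) -> "SimState":
        """Independent copy for re-running scenarios off one burned-in state.

        Shares the (frozen) allele table but not counts, positions, or the
        random stream. Only valid once mutation has ceased growing the table
        or when the clone will not be advanced alongside the original.
        """
        return SimState(
            cfg=self.cfg,
            landscape=self.landscape,
            rng=np.random.default_rng(seed),
            registry=self.registry.clone_counts(),
            x=self.x.copy(),
            y=self.y.copy(),
            age=self.age.copy(),
            ids=self.ids.copy(),
            phenotype=self.phenotype.copy(),
            genomes=list(self.genomes),
            allele_ids=list(self.allele_ids),
            generation=self.generation,
            next_id=self.next_id,
            scenario=self.scenario,
            schedule=self.schedule,
        )


def competition_kernel(d, sigma_p: float):
    """Gaussian competition strength; zero beyond the 3*sigma_p cutoff."""
    if sigma_p <= 0:
        raise ValueError("sigma_p must be positive")
    d = np.asarray(d, dtype=float)
    c = np.exp(-(d**2) / (2.0 * sigma_p**2))
    return np.where(d < 3.0 * sigma_p, c, 0.0)


def _competition_from_tree(tree: cKDTree, positions: np.ndarray, sigma_p: float) -> np.ndarray:
    """Competition load C_i for every individual, via periodic KD-tree pairs."""
    n = positions.shape[0]
    C = np.zeros(n)
    if n < 2:
        return C
    pairs = tree.query_pairs(3.0 * sigma_p, output_type="ndarray")
    if pairs.size:
        d = torus_distance(positions[pairs[:, 0]], positions[pairs[:, 1]])
        c = np.exp(-(d**2) / (2.0 * sigma_p**2))
        np.add.at(C, pairs[:, 0], c)
        np.add.at(C, pairs[:, 1], c)
    return C


def total_competition(state: SimState, positions: np.ndarray | None = None) -> np.ndarray:
    """C_i for all individuals (Gaussian kernel, 3*sigma_p cutoff, self excluded)."""
    pos = state.positions() if positions is None else positions
    tree = cKDTree(pos, boxsize=1.0)
    return _competition_from_tree(tree, pos, state.cfg.sigma_p)


def total_competition_bruteforce(positions: np.ndarray, sigma_p: float) -> np.ndarray:
    """O(n^2) all-pairs oracle for C_i; used to validate the indexed version."""
    n = positions.shape[0]
    C = np.zeros(n)
    for i in range(n):
        d = torus_distance(positions[i], positions)
        c = np.exp(-(d**2) / (2.0 * sigma_p**2))
        keep = (d < 3.0 * sigma_p) & (np.arange(n) != i)
        C[i] = c[keep].sum()
    return C


def sigma_b_schedule(generation: int, burn_in: int, sigma_b0: float = 0.1) -> float:
    """Selection-ramp value: linear from sigma_b0 at 0 to 1 at burn-in end."""
    if generation >= burn_in or burn_in <= 0:
        return 1.0
    return sigma_b0 + (1.0 - sigma_b0) * generation / burn_in


def matching_component(phenotype, env_value, sigma_b: float, sigma_f: float):
    """Gaussian phenotype-environment matching factor, max 1 at perfect match."""
    if sigma_f <= 0:
        raise ValueError("sigma_f must be positive")
    dev = (np.asarray(phenotype, dtype=float) - np.asarray(env_value, dtype=float)) * sigma_b
    return np.exp(-(dev**2) / (2.0 * sigma_f**2))


def fitness(
    phenotype,
    env_value,
    C,
    sigma_b: float,
    cfg: SimConfig,
    destroyed=None,
):
    """Survival probability w_i: competition factor x matching factor, clamped to [0, 1].

    ``C = 0`` (no neighbors) makes the competition factor 1, so an isolated
    individual's survival equals its matching component. Positions flagged
    ``destroyed`` (non-habitat) have w_i = 0.
    """
    C = np.asarray(C, dtype=float)
    cap = 2.0 * math.pi * cfg.sigma_p**2 * cfg.K
    with np.errstate(divide="ignore"):
        comp = np.where(C > 0, cap / np.where(C > 0, C, 1.0), 1.0)
    w = np.minimum(1.0, comp * matching_component(phenotype, env_value, sigma_b, cfg.sigma_f))
    if destroyed is not None:
        w = np.where(destroyed, 0.0, w)
    return w


def select_mate(state: SimState, index: int) -> int | None:
    """Index of the strictly nearest other individual within 3*sigma_p.

    Distance ties are broken by the lowest individual id; returns ``None``
    when no other individual is inside the perception radius (the individual
    then skips reproduction this generation). Exact reference implementation
    (all-pairs); the generation step uses an equivalent indexed search.
    """
    n = state.n
    if n < 2:
        return None
    pos = state.positions()
    d = torus_distance(pos[index], pos)
    d[index] = np.inf
    dmin = d.min()
    if dmin >= state.cfg.interaction_radius:
        return None
    tied = np.flatnonzero(d <= dmin + _TIE_EPS)
    return int(tied[np.argmin(state.ids[tied])])


def _nearest_mates(
    tree: cKDTree, positions: np.ndarray, ids: np.ndarray, radius: float
) -> np.ndarray:
    """Vectorized nearest-other-individual with lowest-id tie-breaking.

    Ties are resolved among the nearest ``k<=8`` neighbors returned by the
    tree, which covers the common coincident-position case (offspring born
    at a parent's position). Returns -1 where no mate is in range.
    """
    n = positions.shape[0]
    out = np.full(n, -1, dtype=np.intp)
    if n < 2:
        return out
    k = min(8, n)
    dist, idx = tree.query(positions, k=k)
    rows = np.arange(n)[:, None]
    dist = np.where(idx == rows, np.inf, dist)  # exclude self
    dmin = dist.min(axis=1)
    in_range = dmin < radius
    tie = dist <= (dmin[:, None] + _TIE_EPS)
    cand_ids = np.where(tie, ids[idx], np.iinfo(np.int64).max)
    best_col = cand_ids.argmin(axis=1)
    out[in_range] = idx[np.arange(n), best_col][in_range]
    return out


def _destroyed_at(state: SimState, x, y):
    if state.scenario is None:
        return None
    return state.scenario.destroyed_at(x, y)


def step_generation(state: SimState, cfg: SimConfig | None = None) -> SimState:
    """Advance the population one generation in place (returns the state).

    Event order: reproduction, habitat choice (newborns included), viability
    selection, aging with the hard age cap, then the generation counter
    update that drives the selection ramp and warming offset. Extinction is
    absorbing.
    """
    cfg = cfg or state.cfg
    rng = state.rng
    state.last_mean_displacement = 0.0
    if state.n == 0:
        state.generation += 1
        return state

    pos = state.positions()
    tree = cKDTree(pos, boxsize=1.0)
    sigma_b = state.sigma_b
    mutate = state.generation < cfg.burn_in

    # --- 1. reproduction: nearest-neighbor mating, Poisson offspring counts
    mates = _nearest_mates(tree, pos, state.ids, cfg.interaction_radius)
    can_mate = mates >= 0
    n_off = np.zeros(state.n, dtype=np.intp)
    if can_mate.any() and cfg.lambda_0 > 0:
        n_off[can_mate] = rng.poisson(cfg.lambda_0, size=int(can_mate.sum()))
    tot_off = int(n_off.sum())
    off_genomes, off_ids_arrays, off_phen = [], [], []
    off_x = np.empty(tot_off)
    off_y = np.empty(tot_off)
    cursor = 0
    effects = state.registry.effects  # cache; may be refreshed after mutation
    for i in np.flatnonzero(n_off):
        j = mates[i]
        for _ in range(n_off[i]):
            gam1 = gn.make_gamete(
                state.genomes[i], state.registry, rng, cfg.recomb_rate,
                cfg.sites_per_group, cfg.sigma_qtl, cfg.mutation_rate_per_site, mutate,
            )
            gam2 = gn.make_gamete(
                state.genomes[j], state.registry, rng, cfg.recomb_rate,
                cfg.sites_per_group, cfg.sigma_qtl, cfg.mutation_rate_per_site, mutate,
            )
            child = (gam1, gam2)
            ids_arr = gn.flat_allele_ids(child)
            off_genomes.append(child)
            off_ids_arrays.append(ids_arr)
            # offspring position: parent 1's position, exactly
            off_x[cursor] = state.x[i]
            off_y[cursor] = state.y[i]
            cursor += 1
    if tot_off:
        effects = state.registry.effects
        off_phen = [float(effects[a].sum()) if a.size else 0.0 for a in off_ids_arrays]
        state.registry.sync_counts()
        for a in off_ids_arrays:
            if a.size:
                state.registry.add_copies(a)

    all_x = np.concatenate((state.x, off_x))
    all_y = np.concatenate((state.y, off_y))
    all_phen = np.concatenate((state.phenotype, np.asarray(off_phen)))
    all_age = np.concatenate((state.age, np.zeros(tot_off, dtype=state.age.dtype)))
    new_ids = state.next_id + np.arange(tot_off)
    state.next_id += tot_off
    all_ids = np.concatenate((state.ids, new_ids))
    all_genomes = state.genomes + off_genomes
    all_allele_ids = state.allele_ids + off_ids_arrays
    n_all = all_x.size

    # --- 2. habitat choice, everyone including newborns, synchronous
    all_pos = np.column_stack((all_x, all_y))
    tree2 = cKDTree(all_pos, boxsize=1.0)
    C_cur = _competition_from_tree(tree2, all_pos, cfg.sigma_p)
    env_cur = state.env_values(all_x, all_y)
    eps = rng.uniform(-cfg.sigma_p, cfg.sigma_p, size=(n_all, 2))
    cand = (all_pos + eps) % 1.0
    C_cand = _candidate_competition(tree2, all_pos, cand, cfg.sigma_p)
    env_cand = state.env_values(cand[:, 0], cand[:, 1])
    destroyed_cand = _destroyed_at(state, cand[:, 0], cand[:, 1])
    if cfg.habitat_choice_fitness == "match_only":
        w_cur = matching_component(all_phen, env_cur, sigma_b, cfg.sigma_f)
        w_cand = matching_component(all_phen, env_cand, sigma_b, cfg.sigma_f)
        if destroyed_cand is not None:
            w_cand = np.where(destroyed_cand, 0.0, w_cand)
    else:
        w_cur = fitness(all_phen, env_cur, C_cur, sigma_b, cfg)
        w_cand = fitness(all_phen, env_cand, C_cand, sigma_b, cfg, destroyed=destroyed_cand)
    move = w_cand > w_cur
    disp = np.zeros(n_all)
    if move.any():
        disp[move] = torus_distance(all_pos[move], cand[move])
        all_pos[move] = cand[move]
        all_x, all_y = all_pos[:, 0], all_pos[:, 1]
    state.last_mean_displacement = float(disp.mean())

    # --- 3. viability selection at post-move positions
    tree3 = cKDTree(all_pos, boxsize=1.0)
    C = _competition_from_tree(tree3, all_pos, cfg.sigma_p)
    env = state.env_values(all_x, all_y)
    w = fitness(all_phen, env, C, sigma_b, cfg)
    survive = rng.random(n_all) < w

    # --- 4. aging and the hard age cap
    all_age = all_age + 1
    survive &= all_age <= cfg.max_age

    dead = np.flatnonzero(~survive)
    if dead.size:
        dead_ids = [all_allele_ids[i] for i in dead if all_allele_ids[i].size]
        if dead_ids:
            state.registry.remove_copies(np.concatenate(dead_ids))
    keep = np.flatnonzero(survive)
    state.x = all_x[keep]
    state.y = all_y[keep]
    state.age = all_age[keep]
    state.ids = all_ids[keep]
    state.phenotype = all_phen[keep]
    state.genomes = [all_genomes[i] for i in keep]
    state.allele_ids = [all_allele_ids[i] for i in keep]

    # --- 5. schedule updates (sigma_b and warming derive from the counter)
    state.generation += 1
    return state


def _candidate_competition(
    tree: cKDTree, positions: np.ndarray, candidates: np.ndarray, sigma_p: float
) -> np.ndarray:
    """Competition load each individual would feel at its candidate position.

    Evaluated against the current (pre-move) neighbor configuration, with the
    individual itself excluded.
    """
    n = candidates.shape[0]
    C = np.zeros(n)
    neighbor_lists = tree.query_ball_point(candidates, 3.0 * sigma_p)
    lengths = np.fromiter((len(l) for l in neighbor_lists), dtype=np.intp, count=n)
    if lengths.sum() == 0:
        return C
    flat = np.concatenate([np.asarray(l, dtype=np.intp) for l in neighbor_lists if l])
    rows = np.repeat(np.arange(n), lengths)
    d = torus_distance(candidates[rows], positions[flat])
    c = np.exp(-(d**2) / (2.0 * sigma_p**2))
    c[flat == rows] = 0.0  # self is not a neighbor
    np.add.at(C, rows, c)
    return C


def init_population(
    landscape: EnvironmentalLandscape, cfg: SimConfig, rng: np.random.Generator
) -> SimState:
    """Founding population: K individuals, uniform positions, empty genomes."""
    n0 = cfg.K
    registry = gn.AlleleRegistry(cfg.n_qtl_groups)
    empty = (gn.empty_haplotype(cfg.n_qtl_groups), gn.empty_haplotype(cfg.n_qtl_groups))
    return SimState(
        cfg=cfg,
        landscape=landscape,
        rng=rng,
        registry=registry,
        x=rng.random(n0),
        y=rng.random(n0),
        age=np.zeros(n0, dtype=np.int64),
        ids=np.arange(n0, dtype=np.int64),
        phenotype=np.zeros(n0),
        genomes=[empty] * n0,
        allele_ids=[np.empty(0, dtype=np.intp)] * n0,
        next_id=n0,
    )


def run_burn_in(
    landscape: EnvironmentalLandscape, cfg: SimConfig, seed: int | None = None
) -> SimState:
    """Initialize and evolve the population through the burn-in ramp.

    Mutation is active and sigma_b ramps linearly to 1; the returned state is
    at generation ``cfg.burn_in`` with full selection. Raises
    :class:`BurnInExtinctionError` if the population dies out, which signals
    a mis-calibrated configuration rather than a scientific outcome.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    state = init_population(landscape, cfg, rng)
    for _ in range(cfg.burn_in):
        step_generation(state, cfg)
        if state.n == 0:
            raise BurnInExtinctionError(
                f"population extinct at burn-in generation {state.generation}"
            )
    return state


def apply_habitat_loss(state: SimState, scenario: LossScenario) -> SimState:
    """Destroy habitat in a single generation, removing stranded individuals.

    Individuals on destroyed cells die immediately (their genotypes leave the
    population with them); destroyed cells are unsuitable forever after.
    """
    state.scenario = scenario
    lost = scenario.destroyed_at(state.x, state.y)
    if lost.any():
        dead = np.flatnonzero(lost)
        dead_ids = [state.allele_ids[i] for i in dead if state.allele_ids[i].size]
        if dead_ids:
            state.registry.remove_copies(np.concatenate(dead_ids))
        keep = np.flatnonzero(~lost)
        state.x = state.x[keep]
        state.y = state.y[keep]
        state.age = state.age[keep]
        state.ids = state.ids[keep]
        state.phenotype = state.phenotype[keep]
        state.genomes = [state.genomes[i] for i in keep]
        state.allele_ids = [state.allele_ids[i] for i in keep]
    return state


def _census_row(state: SimState, gen_post_loss: int) -> dict:
    n = state.n
    return {
        "generation": gen_post_loss,
        "n_alive": n,
        "n_alleles": state.registry.n_segregating(),
        "mean_phenotype": float(state.phenotype.mean()) if n else np.nan,
        "var_phenotype": float(state.phenotype.var()) if n else np.nan,
        "mean_displacement": state.last_mean_displacement,
        "max_age": int(state.age.max()) if n else 0,
    }


def run_scenario(
    burned_in: SimState,
    scenario: LossScenario,
    cfg: SimConfig | None = None,
    seed: int = 0,
    delta_e: float | None = None,
) -> pd.DataFrame:
    """Habitat loss + warming run off a (re-usable) burned-in state.

    Clones the burned-in state, applies the loss scenario, starts the
    warming ramp in the same generation, and simulates
    ``change_duration + post_change`` generations (or until extinction).
    Returns the per-generation census as a DataFrame whose row at generation
    0 is the post-loss census; the pre-loss census is stored in
    ``df.attrs["pre_loss"]``.
    """
    cfg = cfg or burned_in.cfg
    state = burned_in.clone(seed)
    state.cfg = cfg
    pre = _census_row(state, -1)
    de = cfg.delta_e if delta_e is None else delta_e
    state.schedule = WarmingSchedule(
        delta_e=de, duration=cfg.change_duration, start_gen=state.generation
    )
    apply_habitat_loss(state, scenario)
    rows = [_census_row(state, 0)]
    horizon = cfg.change_duration + cfg.post_change
    for g in range(1, horizon + 1):
        step_generation(state, cfg)
        rows.append(_census_row(state, g))
        if state.n == 0:
            break
    df = pd.DataFrame(rows)
    df.attrs["pre_loss"] = pre
    df.attrs["delta_e"] = de
    df.attrs["seed"] = seed
    df.attrs["horizon"] = horizon
    return df
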