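"""Binary habitat-loss maps and the landscape properties of lost habitat.

A loss scenario destroys a fixed proportion ``p_l`` of the landscape's cells.
Which cells are destroyed is controlled by a second autocorrelated field with
its own autocorrelation length ``l_hl``: the ``p_l`` fraction of cells with
the highest field values is removed, so larger ``l_hl`` produces larger,
more contiguous destroyed (and remnant) patches, i.e. less fragmentation.

Three properties summarize what a scenario does to the environment available
to the population:

* ``delta_Be`` — change in the trimmed environmental breadth: the range of
  values strictly inside each grid's own (2.5th, 97.5th) percentile band,
  after minus before loss (negative when loss narrows the available range);
* ``delta_mu_e`` — shift of the mean environmental value of remaining
  habitat (positive when cooler-than-average cells are destroyed);
* ``l_hl`` — the loss field's autocorrelation length (fragmentation axis).

Scenario sets for a study are drawn by weighted density sampling: candidates
are scored on all three properties, and a subset is selected with inverse
kernel-density weights on a focal property (flattening its marginal so the
whole range is covered) while the non-focal properties are constrained to a
band around their candidate-pool means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .landscape import EnvironmentalLandscape, _gaussian_field

__all__ = [
    "LossScenario",
    "ScenarioProperties",
    "DegenerateScenarioError",
    "ConstraintError",
    "generate_loss_map",
    "breadth_loss",
    "mean_shift",
    "scenario_properties",
    "patch_sizes",
    "sample_scenarios",
    "interaction_design",
]

PROPERTY_NAMES = ("delta_Be", "delta_mu_e", "l_hl")


class DegenerateScenarioError(ValueError):
    """Scenario leaves too little habitat for the requested property."""


class ConstraintError(ValueError):
    """Scenario selection constraints cannot be satisfied."""

    def __init__(self, message: str, shortfall: int = 0):
        super().__init__(message)
        self.shortfall = shortfall


@dataclass
class LossScenario:
    """Binary habitat-loss map: 1 = destroyed, 0 = remaining habitat."""

    loss_grid: np.ndarray
    l_hl: float
    p_l: float
    seed: int

    @property
    def fraction_lost(self) -> float:
        return float(self.loss_grid.mean())

    def destroyed_at(self, x, y) -> np.ndarray:
        """Boolean: is the cell containing (x, y) destroyed?"""
        r = self.loss_grid.shape[0]
        i = np.floor(np.asarray(x) % 1.0 * r).astype(np.intp) % r
        j = np.floor(np.asarray(y) % 1.0 * r).astype(np.intp) % r
        return self.loss_grid[i, j].astype(bool)


@dataclass
class ScenarioProperties:
    """Realized landscape properties of one loss scenario."""

    delta_Be: float
    delta_mu_e: float
    l_hl: float
    B1: float
    B2: float
    mu_e_prime: float
    fraction_lost: float
    seed: int = -1


def no_loss_scenario(resolution: int) -> LossScenario:
    """Scenario destroying nothing (control)."""
    return LossScenario(
        loss_grid=np.zeros((resolution, resolution), dtype=np.int8),
        l_hl=np.nan,
        p_l=0.0,
        seed=-1,
    )


def generate_loss_map(l_hl: float, p_l: float, resolution: int, seed: int) -> LossScenario:
    """Quantile-threshold an autocorrelated field into a binary loss map.

    The ``round(p_l * resolution**2)`` cells with the highest field values are
    destroyed, so the destroyed fraction equals ``p_l`` up to one cell's worth
    of rounding. ``p_l = 0`` destroys nothing.
    """
    if not (0.0 <= p_l < 1.0):
        raise ValueError("p_l must lie in [0, 1)")
    if l_hl <= 0:
        raise ValueError("l_hl must be positive")
    rng = np.random.default_rng(seed)
    r = resolution
    grid = np.zeros((r, r), dtype=np.int8)
    n_destroy = int(round(p_l * r * r))
    if n_destroy > 0:
        fld = _gaussian_field(r, l_hl, rng)
        flat = fld.ravel()
        # highest-value cells are destroyed; argpartition is deterministic
        order = np.argpartition(flat, -n_destroy)[-n_destroy:]
        grid.ravel()[order] = 1
    return LossScenario(loss_grid=grid, l_hl=l_hl, p_l=p_l, seed=seed)


def _trimmed_breadth(values: np.ndarray) -> float:
    """Range of values strictly inside the set's own (P2.5, P97.5) band."""
    lo, hi = np.quantile(values, [0.025, 0.975])  # type-7 linear interpolation
    inner = values[(values > lo) & (values < hi)]
    if inner.size < 2:
        raise DegenerateScenarioError(
            "fewer than 2 habitat cells strictly inside the trimmed band"
        )
    return float(inner.max() - inner.min())


def breadth_loss(landscape: EnvironmentalLandscape, scenario: LossScenario):
    """Trimmed-breadth change (delta_Be, B1, B2) caused by the loss map.

    ``B1`` uses all landscape values with that grid's own trim percentiles;
    ``B2`` uses remaining-habitat values with the subset's own percentiles.
    """
    values = landscape.grid.ravel()
    keep = scenario.loss_grid.ravel() == 0
    b1 = _trimmed_breadth(values)
    b2 = _trimmed_breadth(values[keep])
    return b2 - b1, b1, b2


def mean_shift(landscape: EnvironmentalLandscape, scenario: LossScenario) -> float:
    """Mean environmental value of remaining habitat minus the full-grid mean."""
    values = landscape.grid.ravel()
    keep = scenario.loss_grid.ravel() == 0
    if not keep.any():
        raise DegenerateScenarioError("all habitat destroyed")
    return float(values[keep].mean() - values.mean())


def scenario_properties(
    landscape: EnvironmentalLandscape, scenario: LossScenario
) -> ScenarioProperties:
    """All three landscape properties plus breadths for one scenario."""
    delta_be, b1, b2 = breadth_loss(landscape, scenario)
    dmu = mean_shift(landscape, scenario)
    keep = scenario.loss_grid.ravel() == 0
    return ScenarioProperties(
        delta_Be=delta_be,
        delta_mu_e=dmu,
        l_hl=scenario.l_hl,
        B1=b1,
        B2=b2,
        mu_e_prime=float(landscape.grid.ravel()[keep].mean()),
        fraction_lost=scenario.fraction_lost,
        seed=scenario.seed,
    )


def patch_sizes(grid: np.ndarray, value: int = 0) -> np.ndarray:
    """Sizes of 4-connected patches of ``value`` cells on the torus.

    Components touching opposite edges are merged, honoring periodicity.
    """
    mask = np.asarray(grid) == value
    labels, n = ndimage.label(mask)  # rook connectivity
    if n == 0:
        return np.array([], dtype=np.intp)
    # merge labels across the periodic seams with union-find
    parent = np.arange(n + 1)

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for edge_a, edge_b in ((labels[0, :], labels[-1, :]), (labels[:, 0], labels[:, -1])):
        both = (edge_a > 0) & (edge_b > 0)
        for a, b in zip(edge_a[both], edge_b[both]):
            union(a, b)

    roots = np.array([find(k) for k in range(n + 1)])
    merged = roots[labels]
    sizes = np.bincount(merged.ravel())[1:]
    return sizes[sizes > 0]


def _candidate_pool(
    landscape: EnvironmentalLandscape,
    n_candidates: int,
    p_l: float,
    seed: int,
    l_hl_range: tuple[float, float] = (0.02, 0.3),
):
    """Random (l_hl, seed) candidates scored on all three properties.

    l_hl is drawn log-uniformly so both heavily fragmented and contiguous
    scenarios are well represented; degenerate scenarios (too little habitat
    inside the trim band) are skipped.
    """
    rng = np.random.default_rng(seed)
    res = landscape.resolution
    scenarios, props = [], []
    lo, hi = np.log(l_hl_range[0]), np.log(l_hl_range[1])
    while len(scenarios) < n_candidates:
        l_hl = float(np.exp(rng.uniform(lo, hi)))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        sc = generate_loss_map(l_hl, p_l, res, sub_seed)
        try:
            pr = scenario_properties(landscape, sc)
        except DegenerateScenarioError:
            continue
        scenarios.append(sc)
        props.append(pr)
    return scenarios, props


def _property_matrix(props) -> np.ndarray:
    return np.array([[p.delta_Be, p.delta_mu_e, p.l_hl] for p in props])


def _inverse_density_weights(values: np.ndarray) -> np.ndarray:
    """Selection weights inversely proportional to a Silverman-bandwidth KDE."""
    if np.ptp(values) == 0:
        return np.ones_like(values)
    kde = stats.gaussian_kde(values, bw_method="silverman")
    dens = kde(values)
    return 1.0 / np.clip(dens, 1e-300, None)


def _select_flat(
    focal_values: np.ndarray,
    eligible: np.ndarray,
    n_select: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Weighted sampling without replacement flattening the focal marginal."""
    idx = np.flatnonzero(eligible)
    if idx.size < n_select:
        raise ConstraintError(
            f"only {idx.size} candidates satisfy the non-focal constraint band, "
            f"{n_select} requested",
            shortfall=n_select - idx.size,
        )
    w = _inverse_density_weights(focal_values[idx])
    chosen = rng.choice(idx, size=n_select, replace=False, p=w / w.sum())
    return np.sort(chosen)


def sample_scenarios(
    landscape: EnvironmentalLandscape,
    n_candidates: int,
    n_select: int,
    focal: str,
    seed: int,
    p_l: float = 2.0 / 3.0,
    constrain: bool = True,
    band_sd: float = 0.25,
    candidates=None,
):
    """Select a scenario set spanning a wide range of one focal property.

    Candidates are generated by randomizing (l_hl, seed) at fixed ``p_l``;
    selection uses inverse-KDE weights on the focal property while the two
    non-focal properties are held within ``band_sd`` pooled SDs of their
    candidate-pool means. Returns (scenarios, properties) lists.
    """
    if focal not in PROPERTY_NAMES:
        raise ValueError(f"focal must be one of {PROPERTY_NAMES}")
    if n_select > n_candidates:
        raise ValueError("n_select must not exceed n_candidates")
    if candidates is None:
        candidates = _candidate_pool(landscape, n_candidates, p_l, seed)
    scens, props = candidates
    mat = _property_matrix(props)
    k = PROPERTY_NAMES.index(focal)
    rng = np.random.default_rng(seed + 1)
    if n_select == len(scens) and not constrain:
        return list(scens), list(props)
    if constrain:
        others = [i for i in range(3) if i != k]
        eligible = np.ones(len(scens), dtype=bool)
        for i in others:
            col = mat[:, i]
            eligible &= np.abs(col - col.mean()) <= band_sd * col.std()
    else:
        eligible = np.ones(len(scens), dtype=bool)
    chosen = _select_flat(mat[:, k], eligible, n_select, rng)
    return [scens[i] for i in chosen], [props[i] for i in chosen]


def interaction_design(
    candidates,
    V1: str,
    V2: str,
    n_select: int,
    seed: int,
    band_sd: float = 0.1,
    mean_band_sd: float = 0.25,
):
    """Two scenario sets probing the V1 x V2 interaction.

    For the ordered property pair (V1, V2): V1's marginal is flattened as in
    :func:`sample_scenarios`, V2 is pinned near its candidate-pool 25th or
    75th percentile (band of ``band_sd`` pooled SDs), and the third property
    is held near its mean. Returns ``{"p25": (scens, props), "p75": ...}``.
    """
    if V1 == V2:
        raise ValueError("V1 and V2 must differ")
    for v in (V1, V2):
        if v not in PROPERTY_NAMES:
            raise ValueError(f"unknown property {v!r}")
    scens, props = candidates
    mat = _property_matrix(props)
    k1 = PROPERTY_NAMES.index(V1)
    k2 = PROPERTY_NAMES.index(V2)
    k3 = ({0, 1, 2} - {k1, k2}).pop()
    col2, col3 = mat[:, k2], mat[:, k3]
    near_mean3 = np.abs(col3 - col3.mean()) <= mean_band_sd * col3.std()
    out = {}
    for tag, q in (("p25", 0.25), ("p75", 0.75)):
        target = np.quantile(col2, q)
        eligible = near_mean3 & (np.abs(col2 - target) <= band_sd * col2.std())
        rng = np.random.default_rng(seed + (0 if tag == "p25" else 1))
        chosen = _select_flat(mat[:, k1], eligible, n_select, rng)
        out[tag] = ([scens[i] for i in chosen], [props[i] for i in chosen])
    return out
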