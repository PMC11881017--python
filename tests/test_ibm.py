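"""Individual-based model: kernels, fitness, mating, generation stepping."""

import math

import numpy as np
import pytest

from evorescue.genome import phenotype_of
from evorescue.ibm import (
    BurnInExtinctionError,
    SimConfig,
    apply_habitat_loss,
    competition_kernel,
    fitness,
    init_population,
    matching_component,
    run_burn_in,
    run_scenario,
    select_mate,
    sigma_b_schedule,
    step_generation,
    total_competition,
    total_competition_bruteforce,
)
from evorescue.landscape import LandscapeParams, generate_landscape
from evorescue.scenarios import LossScenario, generate_loss_map, no_loss_scenario


def _uniform_state(landscape, cfg, n, seed=0):
    from dataclasses import replace

    rng = np.random.default_rng(seed)
    state = init_population(landscape, replace(cfg, K=max(n, 1)), rng)
    state.cfg = cfg
    state.x = rng.random(n)
    state.y = rng.random(n)
    state.age = np.zeros(n, dtype=np.int64)
    state.ids = np.arange(n, dtype=np.int64)
    state.phenotype = np.zeros(n)
    state.genomes = [state.genomes[0]] * n
    state.allele_ids = [state.allele_ids[0]] * n
    return state


class TestCompetition:
    def test_kernel_values(self):
        sp = 0.02
        assert competition_kernel(0.0, sp) == 1.0
        assert competition_kernel(sp, sp) == pytest.approx(math.exp(-0.5))
        assert competition_kernel(3 * sp, sp) == 0.0  # beyond the cutoff
        with pytest.raises(ValueError):
            competition_kernel(0.1, 0.0)

    def test_isolated_and_coincident(self, landscape64, small_cfg):
        st = _uniform_state(landscape64, small_cfg, 1)
        assert total_competition(st)[0] == 0.0
        st2 = _uniform_state(landscape64, small_cfg, 2)
        st2.x = np.array([0.5, 0.5])
        st2.y = np.array([0.5, 0.5])
        np.testing.assert_allclose(total_competition(st2), [1.0, 1.0])

    def test_indexed_matches_bruteforce(self, landscape64, small_cfg, rng):
        st = _uniform_state(landscape64, small_cfg, 200)
        # cluster some points so the cutoff actually bites
        st.x[:50] = (0.5 + 0.01 * rng.standard_normal(50)) % 1
        indexed = total_competition(st)
        naive = total_competition_bruteforce(st.positions(), small_cfg.sigma_p)
        np.testing.assert_allclose(indexed, naive, atol=1e-12)


class TestSigmaBSchedule:
    def test_endpoints_and_plateau(self):
        assert sigma_b_schedule(10_000, 10_000) == 1.0
        assert sigma_b_schedule(20_000, 10_000) == 1.0
        assert sigma_b_schedule(5_000, 10_000, sigma_b0=0.1) == pytest.approx(0.55)
        assert sigma_b_schedule(0, 10_000, sigma_b0=0.1) == pytest.approx(0.1)

    def test_monotone_nondecreasing(self):
        vals = [sigma_b_schedule(g, 1000) for g in range(0, 2000, 37)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestFitness:
    def test_perfect_match_at_capacity_density(self):
        cfg = SimConfig(K=500)
        cap = 2 * math.pi * cfg.sigma_p**2 * cfg.K
        w = fitness(1.3, 1.3, C=cap, sigma_b=1.0, cfg=cfg)
        assert w == pytest.approx(1.0)

    @pytest.mark.parametrize("sigma_b", [0.1, 0.5, 1.0])
    def test_matching_component_is_one_at_match(self, sigma_b):
        assert matching_component(2.0, 2.0, sigma_b, 0.5) == 1.0

    def test_monotone_in_competition_and_mismatch(self):
        cfg = SimConfig(K=500)
        cap = 2 * math.pi * cfg.sigma_p**2 * cfg.K
        Cs = cap * np.linspace(1, 5, 20)
        w = fitness(0.0, 0.0, Cs, 1.0, cfg)
        assert np.all(np.diff(w) < 0)
        devs = np.linspace(0, 3, 20)
        w2 = fitness(devs, 0.0, cap, 1.0, cfg)
        assert np.all(np.diff(w2) < 0)

    def test_zero_competition_factor_is_one(self):
        cfg = SimConfig(K=500)
        w = fitness(0.5, 0.0, C=0.0, sigma_b=1.0, cfg=cfg)
        assert w == pytest.approx(matching_component(0.5, 0.0, 1.0, cfg.sigma_f))

    def test_destroyed_habitat_is_lethal(self):
        cfg = SimConfig(K=500)
        w = fitness(np.array([0.0]), np.array([0.0]), np.array([1.0]), 1.0, cfg,
                    destroyed=np.array([True]))
        assert w[0] == 0.0

    def test_invalid_sigma_f(self):
        with pytest.raises(ValueError):
            matching_component(0.0, 0.0, 1.0, 0.0)


class TestMateChoice:
    def test_no_neighbor_in_range(self, landscape64, small_cfg):
        st = _uniform_state(landscape64, small_cfg, 2)
        st.x = np.array([0.1, 0.5])
        st.y = np.array([0.1, 0.5])
        assert select_mate(st, 0) is None

    def test_nearest_is_chosen(self, landscape64, small_cfg):
        sp = small_cfg.sigma_p
        st = _uniform_state(landscape64, small_cfg, 3)
        st.x = np.array([0.5, 0.5 + sp, 0.5 + 2 * sp])
        st.y = np.array([0.5, 0.5, 0.5])
        assert select_mate(st, 0) == 1

    def test_exact_tie_breaks_to_lowest_id(self, landscape64, small_cfg):
        sp = small_cfg.sigma_p
        st = _uniform_state(landscape64, small_cfg, 3)
        st.x = np.array([0.5, 0.5 - sp, 0.5 + sp])
        st.y = np.array([0.5, 0.5, 0.5])
        st.ids = np.array([10, 7, 3])
        assert select_mate(st, 0) == 2  # id 3 < id 7 at equal distance
        st.ids = np.array([10, 2, 3])
        assert select_mate(st, 0) == 1


class TestStepGeneration:
    def test_empty_population_stays_empty(self, landscape64, small_cfg):
        st = _uniform_state(landscape64, small_cfg, 0)
        step_generation(st, small_cfg)
        assert st.n == 0 and st.generation == 1

    def test_offspring_at_parent1_position_and_poisson_counts(self, landscape64):
        """With survival forced to 1 (huge K, flat selection), one generation
        adds Poisson(lambda_0) offspring per mating individual, each at an
        existing parent position."""
        cfg = SimConfig(K=10**9, sigma_p=0.05, sigma_f=100.0, lambda_0=0.45, burn_in=0)
        st = _uniform_state(landscape64, cfg, 1000, seed=3)
        before = set(zip(st.x.tolist(), st.y.tolist()))
        n_before = st.n
        step_generation(st, cfg)
        births = st.n - n_before
        # everyone has a mate w.h.p.; mean births = N * lambda_0, 3 SE band
        expect = n_before * cfg.lambda_0
        assert births > 0
        assert abs(births - expect) < 3 * math.sqrt(expect)
        # flat fitness => habitat-choice candidates are never strictly better,
        # so newborns sit exactly on their parent-1 positions
        newborn_pos = set(zip(st.x[st.age == 1].tolist(), st.y[st.age == 1].tolist()))
        assert newborn_pos <= before

    def test_trajectory_is_deterministic(self, landscape64, small_cfg):
        runs = []
        for _ in range(2):
            st = _uniform_state(landscape64, small_cfg, 300, seed=9)
            sizes = []
            for _ in range(50):
                step_generation(st, small_cfg)
                sizes.append(st.n)
            runs.append(sizes)
        assert runs[0] == runs[1]

    def test_age_cap_holds_over_long_run(self, landscape64, small_cfg):
        st = _uniform_state(landscape64, small_cfg, 300, seed=5)
        max_age = 0
        for _ in range(200):
            step_generation(st, small_cfg)
            if st.n:
                max_age = max(max_age, int(st.age.max()))
        assert max_age <= small_cfg.max_age

    def test_habitat_choice_respects_destroyed_cells(self, landscape64, small_cfg):
        scenario = generate_loss_map(0.1, 0.5, 64, 3)
        st = _uniform_state(landscape64, small_cfg, 300, seed=7)
        apply_habitat_loss(st, scenario)
        for _ in range(20):
            step_generation(st, small_cfg)
            if st.n == 0:
                break
            assert not scenario.destroyed_at(st.x, st.y).any()

    def test_displacement_bounded_by_perception(self, landscape64, small_cfg):
        st = _uniform_state(landscape64, small_cfg, 300, seed=8)
        for _ in range(5):
            step_generation(st, small_cfg)
            assert st.last_mean_displacement <= small_cfg.sigma_p * math.sqrt(2) + 1e-12


class TestBurnIn:
    def test_initial_population_has_no_alleles(self, landscape64, small_cfg, rng):
        st = init_population(landscape64, small_cfg, rng)
        assert st.n == small_cfg.K
        assert st.registry.n_segregating() == 0
        assert np.all(st.phenotype == 0.0)

    def test_local_adaptation_emerges(self, burned_state):
        corr = np.corrcoef(burned_state.phenotype, burned_state.env_values())[0, 1]
        assert corr > 0.3

    def test_population_regulated_near_capacity(self, burned_state, small_cfg):
        assert 0.5 * small_cfg.K <= burned_state.n <= 1.5 * small_cfg.K

    def test_extinction_raises_burn_in_error(self, landscape64):
        # far below the mate-finding density threshold at this sigma_p
        cfg = SimConfig(K=20, sigma_p=0.02, burn_in=200)
        with pytest.raises(BurnInExtinctionError):
            run_burn_in(landscape64, cfg, seed=1)

    def test_phenotype_cache_matches_recomputation(self, burned_state):
        reg = burned_state.registry
        for i in range(0, burned_state.n, max(1, burned_state.n // 25)):
            assert burned_state.phenotype[i] == pytest.approx(
                phenotype_of(burned_state.genomes[i], reg), abs=1e-12
            )

    def test_mutation_freeze_after_burn_in(self, burned_state, small_cfg):
        st = burned_state.clone(seed=123)
        n_registered = len(st.registry)
        seg = [st.registry.n_segregating()]
        for _ in range(50):
            step_generation(st, small_cfg)
            seg.append(st.registry.n_segregating())
        assert len(st.registry) == n_registered  # no new alleles
        assert all(b <= a for a, b in zip(seg, seg[1:]))  # loss only


class TestHabitatLossAndScenarios:
    def test_no_loss_keeps_population(self, burned_state):
        st = burned_state.clone(seed=1)
        n0 = st.n
        apply_habitat_loss(st, no_loss_scenario(64))
        assert st.n == n0

    def test_total_loss_means_extinction(self, burned_state):
        st = burned_state.clone(seed=2)
        grid = np.ones((64, 64), dtype=np.int8)
        apply_habitat_loss(st, LossScenario(loss_grid=grid, l_hl=0.1, p_l=0.99, seed=0))
        assert st.n == 0

    def test_removed_fraction_tracks_occupied_loss(self, burned_state):
        """Fraction of individuals removed ~ fraction of occupied cells lost."""
        ratios = []
        for seed in range(5):
            st = burned_state.clone(seed=seed)
            sc = generate_loss_map(0.08, 2 / 3, 64, 100 + seed)
            occupied_lost = sc.destroyed_at(st.x, st.y).mean()
            n0 = st.n
            apply_habitat_loss(st, sc)
            ratios.append((1 - st.n / n0) - occupied_lost)
        assert max(abs(r) for r in ratios) < 1e-12  # removal is exact by construction

    def test_control_run_persists(self, burned_state, small_cfg):
        traj = run_scenario(burned_state, no_loss_scenario(64), small_cfg, seed=5, delta_e=0.0)
        assert traj["n_alive"].iloc[-1] > 0
        assert len(traj) == traj.attrs["horizon"] + 1

    def test_trajectory_length_contract(self, burned_state, small_cfg):
        sc = generate_loss_map(0.08, 2 / 3, 64, 9)
        traj = run_scenario(burned_state, sc, small_cfg, seed=6, delta_e=3.0)
        assert len(traj) <= small_cfg.change_duration + small_cfg.post_change + 1
        if len(traj) < small_cfg.change_duration + small_cfg.post_change + 1:
            assert traj["n_alive"].iloc[-1] == 0

    def test_extreme_stress_causes_extinction(self, burned_state):
        cfg = SimConfig(K=400, burn_in=300, sigma_f=0.05, delta_e=10.0)
        sc = generate_loss_map(0.08, 2 / 3, 64, 10)
        traj = run_scenario(burned_state, sc, cfg, seed=7, delta_e=10.0)
        assert traj["n_alive"].iloc[-1] == 0
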