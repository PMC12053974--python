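import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paddyfield.engine import (
    ObjectiveError,
    Plant,
    RunnerConfig,
    TrialState,
    adaptive_radius,
    check_termination,
    count_neighbors,
    disperse,
    pollinate,
    pollination_factor,
    run_trial,
    seed_count,
    select_plants,
)
from paddyfield.param_space import ParameterSpec


def make_state(fitnesses, threshold=2, mode="population", iteration=0,
               generations=None):
    config = RunnerConfig(
        n_random_seeds=len(fitnesses), threshold=threshold, s_max=10,
        radius=0.1, iterations=10, mode=mode,
    )
    gens = generations or [0] * len(fitnesses)
    plants = [
        Plant(id=i, params=np.array([float(i)]), fitness=f, generation=g)
        for i, (f, g) in enumerate(zip(fitnesses, gens))
    ]
    return TrialState(
        config=config,
        specs=[ParameterSpec(name="x")],
        population=plants,
        current_iteration=iteration,
    )


class TestSelection:
    def test_top_k_sorted_ascending(self):
        sel = select_plants(make_state([1.0, 3.0, 2.0], threshold=2))
        assert [p.fitness for p in sel.selected] == [2.0, 3.0]
        assert sel.pivot_fitness == 2.0
        assert sel.best_fitness == 3.0

    def test_initiation_fallback_75_percent(self):
        sel = select_plants(make_state([1.0, 2.0, 3.0], threshold=5))
        assert len(sel.selected) == 2  # round(0.75 * 3)

    def test_generational_mode_excludes_older_generations(self):
        state = make_state(
            [9.0, 1.0, 2.0], threshold=2, mode="generational",
            iteration=1, generations=[0, 1, 1],
        )
        sel = select_plants(state)
        assert {p.fitness for p in sel.selected} == {1.0, 2.0}

    def test_fitness_ties_break_toward_older_plant(self):
        sel = select_plants(make_state([5.0, 5.0, 5.0], threshold=2))
        assert [p.id for p in sel.selected] == [1, 0]

    def test_matches_full_sort_oracle_on_random_pools(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            n = int(rng.integers(1, 100))
            k = int(rng.integers(1, 30))
            fits = rng.normal(size=n).round(2).tolist()  # rounding forces ties
            state = make_state(fits, threshold=k)
            sel = select_plants(state)
            from paddyfield.param_space import round_half_away

            expected_k = k if n >= k else max(1, int(round_half_away(0.75 * n)))
            oracle = sorted(
                state.population, key=lambda p: (-p.fitness, p.id)
            )[:expected_k]
            assert [p.id for p in sel.selected] == [p.id for p in oracle[::-1]]


class TestSeeding:
    @pytest.mark.parametrize(
        "y,pivot,best,s_max,expected",
        [(2.0, 0.0, 2.0, 100, 100.0), (0.0, 0.0, 2.0, 100, 0.0),
         (1.0, 0.0, 2.0, 100, 50.0)],
    )
    def test_normalized_seed_counts(self, y, pivot, best, s_max, expected):
        assert seed_count(y, pivot, best, s_max) == expected

    def test_degenerate_range_raises(self):
        with pytest.raises(ZeroDivisionError):
            seed_count(1.0, 1.0, 1.0, 10)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=10))
    @settings(derandomize=True, max_examples=50)
    def test_monotone_and_bounded(self, ys):
        pivot, best = min(ys), max(ys)
        if best - pivot < 1e-9:
            return
        s = sorted(seed_count(y, pivot, best, 25) for y in ys)
        assert all(0 <= v <= 25 for v in s)
        assert s == sorted(s)


class TestNeighbors:
    def test_single_plant_has_no_neighbors(self):
        assert count_neighbors(np.array([[0.5, 0.5]]), 0.1).tolist() == [0]

    def test_close_pair_counts_each_other(self):
        X = np.array([[0.0, 0.0], [0.01, 0.0]])
        assert count_neighbors(X, 0.02).tolist() == [1, 1]

    def test_exact_radius_is_not_a_neighbor(self):
        X = np.array([[0.0], [0.02]])
        assert count_neighbors(X, 0.02).tolist() == [0, 0]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(2, 30))
            d = int(rng.integers(1, 4))
            X = rng.uniform(size=(n, d))
            r = float(rng.uniform(0.01, 1.0))
            expected = [
                sum(
                    1
                    for k in range(n)
                    if k != j and np.linalg.norm(X[j] - X[k]) < r
                )
                for j in range(n)
            ]
            assert count_neighbors(X, r).tolist() == expected


class TestAdaptiveRadius:
    def test_user_radius_kept_when_it_works(self):
        X = np.array([[0.0], [0.01]])
        counts, r, fallback = adaptive_radius(X, 0.02)
        assert counts.tolist() == [1, 1] and r == 0.02 and not fallback

    def test_quantile_fallback_assigns_neighbors(self):
        X = np.array([[0.0], [10.0], [25.0]])  # pair distances 10, 15, 25
        counts, r, fallback = adaptive_radius(X, 0.02)
        assert fallback
        assert counts.sum() >= 1
        # 0.75 quantile of the ordered-pair multiset {10,10,15,15,25,25}
        assert r == pytest.approx(
            np.quantile([10, 10, 15, 15, 25, 25], 0.75)
        )

    def test_single_plant_gets_unit_neighbor(self):
        counts, _, fallback = adaptive_radius(np.array([[0.3, 0.3]]), 0.02)
        assert counts.tolist() == [1] and fallback

    def test_identical_points_never_need_fallback(self):
        X = np.zeros((3, 2))
        counts, _, fallback = adaptive_radius(X, 0.02)
        assert counts.tolist() == [2, 2, 2] and not fallback


class TestPollination:
    def test_endpoint_values(self):
        assert pollination_factor(0, 4) == pytest.approx(math.exp(-1))
        assert pollination_factor(4, 4) == 1.0
        assert pollination_factor(1, 2) == pytest.approx(math.exp(-0.5))

    def test_invalid_counts_raise(self):
        with pytest.raises(ValueError):
            pollination_factor(3, 2)
        with pytest.raises(ValueError):
            pollination_factor(0, 0)

    def test_monotone_in_neighbor_count(self):
        values = [pollination_factor(nu, 10) for nu in range(11)]
        assert values == sorted(values)
        assert all(math.exp(-1) <= v <= 1.0 for v in values)

    def _selection(self, fitnesses):
        plants = [
            Plant(id=i, params=np.array([0.1 * i]), fitness=f)
            for i, f in enumerate(fitnesses)
        ]
        from paddyfield.engine import SelectionResult

        return SelectionResult(
            selected=plants,
            pivot_fitness=fitnesses[0],
            best_fitness=fitnesses[-1],
        )

    def test_full_density_gives_full_seed_count(self):
        sel = self._selection([0.0, 1.0])
        plan = pollinate(sel, [1, 1], s_max=10, effective_radius=0.1,
                         radius_fallback=False)
        assert plan.n_children == [0, 10]  # pivot 0 seeds, best U=1

    def test_isolated_plant_penalized(self):
        sel = self._selection([0.0, 0.5, 1.0])
        plan = pollinate(sel, [1, 0, 1], s_max=10, effective_radius=0.1,
                         radius_fallback=False)
        # middle plant: s = 5, U = e^-1 -> round(1.84) = 2
        assert plan.n_children[1] == 2

    def test_best_plant_always_emits_a_child(self):
        sel = self._selection([0.0, 1e-15 if False else 1.0])
        plan = pollinate(sel, [0, 1], s_max=1, effective_radius=0.1,
                         radius_fallback=False)
        assert plan.n_children[-1] >= 1

    def test_children_never_exceed_rounded_seed_count(self):
        sel = self._selection([0.0, 0.3, 0.7, 1.0])
        plan = pollinate(sel, [2, 1, 0, 2], s_max=25, effective_radius=0.1,
                         radius_fallback=False)
        for s, n in zip(plan.s_raw, plan.n_children):
            assert n <= max(1, round(s + 0.5))
        assert all(
            math.exp(-1) - 1e-12 <= u <= 1.0 for u in plan.pollination_factor
        )


class TestDispersion:
    def test_zero_children_empty(self, unit_specs, rng):
        parent = Plant(id=0, params=np.array([0.5, 0.5]), fitness=1.0)
        assert disperse(parent, 0, unit_specs, "default", rng) == []

    def test_children_respect_limits_and_integrality(self, rng):
        specs = [
            ParameterSpec(name="c", lower=0.0, upper=1.0),
            ParameterSpec(name="k", kind="integer", lower=0.0, upper=5.0),
        ]
        parent = Plant(id=0, params=np.array([0.9, 4.0]), fitness=1.0)
        for params, _ in disperse(parent, 200, specs, "default", rng):
            assert 0.0 <= params[0] <= 1.0
            assert params[1] in range(6)

    def test_scaled_mode_width_follows_delta(self, unit_specs):
        # delta ~ 1 gives sigma ~ 1e-7: children glued to the parent
        parent = Plant(
            id=0, params=np.array([0.5, 0.5]), fitness=1.0, delta=1.0
        )
        rng = np.random.default_rng(0)
        kids = disperse(parent, 50, unit_specs, "scaled", rng)
        spread = np.array([p for p, _ in kids]).std(axis=0)
        assert np.all(spread < 1e-4)
        # default mode from the same parent is much wider
        rng = np.random.default_rng(0)
        kids = disperse(parent, 50, unit_specs, "default", rng)
        spread = np.array([p for p, _ in kids]).std(axis=0)
        assert np.all(spread > 0.05)

    def test_normalized_dispersal_scales_with_limits(self):
        # sigma 0.2 in normalized space = 0.2 * span in raw units
        wide = ParameterSpec(name="w", lower=0.0, upper=1000.0, normalize=True)
        parent = Plant(id=0, params=np.array([500.0]), fitness=1.0)
        rng = np.random.default_rng(3)
        kids = disperse(parent, 300, [wide], "default", rng)
        spread = np.array([p for p, _ in kids]).std()
        assert 100 < spread < 300  # ~0.2 * 1000 modulo clamping


class TestTermination:
    def test_converged_when_pivot_equals_best(self):
        state = make_state([2.0, 2.0], threshold=2)
        sel = select_plants(state)
        assert check_termination(sel, state) == "converged_yt_equals_ymax"

    def test_none_when_fitness_spread_and_budget_remain(self):
        state = make_state([1.0, 2.0], threshold=2)
        assert check_termination(select_plants(state), state) is None

    def test_budget_exhaustion(self):
        state = make_state([1.0, 2.0], threshold=2, iteration=10)
        sel = select_plants(state)
        assert check_termination(sel, state) == "iterations_exhausted"


class TestRunTrial:
    def sphere(self, v):
        return -float(np.sum((v - 0.5) ** 2))

    def test_zero_iterations_returns_best_of_sow(self, unit_specs):
        config = RunnerConfig(n_random_seeds=10, threshold=5, s_max=5,
                              radius=0.05, iterations=0, rng_seed=1)
        state = run_trial(self.sphere, unit_specs, config)
        assert len(state.population) == 10
        assert state.termination_reason == "iterations_exhausted"
        assert state.best.fitness == max(p.fitness for p in state.population)

    def test_same_seed_reproduces_full_trajectory(self, unit_specs):
        config = RunnerConfig(n_random_seeds=10, threshold=5, s_max=10,
                              radius=0.05, iterations=3, rng_seed=42)
        a = run_trial(self.sphere, unit_specs, config)
        b = run_trial(self.sphere, unit_specs, config)
        assert len(a.population) == len(b.population)
        for pa, pb in zip(a.population, b.population):
            assert pa.fitness == pb.fitness
            np.testing.assert_array_equal(pa.params, pb.params)

    def test_evaluation_count_matches_iteration_log(self, unit_specs):
        config = RunnerConfig(n_random_seeds=12, threshold=6, s_max=8,
                              radius=0.05, iterations=4, rng_seed=3)
        state = run_trial(self.sphere, unit_specs, config)
        total = config.n_random_seeds + sum(
            rec["children"] for rec in state.iteration_log
        )
        assert len(state.population) == total

    def test_population_mode_best_is_monotone(self, unit_specs):
        config = RunnerConfig(n_random_seeds=15, threshold=5, s_max=10,
                              radius=0.05, iterations=5, mode="population",
                              rng_seed=11)
        state = run_trial(self.sphere, unit_specs, config)
        best_by_gen = []
        running = -math.inf
        for g in range(state.current_iteration + 1):
            plants = state.plants_of_generation(g)
            if plants:
                running = max(running, max(p.fitness for p in plants))
            best_by_gen.append(running)
        assert best_by_gen == sorted(best_by_gen)

    def test_every_plant_respects_limits(self, unit_specs):
        config = RunnerConfig(n_random_seeds=10, threshold=5, s_max=10,
                              radius=0.05, iterations=3, rng_seed=8)
        state = run_trial(self.sphere, unit_specs, config)
        for p in state.population:
            assert np.all(p.params >= 0.0) and np.all(p.params <= 1.0)

    def test_generation_zero_has_no_parents(self, unit_specs):
        config = RunnerConfig(n_random_seeds=5, threshold=3, s_max=5,
                              radius=0.05, iterations=2, rng_seed=9)
        state = run_trial(self.sphere, unit_specs, config)
        for p in state.population:
            assert (p.generation == 0) == (p.parent_id is None)

    def test_constant_objective_converges_immediately(self, unit_specs):
        config = RunnerConfig(n_random_seeds=10, threshold=5, s_max=5,
                              radius=0.05, iterations=5, rng_seed=2)
        state = run_trial(lambda v: 1.0, unit_specs, config)
        assert state.termination_reason == "converged_yt_equals_ymax"
        assert len(state.population) == 10

    def test_nan_fitness_rejected_with_context(self, unit_specs):
        config = RunnerConfig(n_random_seeds=3, threshold=2, s_max=5,
                              radius=0.05, iterations=1, rng_seed=1)
        with pytest.raises(ObjectiveError, match="non-finite"):
            run_trial(lambda v: float("nan"), unit_specs, config)

    def test_objective_exception_carries_plant_context(self, unit_specs):
        config = RunnerConfig(n_random_seeds=3, threshold=2, s_max=5,
                              radius=0.05, iterations=1, rng_seed=1)

        def bad(v):
            raise RuntimeError("boom")

        with pytest.raises(ObjectiveError, match="x="):
            run_trial(bad, unit_specs, config)


class TestRunnerConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(threshold=0), dict(n_random_seeds=0), dict(s_max=0),
         dict(radius=0.0), dict(mode="other"), dict(gaussian="other")],
    )
    def test_invalid_fields_rejected(self, kwargs):
        with pytest.raises(ValueError):
            RunnerConfig(**kwargs)

    def test_unknown_key_rejected_by_name(self):
        with pytest.raises(ValueError, match="bogus"):
            RunnerConfig.from_dict({"bogus": 1})
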