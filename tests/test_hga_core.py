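"""Genetic operators, local refinement and full hybrid-GA runs."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from hgaopt import (
    BoundedProblem,
    Candidate,
    HGAConfig,
    QuadraticResponseModel,
    case_study,
    crossover,
    initialize_population,
    local_refine,
    mutate,
    roulette_select,
    run_hga,
    selection_scores,
    step_generation,
)


def unit_problem(d=1):
    """Trivial quadratic on [0, 1]^d (used to probe sampling distributions)."""
    model = QuadraticResponseModel(0.0, np.zeros(d), np.zeros(d))
    return BoundedProblem(
        name="unit", objective=model, goal="maximize",
        coded_box=np.tile([0.0, 1.0], (d, 1)),
    )


class TestInitialization:
    def test_bounds_and_size(self):
        problem = case_study("anthocyanin")
        pop = initialize_population(problem, HGAConfig(), np.random.default_rng(0))
        assert len(pop) == 100
        G = np.stack([c.genome for c in pop])
        assert np.all(G >= -1.0) and np.all(G <= 1.0)
        assert all(math.isfinite(c.fitness) for c in pop)

    def test_same_seed_same_population(self):
        problem = case_study("fame")
        a = initialize_population(problem, HGAConfig(), np.random.default_rng(11))
        b = initialize_population(problem, HGAConfig(), np.random.default_rng(11))
        assert all(np.array_equal(x.genome, y.genome) for x, y in zip(a, b))

    def test_coordinates_uniform(self):
        cfg = HGAConfig(population_size=10_000)
        pop = initialize_population(unit_problem(), cfg, np.random.default_rng(5))
        coords = np.array([c.genome[0] for c in pop])
        assert stats.kstest(coords, "uniform").pvalue > 0.01


class TestSelection:
    def test_scores_monotone_toward_goal(self):
        cfg = HGAConfig()
        pop = [Candidate(np.zeros(1), 1.0), Candidate(np.zeros(1), 3.0)]
        s_max = selection_scores(pop, "maximize", cfg)
        assert s_max[1] > s_max[0]
        s_min = selection_scores(pop, "minimize", cfg)
        assert s_min[0] > s_min[1]
        assert s_max.sum() == pytest.approx(1.0) and np.all(s_max >= 0)

    def test_identical_fitness_uniform(self):
        pop = [Candidate(np.zeros(1), 2.0) for _ in range(4)]
        assert np.allclose(selection_scores(pop, "maximize", HGAConfig()), 0.25)

    def test_ackley_origin_preferred_when_minimizing(self):
        problem = case_study("ackley")
        pop = [
            Candidate(np.zeros(2), float(problem.evaluate(np.zeros(2)))),
            Candidate(np.array([10.0, 10.0]), float(problem.evaluate([10.0, 10.0]))),
        ]
        s = selection_scores(pop, "minimize", HGAConfig())
        assert s[0] > s[1]

    def test_response_band_penalty_reorders_scores(self):
        # candidate 1 has higher raw fitness but violates the response band
        cfg = HGAConfig(response_bounds=(None, 2.0), constraint_weights=[10.0])
        pop = [Candidate(np.zeros(1), 1.9), Candidate(np.zeros(1), 2.5)]
        s = selection_scores(pop, "maximize", cfg)
        assert s[0] > s[1]

    def test_roulette_degenerate_wheel(self):
        pop = [Candidate(np.array([1.0]), 1.0), Candidate(np.array([2.0]), 2.0)]
        rng = np.random.default_rng(0)
        for _ in range(50):
            assert roulette_select(pop, np.array([1.0, 0.0]), rng) is pop[0]

    def test_roulette_frequencies_match_scores(self):
        pop = [Candidate(np.array([float(i)]), float(i)) for i in range(3)]
        scores = np.array([0.7, 0.2, 0.1])
        rng = np.random.default_rng(123)
        n = 10_000
        counts = np.zeros(3)
        for _ in range(n):
            counts[int(roulette_select(pop, scores, rng).genome[0])] += 1
        freq = counts / n
        sigma = np.sqrt(scores * (1 - scores) / n)
        assert np.all(np.abs(freq - scores) <= 3 * sigma + 1e-9)

    def test_roulette_even_wheel(self):
        pop = [Candidate(np.array([0.0]), 0.0), Candidate(np.array([1.0]), 1.0)]
        rng = np.random.default_rng(9)
        hits = sum(
            roulette_select(pop, np.array([0.5, 0.5]), rng) is pop[1]
            for _ in range(10_000)
        )
        assert abs(hits / 10_000 - 0.5) < 0.02


class TestCrossoverMutation:
    def test_identical_parents_fixed_point(self):
        g = np.array([0.3, -0.7])
        child = crossover(Candidate(g.copy()), Candidate(g.copy()), np.random.default_rng(0))
        assert np.allclose(child.genome, g)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimensionality"):
            crossover(Candidate(np.zeros(2)), Candidate(np.zeros(3)), np.random.default_rng(0))

    @settings(deadline=None, max_examples=200)
    @given(st.integers(0, 2**31 - 1))
    def test_child_coordinatewise_between_parents(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(-5, 5, size=4)
        b = rng.uniform(-5, 5, size=4)
        child = crossover(Candidate(a), Candidate(b), rng).genome
        assert np.all(child >= np.minimum(a, b) - 1e-12)
        assert np.all(child <= np.maximum(a, b) + 1e-12)

    def test_mutation_stays_in_box_and_uniform(self):
        box = np.array([[-2.0, 3.0]])
        rng = np.random.default_rng(21)
        draws = np.array(
            [mutate(Candidate(np.array([0.0]), 1.0), box, rng).genome[0] for _ in range(5000)]
        )
        assert np.all(draws >= -2.0) and np.all(draws <= 3.0)
        assert stats.kstest((draws + 2.0) / 5.0, "uniform").pvalue > 0.01

    def test_mutation_resets_fitness_and_refined(self):
        out = mutate(
            Candidate(np.array([0.0]), 1.0, refined=True),
            np.array([[0.0, 1.0]]),
            np.random.default_rng(0),
        )
        assert math.isnan(out.fitness) and not out.refined


class TestLocalRefine:
    def test_parabola_vertex(self, parabola_1d):
        cfg = HGAConfig()
        start = Candidate(np.array([0.9]))
        out = local_refine(parabola_1d, start, cfg)
        assert out.genome[0] == pytest.approx(0.3, abs=1e-5)
        assert out.fitness == pytest.approx(0.0, abs=1e-9)
        assert out.refined

    def test_anthocyanin_refines_to_stationary_ph(self):
        problem = case_study("anthocyanin")
        cfg = HGAConfig(refine_max_evals=2000)
        start_genome = np.array([-1.0, -1.0, 1.0, -0.4])
        start = Candidate(start_genome, float(problem.evaluate(start_genome)))
        out = local_refine(problem, start, cfg)
        assert out.fitness >= start.fitness
        assert out.genome[3] == pytest.approx(-0.5186, abs=0.005)

    def test_ackley_central_basin_to_near_zero(self):
        problem = case_study("ackley")
        cfg = HGAConfig(refine_min_step=1e-14, refine_max_evals=5000)
        g = np.array([0.1, 0.1])
        out = local_refine(problem, Candidate(g, float(problem.evaluate(g))), cfg)
        assert out.fitness < 1e-12

    @pytest.mark.parametrize("name", ["ackley", "anthocyanin", "fame", "xylanase"])
    def test_never_worsens_over_random_starts(self, name, problems):
        problem = problems[name]
        cfg = HGAConfig(refine_max_evals=40)
        rng = np.random.default_rng(8)
        lo, hi = problem.coded_box[:, 0], problem.coded_box[:, 1]
        n = 1000
        G = rng.uniform(lo, hi, size=(n, problem.d))
        F = np.atleast_1d(problem.evaluate(G))
        sign = 1.0 if problem.maximize else -1.0
        for g, f in zip(G, F):
            out = local_refine(problem, Candidate(g, float(f)), cfg)
            assert sign * (out.fitness - f) >= 0.0
            assert np.all(out.genome >= lo) and np.all(out.genome <= hi)


class TestStepGeneration:
    def test_elite_count_and_preservation(self):
        problem = case_study("anthocyanin")
        cfg = HGAConfig(refine_max_evals=30)
        rng = np.random.default_rng(2)
        pop = initialize_population(problem, cfg, rng)
        best_before = max(c.fitness for c in pop)
        elite_genomes = sorted(pop, key=lambda c: -c.fitness)[:10]
        new_pop, stats_ = step_generation(pop, problem, cfg, rng)
        assert len(new_pop) == 100
        for i, e in enumerate(elite_genomes):
            assert np.array_equal(new_pop[i].genome, e.genome)
        assert stats_.best_fitness >= best_before

    def test_operator_bypass_resamples_parents(self):
        problem = case_study("fame")
        cfg = HGAConfig(
            population_size=30, crossover_rate=0.0, mutation_rate=0.0, refine_fraction=0.0
        )
        rng = np.random.default_rng(4)
        pop = initialize_population(problem, cfg, rng)
        genomes = {tuple(c.genome) for c in pop}
        new_pop, stats_ = step_generation(pop, problem, cfg, rng)
        assert all(tuple(c.genome) in genomes for c in new_pop)
        assert stats_.best_fitness == max(c.fitness for c in pop)

    def test_best_never_worsens_when_minimizing(self):
        problem = case_study("ackley")
        cfg = HGAConfig(population_size=30, refine_max_evals=50)
        rng = np.random.default_rng(17)
        pop = initialize_population(problem, cfg, rng)
        best = min(c.fitness for c in pop)
        for _ in range(5):
            pop, stats_ = step_generation(pop, problem, cfg, rng)
            assert stats_.best_fitness <= best + 1e-15
            best = min(best, stats_.best_fitness)


class TestRunHGA:
    def test_seed_determinism_bitwise(self):
        problem = case_study("fame")
        cfg = HGAConfig(population_size=30, generations=10, refine_max_evals=60, seed=99)
        a = run_hga(problem, cfg)
        b = run_hga(problem, cfg)
        assert a.best_fitness == b.best_fitness
        assert np.array_equal(a.best.genome, b.best.genome)
        assert len(a.history) == len(b.history)
        for sa, sb in zip(a.history, b.history):
            assert sa.best_fitness == sb.best_fitness
            assert sa.mean_fitness == sb.mean_fitness
            assert np.array_equal(sa.best_genome, sb.best_genome)
        assert a.evaluations == b.evaluations

    def test_anthocyanin_defaults_reach_reported_optimum(self):
        result = run_hga(case_study("anthocyanin"), HGAConfig(seed=1))
        assert result.best_fitness == pytest.approx(95.82, abs=0.01)
        assert result.best_natural[3] == pytest.approx(3.2407, abs=0.001)

    def test_tolerance_set_contract(self):
        problem = case_study("anthocyanin")
        cfg = HGAConfig(population_size=40, generations=15, tolerance=0.5, seed=3,
                        refine_max_evals=80)
        result = run_hga(problem, cfg)
        assert result.tolerance_set
        for c in result.tolerance_set:
            assert abs(c.fitness - result.best_fitness) <= 0.5

    def test_persistence_stops_early(self):
        problem = case_study("anthocyanin")
        cfg = HGAConfig(generations=100, persistence=3, tolerance=1e-9, seed=5,
                        population_size=30, refine_max_evals=100)
        result = run_hga(problem, cfg)
        assert len(result.history) - 1 < 100

    def test_history_best_monotone(self):
        result = run_hga(
            case_study("xylanase"),
            HGAConfig(population_size=30, generations=12, refine_max_evals=60, seed=7),
        )
        best = [st.best_fitness for st in result.history]
        assert all(b2 >= b1 - 1e-12 for b1, b2 in zip(best, best[1:]))
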