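"""Hybrid (memetic) genetic algorithm over a box-constrained problem.

The engine is a real-coded GA — roulette-wheel selection, per-coordinate
blend crossover, full-randomization mutation, elitism — whose offspring are
additionally pushed to a nearby local optimum each generation by an
adaptive-step steepest ascent/descent.  The GA supplies global exploration;
the deterministic refinement supplies exact local convergence, so the best
candidate of a run sits on a stationary point (or box face) of the objective
rather than merely near one.

All randomness flows through a single :class:`numpy.random.Generator`; runs
are bit-for-bit reproducible from the configured seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .rsm_models import BoundedProblem

__all__ = [
    "HGAConfig",
    "Candidate",
    "GenerationStats",
    "OptimizationResult",
    "initialize_population",
    "selection_scores",
    "roulette_select",
    "crossover",
    "mutate",
    "local_refine",
    "step_generation",
    "run_hga",
]


@dataclass(frozen=True)
class HGAConfig:
    """Run parameters for the hybrid genetic algorithm.

    The genetic-operator defaults are the standard rates used throughout the
    case studies: population 100, 100 generations, crossover 0.80, mutation
    0.01, elitism 0.10.  ``tolerance`` controls both the returned solution set
    (candidates within ``tolerance`` of the best) and, together with
    ``persistence``, early stopping: with ``persistence > 0`` a run halts once
    the best fitness has failed to improve by more than ``tolerance`` for that
    many consecutive generations.

    Refinement parameters govern the local search: the step starts at
    ``refine_initial_step`` times the widest box side, doubles
    (``refine_grow``) after an improving move, halves (``refine_shrink``)
    after a failed one, and the search stops when the step falls below
    ``refine_min_step`` (absolute, in optimization-space units) or after
    ``refine_max_evals`` objective evaluations for that candidate.

    ``response_bounds`` (with ``constraint_weights``) soft-constrains the
    objective value itself: deviation of the response from the stated band is
    multiplied by the weight and counted against a candidate during selection
    scoring, without discarding it.  ``objective_weights`` scalarize a
    multi-response problem into one fitness by weighted sum.
    """

    population_size: int = 100
    generations: int = 100
    crossover_rate: float = 0.80
    mutation_rate: float = 0.01
    elitism_rate: float = 0.10
    tolerance: float = 0.0
    persistence: int = 0
    refine_initial_step: float = 0.1
    refine_shrink: float = 0.5
    refine_grow: float = 2.0
    refine_min_step: float = 1e-12
    refine_max_evals: int = 500
    refine_fraction: float = 1.0
    seed: int = 0
    constraint_weights: Optional[Sequence[float]] = None
    objective_weights: Optional[Sequence[float]] = None
    response_bounds: Optional[Sequence[float]] = None  # (lower, upper); None = unbounded

    def __post_init__(self) -> None:
        if self.population_size < 1 or self.generations < 1:
            raise ValueError("population_size and generations must be positive")
        for name in ("crossover_rate", "mutation_rate", "elitism_rate", "refine_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.tolerance < 0 or self.persistence < 0:
            raise ValueError("tolerance and persistence must be non-negative")
        if not 0.0 < self.refine_shrink < 1.0:
            raise ValueError("refine_shrink must lie in (0, 1)")
        if self.refine_grow <= 1.0:
            raise ValueError("refine_grow must exceed 1")
        if self.refine_min_step < 0 or self.refine_max_evals < 1:
            raise ValueError("invalid refinement budget")


@dataclass
class Candidate:
    """One member of the population: a genome in optimization space plus its
    fitness.  ``refined`` marks genomes already sitting at a local-search
    fixed point, so unchanged copies are not re-refined."""

    genome: np.ndarray
    fitness: float = math.nan
    refined: bool = False

    def copy(self) -> "Candidate":
        return Candidate(self.genome.copy(), self.fitness, self.refined)


@dataclass(frozen=True)
class GenerationStats:
    generation_index: int
    best_fitness: float
    mean_fitness: float
    worst_fitness: float
    best_genome: np.ndarray


@dataclass(frozen=True)
class OptimizationResult:
    """Outcome of a hybrid-GA run."""

    best: Candidate
    best_natural: np.ndarray
    history: list
    tolerance_set: list
    evaluations: int
    seed: int
    problem_name: str = ""

    @property
    def best_fitness(self) -> float:
        return self.best.fitness

    def history_frame(self) -> pd.DataFrame:
        """Per-generation statistics as a DataFrame (one row per generation)."""
        rows = []
        for st in self.history:
            row = {
                "generation": st.generation_index,
                "best": st.best_fitness,
                "mean": st.mean_fitness,
                "worst": st.worst_fitness,
            }
            for i, v in enumerate(st.best_genome):
                row[f"x{i + 1}"] = v
            rows.append(row)
        return pd.DataFrame(rows)


class _CountingObjective:
    """Wraps problem evaluation, applying objective weights and counting calls."""

    def __init__(self, problem: BoundedProblem, config: HGAConfig) -> None:
        self.problem = problem
        self.weights = config.objective_weights
        self.count = 0

    def __call__(self, x) -> float:
        self.count += 1
        return float(self.problem.evaluate(x, objective_weights=self.weights))

    def batch(self, X: np.ndarray) -> np.ndarray:
        self.count += X.shape[0]
        return np.atleast_1d(
            self.problem.evaluate(X, objective_weights=self.weights)
        ).astype(float)

    def gradient(self, x) -> np.ndarray:
        # finite-difference gradients cost 2 evaluations per dimension
        if not all(
            type(o).__name__ == "QuadraticResponseModel" for o in self.problem.objectives
        ):
            self.count += 2 * self.problem.d
        return self.problem.gradient(x, objective_weights=self.weights)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _better(a: float, b: float, maximize: bool) -> bool:
    return a > b if maximize else a < b


def initialize_population(
    problem: BoundedProblem,
    config: HGAConfig,
    rng: np.random.Generator,
    objective: Optional[_CountingObjective] = None,
) -> list:
    """Draw ``population_size`` candidates uniformly inside the box and
    evaluate them."""
    box = problem.coded_box
    if not np.all(np.isfinite(box)):
        raise ValueError("initialization requires a finite box in every dimension")
    obj = objective or _CountingObjective(problem, config)
    genomes = rng.uniform(box[:, 0], box[:, 1], size=(config.population_size, problem.d))
    fitness = obj.batch(genomes)
    return [Candidate(g, f) for g, f in zip(genomes, fitness)]


def _penalized_fitness(fitness: np.ndarray, config: HGAConfig, maximize: bool) -> np.ndarray:
    """Fitness used for selection: raw fitness minus (maximize) or plus
    (minimize) the weighted deviation of the response from any stated band."""
    if config.response_bounds is None:
        return fitness
    lo, hi = config.response_bounds
    lo = -math.inf if lo is None else float(lo)
    hi = math.inf if hi is None else float(hi)
    violation = np.maximum(0.0, lo - fitness) + np.maximum(0.0, fitness - hi)
    w = 1.0 if not config.constraint_weights else float(config.constraint_weights[0])
    return fitness - w * violation if maximize else fitness + w * violation


def selection_scores(
    population: Sequence[Candidate], goal: str, config: HGAConfig
) -> np.ndarray:
    """Non-negative roulette weights, summing to one, monotone in (penalized)
    fitness toward the goal.

    Raw fitness is shifted to a non-negative score — ``f - min + eps`` when
    maximizing, ``max - f + eps`` when minimizing — with a small ``eps``
    relative to the population spread so the worst member retains a sliver of
    selection probability.  An all-identical population scores uniformly.
    """
    if len(population) == 0:
        raise ValueError("population must be non-empty")
    maximize = goal == "maximize"
    f = _penalized_fitness(
        np.array([c.fitness for c in population]), config, maximize
    )
    spread = float(np.max(f) - np.min(f))
    if spread == 0.0 or not math.isfinite(spread):
        return np.full(len(population), 1.0 / len(population))
    eps = 1e-6 * spread
    raw = (f - np.min(f) + eps) if maximize else (np.max(f) - f + eps)
    return raw / raw.sum()


def roulette_select(
    population: Sequence[Candidate], scores: np.ndarray, rng: np.random.Generator
) -> Candidate:
    """Sample one member with probability proportional to its score."""
    idx = _roulette_indices(len(population), scores, rng, 1)[0]
    return population[idx]


def _roulette_indices(
    n: int, scores: np.ndarray, rng: np.random.Generator, size: int
) -> np.ndarray:
    cum = np.cumsum(scores)
    cum /= cum[-1]
    return np.searchsorted(cum, rng.random(size), side="right").clip(0, n - 1)


def crossover(
    parent_a: Candidate, parent_b: Candidate, rng: np.random.Generator
) -> Candidate:
    """Blend (arithmetic) crossover: each child coordinate is an independent
    convex combination of the parents', so the child stays inside any box
    containing both parents.  Fitness is left unevaluated (NaN)."""
    a, b = parent_a.genome, parent_b.genome
    if a.shape != b.shape:
        raise ValueError("parents must share dimensionality")
    lam = rng.random(a.shape[0])
    return Candidate(lam * a + (1.0 - lam) * b)


def mutate(
    candidate: Candidate, box: np.ndarray, rng: np.random.Generator
) -> Candidate:
    """Full-randomization mutation: the genome is replaced by a fresh uniform
    draw within the box (the alleles are completely randomized).  Fitness is
    left unevaluated; callers must not pass the elite."""
    genome = rng.uniform(box[:, 0], box[:, 1])
    return Candidate(genome)


def local_refine(
    problem: BoundedProblem,
    candidate: Candidate,
    config: HGAConfig,
    objective: Optional[Callable] = None,
) -> Candidate:
    """Adaptive-step steepest ascent (maximize) / descent (minimize) from a
    candidate, projected onto the box.

    The move direction is the normalized (±)gradient — analytic for quadratic
    response models, central finite differences otherwise.  The step length
    starts at ``refine_initial_step`` times the widest box side, grows by
    ``refine_grow`` after each improving move (when the gradient is also
    refreshed) and shrinks by ``refine_shrink`` after a failed one (the
    direction is kept).  Terminates when the step drops below
    ``refine_min_step`` or the per-candidate evaluation budget is spent.  The
    returned candidate is never worse than the input; any non-finite objective
    value aborts the search and returns the input unchanged.
    """
    obj = objective or _CountingObjective(problem, config)
    maximize = problem.maximize
    box = problem.coded_box
    lo, hi = box[:, 0], box[:, 1]
    x = np.clip(candidate.genome.astype(float), lo, hi)
    f = candidate.fitness
    if not math.isfinite(f):
        f = obj(x)
        if not math.isfinite(f):
            return candidate
    start_f = f

    evals = 0
    budget = config.refine_max_evals
    step = config.refine_initial_step * float(np.max(hi - lo))
    sign = 1.0 if maximize else -1.0

    def direction(point: np.ndarray):
        g = obj.gradient(point) if hasattr(obj, "gradient") else problem.gradient(point)
        norm = float(np.linalg.norm(g))
        if norm == 0.0 or not math.isfinite(norm):
            return None
        return sign * g / norm

    d = direction(x)
    if hasattr(obj, "gradient") and not all(
        type(o).__name__ == "QuadraticResponseModel" for o in problem.objectives
    ):
        evals += 2 * problem.d
    if d is None:
        return Candidate(x, f, refined=True)

    grad_cost = (
        0
        if all(type(o).__name__ == "QuadraticResponseModel" for o in problem.objectives)
        else 2 * problem.d
    )

    while step >= config.refine_min_step and evals < budget:
        trial = np.clip(x + step * d, lo, hi)
        ft = obj(trial)
        evals += 1
        if not math.isfinite(ft):
            break
        if _better(ft, f, maximize):
            x, f = trial, ft
            step *= config.refine_grow
            d = direction(x)
            evals += grad_cost
            if d is None:
                break
        else:
            step *= config.refine_shrink

    if not _better(f, start_f, maximize) and f != start_f:  # pragma: no cover
        return candidate
    return Candidate(x, f, refined=True)


def step_generation(
    population: Sequence[Candidate],
    problem: BoundedProblem,
    config: HGAConfig,
    rng: np.random.Generator,
    objective: Optional[_CountingObjective] = None,
) -> tuple:
    """Advance one generation and return ``(new_population, stats)``.

    Order of operations: (1) the top ``elitism_rate`` fraction is copied
    unchanged (at least one elite always survives); (2) a ``crossover_rate``
    fraction of the child slots is bred from roulette-selected parents;
    (3) the remaining slots are filled with copies of roulette-selected
    parents; (4) a ``mutation_rate`` fraction of the children is mutated
    (elites are never mutation candidates); (5) children not already at a
    refined point are locally refined (a ``refine_fraction`` below one refines
    a random subset).  The child population has the parents' size and the best
    fitness never worsens.
    """
    obj = objective or _CountingObjective(problem, config)
    n = len(population)
    maximize = problem.maximize
    box = problem.coded_box

    order = np.argsort([c.fitness for c in population], kind="stable")
    if maximize:
        order = order[::-1]
    n_elite = min(n, max(1, _round_half_away(config.elitism_rate * n)))
    elites = [population[i].copy() for i in order[:n_elite]]

    n_children = n - n_elite
    n_cross = min(n_children, _round_half_away(config.crossover_rate * n_children))
    scores = selection_scores(population, problem.goal, config)

    children: list = []
    if n_cross > 0:
        pairs = _roulette_indices(n, scores, rng, 2 * n_cross)
        for k in range(n_cross):
            pa = population[pairs[2 * k]]
            pb = population[pairs[2 * k + 1]]
            children.append(crossover(pa, pb, rng))
    n_copy = n_children - n_cross
    if n_copy > 0:
        for idx in _roulette_indices(n, scores, rng, n_copy):
            children.append(population[idx].copy())

    # mutation over the child pool (never the elites, which sit outside it)
    n_mut = min(n_children, _round_half_away(config.mutation_rate * n))
    if n_mut > 0 and n_children > 0:
        for idx in rng.choice(n_children, size=n_mut, replace=False):
            children[idx] = mutate(children[idx], box, rng)

    # evaluate children produced without a fitness
    pending = [i for i, c in enumerate(children) if not math.isfinite(c.fitness)]
    if pending:
        fresh = obj.batch(np.stack([children[i].genome for i in pending]))
        for i, f in zip(pending, fresh):
            children[i].fitness = float(f)

    # local refinement of children not already at a refined point
    if config.refine_fraction > 0 and n_children > 0:
        unrefined = [i for i, c in enumerate(children) if not c.refined]
        n_ref = min(
            len(unrefined), _round_half_away(config.refine_fraction * n_children)
        )
        if n_ref < len(unrefined):
            chosen = rng.choice(len(unrefined), size=n_ref, replace=False)
            targets = [unrefined[j] for j in chosen]
        else:
            targets = unrefined
        for i in targets:
            children[i] = local_refine(problem, children[i], config, objective=obj)

    new_pop = elites + children
    fits = np.array([c.fitness for c in new_pop])
    best_idx = int(np.argmax(fits) if maximize else np.argmin(fits))
    stats = GenerationStats(
        generation_index=-1,  # filled by run_hga
        best_fitness=float(fits[best_idx]),
        mean_fitness=float(np.mean(fits)),
        worst_fitness=float(np.min(fits) if maximize else np.max(fits)),
        best_genome=new_pop[best_idx].genome.copy(),
    )
    return new_pop, stats


def run_hga(problem: BoundedProblem, config: HGAConfig) -> OptimizationResult:
    """Run the hybrid genetic algorithm and return the full result.

    Stops after ``config.generations`` generations, or earlier when
    ``config.persistence > 0`` and the best fitness has not improved by more
    than ``config.tolerance`` for that many consecutive generations.
    """
    rng = np.random.default_rng(config.seed)
    obj = _CountingObjective(problem, config)
    maximize = problem.maximize

    try:
        population = initialize_population(problem, config, rng, objective=obj)
    except Exception as exc:
        raise RuntimeError(f"initialization failed for {problem.name!r}: {exc}") from exc

    history: list = []
    fits = np.array([c.fitness for c in population])
    best_idx = int(np.argmax(fits) if maximize else np.argmin(fits))
    history.append(
        GenerationStats(
            generation_index=0,
            best_fitness=float(fits[best_idx]),
            mean_fitness=float(np.mean(fits)),
            worst_fitness=float(np.min(fits) if maximize else np.max(fits)),
            best_genome=population[best_idx].genome.copy(),
        )
    )

    best_so_far = history[0].best_fitness
    stall = 0
    for gen in range(1, config.generations + 1):
        try:
            population, stats = step_generation(
                population, problem, config, rng, objective=obj
            )
        except Exception as exc:
            raise RuntimeError(f"generation {gen} failed: {exc}") from exc
        stats = replace(stats, generation_index=gen)
        history.append(stats)
        improvement = (
            stats.best_fitness - best_so_far
            if maximize
            else best_so_far - stats.best_fitness
        )
        if improvement > config.tolerance:
            best_so_far = stats.best_fitness
            stall = 0
        else:
            stall += 1
            if config.persistence > 0 and stall >= config.persistence:
                break

    fits = np.array([c.fitness for c in population])
    best_idx = int(np.argmax(fits) if maximize else np.argmin(fits))
    best = population[best_idx].copy()
    tolerance_set = [
        c.copy()
        for c in population
        if abs(c.fitness - best.fitness) <= config.tolerance
    ]
    return OptimizationResult(
        best=best,
        best_natural=problem.decode_point(best.genome),
        history=history,
        tolerance_set=tolerance_set,
        evaluations=obj.count,
        seed=config.seed,
        problem_name=problem.name,
    )
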