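# Methods

## The optimization problem

Each case study is a box-constrained maximization (minimization for the
Ackley benchmark) of a known analytic objective. The three process models
are second-order response surfaces whose coefficients were fitted by the
original experimental studies and are consumed here as printed — this
package optimizes the surfaces, it does not refit them. Surfaces are stated
in *coded* variables: each process variable is mapped affinely so that its
design levels land on symmetric values (±1 for the factorial problems,
±2.378 for the five-variable central-composite design). Optimization
happens in coded space and results are decoded to natural units only for
reporting; the Ackley benchmark carries no coding and is optimized directly
in natural units on [−20, 20]².

One of the published design tables pairs its larger natural limit with the
lower coded level. `VariableCoding` normalizes every variable at
construction so that the smaller natural value always pairs with the
smaller coded level. This is the only reading consistent with the design's
axial coding (±2.378 with the center at coded zero) and with the published
optimum, whose substrate concentration of 10.71 g sits essentially at the
10.0 g design center. Likewise, one cross term in the five-variable model
is printed with a garbled subscript; it is implemented as the x1·x2 term —
the only i<j pair otherwise missing — and this reading reproduces the
published optimum value to 0.001 IU/gds.

## The hybrid algorithm

The engine is a real-coded GA with one deterministic addition: after
selection, crossover and mutation, each new offspring is refined by
adaptive-step steepest ascent (descent when minimizing) before it enters
the population. One generation proceeds in order:

1. **Elitism** — the top `elitism_rate` fraction (at least one candidate;
   fractional counts round half away from zero) is copied unchanged.
2. **Crossover** — a `crossover_rate` fraction of the child slots is bred
   from roulette-selected parents. The operator is per-coordinate blend
   (arithmetic) crossover: each child coordinate is an independent convex
   combination of the parents', which keeps children inside the box by
   construction. Selection is with replacement and parents may self-pair.
3. **Copying** — the remaining slots are filled with roulette-selected
   copies.
4. **Mutation** — a `mutation_rate` fraction of the children has its genome
   completely re-randomized (a fresh uniform draw in the box, not a
   Gaussian perturbation). Elites are never mutation candidates.
5. **Refinement** — children not already sitting at a refined point are
   locally refined (all of them by default; `refine_fraction` can lower
   this for evaluation-budget control).

Roulette scores shift fitness to a non-negative scale — `f − min + ε`
maximizing, `max − f + ε` minimizing, with ε at 1e-6 of the population
spread — and an all-identical population scores uniformly. When a response
band is configured (`response_bounds`), the weighted deviation of a
candidate's response from the band is charged against its fitness before
scoring, so infeasible candidates lose selection pressure without being
discarded. Multiple response models sharing one coding can be scalarized
into a single fitness by a weighted sum (`objective_weights`); Pareto-front
analysis is out of scope.

### Local refinement

From a candidate `x` the refiner repeatedly moves along the normalized
(±)gradient — analytic for quadratic models, central finite differences
with step 1e-6 × box width otherwise — projecting each trial onto the box.
The step length starts at `refine_initial_step` (default 0.1) times the
widest box side, doubles after an improving move (when the gradient is also
refreshed), and halves after a failed one (keeping the direction). The
search stops when the step falls below `refine_min_step` (default 1e-12;
1e-14 for high-precision Ackley runs) or after `refine_max_evals` (default
500) objective evaluations for that candidate. The returned candidate is
never worse than the input, and non-finite objective values abort the
search and return the input unchanged.

Candidates carry a `refined` flag: a child copied from an already-refined
parent is not re-refined, since steepest ascent restarted at a converged
point can only burn its evaluation budget. On the Ackley surface, the
smooth exponential envelope gives the refiner a global pull toward the
origin, so in practice the very first refined generation already reaches
the global basin — which is the entire argument for hybridization: the same
descent started from a deterministic grid would stall in any of the
hundreds of cosine wells.

## Configuration defaults

| parameter | default | meaning |
|---|---|---|
| population_size | 100 | candidates per generation |
| generations | 100 | generations per run |
| crossover_rate | 0.80 | fraction of child slots bred |
| mutation_rate | 0.01 | fraction of children re-randomized |
| elitism_rate | 0.10 | fraction copied unchanged |
| tolerance | 0 | fitness band for the returned solution set, and the improvement threshold for early stopping |
| persistence | 0 | early-stop patience in generations (0 disables) |
| refine_initial_step | 0.1 | initial step, fraction of widest box side |
| refine_grow / refine_shrink | 2.0 / 0.5 | step adaptation factors |
| refine_min_step | 1e-12 | absolute step at which refinement stops |
| refine_max_evals | 500 | per-candidate refinement evaluation budget |
| refine_fraction | 1.0 | fraction of children refined |

The genetic-operator rates are the standard values used across all four
case studies. Runs are bit-for-bit reproducible from `seed`: all
randomness flows through one `numpy.random.Generator`.

## The oracle

For a quadratic on a box, the exact optimum is found by active-set
enumeration: every one of the 3^d assignments of variables to {lower,
upper, free} fixes a face; the stationarity linear system is solved on the
free coordinates; infeasible or singular faces are discarded (singular
faces are logged and skipped — the 2^d corners always remain); the best
feasible candidate wins and is certified against first-order optimality.
KKT tolerance is 1e-6 in coded units — tighter would be meaningless for
coefficients printed to two decimals. Enumeration was chosen over a general
QP solver because d ≤ 5 in every bundled problem, making the exact method
dependency-free and auditable. For non-quadratic objectives a chunked
full-lattice search (≤ 10^7 points) serves as a heuristic cross-check
instead; it carries no optimality certificate.

A deliberate consequence of certifying the printed coefficients: the
biodiesel surface's exact constrained maximum is 98.372%, slightly above
the 98.28% reported by the source study. The package reports what the
stated coefficients imply and treats the published figure as a lower bound.

## Replication experiments

`replicate_case_studies` runs the hybrid GA (default configuration) and the
oracle on each bundled problem and tabulates both against the optima
reported in the original studies (anthocyanin 90.02%, FAME 93.55%, xylanase
553.17 IU/gds), including absolute and relative improvements.
`convergence_profile` aggregates independent seeded trials into a
per-generation mean of best-so-far fitness plus the fastest- and
slowest-converging trials, ranked by the first generation at which the best
fitness crosses a threshold (1e-6 by default for Ackley; trials that never
cross rank last). The mean is taken over best-so-far fitness per
generation, so elitism makes every trajectory — and hence the mean —
monotone.

## Problem sizes used in tests and the acceptance script

Accuracy-bearing checks (reproducing the case-study optima, the
best-of-ten-seeds Ackley minimum) run at the full default configuration.
Structural property checks — elitism monotonicity across fixtures and
seeds, refinement dominance over 10³ random starts, stochastic-vs-oracle
agreement over 20 seeds — use reduced populations and generation counts
(20–40 candidates, 10–30 generations), chosen because these properties are
invariants of the operators, not of the budget; the reduced runs still
recover the certified optima to 1e-3. The multi-trial convergence profile
is exercised at 50 trials; the full 1000-trial profile is available through
the same API and CLI.

## Known limitations

- The optimality certificate applies only to quadratic objectives; for
  anything else the lattice search is a sanity check, not a proof.
- Chromosomes are real vectors; bit-string encodings are not supported.
- Constraint handling is a soft penalty at selection time; hard nonlinear
  constraints and Pareto-front multi-objective output are not implemented.
- Full-randomization mutation is aggressive by design (it matches the
  operator set the engine is built around); surfaces needing fine-grained
  mutation noise would want a Gaussian operator instead.
- As with any stochastic search, per-run time and evaluation counts vary
  with the seed; no real-time guarantee is offered.
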