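"""Independent verification of box-constrained optima.

For a quadratic response surface on a box, the exact optimum can be found
without any iterative optimizer: assign every variable to one of {lower
bound, upper bound, free}, solve the stationarity linear system on the free
coordinates of each of the 3^d assignments, keep the feasible candidates, and
take the best.  With d <= 5 in every bundled case study this enumeration is
instantaneous and auditable, and the winner is certified against first-order
(KKT) optimality: interior coordinates must have zero partial derivative,
bound coordinates a gradient sign that pushes outward.

For non-quadratic objectives (the Ackley benchmark), a brute-force lattice
search provides a heuristic cross-check instead.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np

from .rsm_models import BoundedProblem, QuadraticResponseModel, evaluate_quadratic, gradient_quadratic

__all__ = ["OracleSolution", "quadratic_box_optimum", "grid_search", "kkt_check"]

logger = logging.getLogger(__name__)

_GRID_BUDGET = 10_000_000


@dataclass(frozen=True)
class OracleSolution:
    """Certified optimum of a box-constrained quadratic."""

    argmax_coded: np.ndarray
    value: float
    active_set: tuple  # per variable: "at_lower" | "at_upper" | "interior"
    kkt_verified: bool

    def report(self) -> str:
        lines = [f"value: {self.value:.6f}  (KKT verified: {self.kkt_verified})"]
        for i, (x, a) in enumerate(zip(self.argmax_coded, self.active_set)):
            lines.append(f"  x{i + 1} = {x: .6f}  [{a}]")
        return "\n".join(lines)


def quadratic_box_optimum(
    model: QuadraticResponseModel, box, goal: str = "maximize"
) -> OracleSolution:
    """Exact optimum of ``model`` over ``box`` by 3^d active-set enumeration.

    ``box`` is a ``(d, 2)`` array of lower/upper bounds in coded units.
    Faces whose stationarity system is singular are skipped (logged at DEBUG);
    every corner is always evaluated, so a best candidate always exists.
    """
    d = model.d
    if d > 8:
        raise ValueError("active-set enumeration is limited to d <= 8")
    if goal not in ("maximize", "minimize"):
        raise ValueError("goal must be 'maximize' or 'minimize'")
    box = np.asarray(box, dtype=float).reshape(d, 2)
    lo, hi = box[:, 0], box[:, 1]
    maximize = goal == "maximize"
    H = model.hessian()

    best_x = None
    best_v = -math.inf if maximize else math.inf
    for assign in itertools.product((0, 1, 2), repeat=d):
        free = [i for i, a in enumerate(assign) if a == 2]
        x = np.array(
            [lo[i] if a == 0 else (hi[i] if a == 1 else 0.0) for i, a in enumerate(assign)]
        )
        if free:
            fixed = [i for i in range(d) if i not in free]
            A = H[np.ix_(free, free)]
            rhs = -(model.linear[free] + (H[np.ix_(free, fixed)] @ x[fixed] if fixed else 0.0))
            try:
                sol = np.linalg.solve(A, rhs)
            except np.linalg.LinAlgError:
                logger.debug("singular stationarity system on face %s; skipped", assign)
                continue
            if not np.all(np.isfinite(sol)):
                continue
            x[free] = sol
            if np.any(x[free] < lo[free] - 1e-12) or np.any(x[free] > hi[free] + 1e-12):
                continue
            x[free] = np.clip(x[free], lo[free], hi[free])
        v = evaluate_quadratic(model, x)
        if (v > best_v) if maximize else (v < best_v):
            best_v, best_x = v, x

    active = _classify_active(best_x, lo, hi)
    ok, _ = kkt_check(model, box, best_x, goal)
    return OracleSolution(
        argmax_coded=best_x, value=float(best_v), active_set=active, kkt_verified=ok
    )


def _classify_active(x: np.ndarray, lo: np.ndarray, hi: np.ndarray, tol: float = 1e-9):
    out = []
    for xi, l, h in zip(x, lo, hi):
        if abs(xi - l) <= tol:
            out.append("at_lower")
        elif abs(xi - h) <= tol:
            out.append("at_upper")
        else:
            out.append("interior")
    return tuple(out)


def kkt_check(
    model: QuadraticResponseModel,
    box,
    point,
    goal: str = "maximize",
    tol: float = 1e-6,
):
    """First-order optimality at ``point``: ``(ok, per-coordinate report)``.

    Interior coordinates need a zero partial derivative; a coordinate at a
    bound needs the gradient sign that makes every feasible move non-improving
    (maximizing: dY/dx_i <= 0 at the lower bound, >= 0 at the upper bound;
    minimizing, the reverse).
    """
    box = np.asarray(box, dtype=float).reshape(model.d, 2)
    x = np.asarray(point, dtype=float)
    if np.any(x < box[:, 0] - 1e-9) or np.any(x > box[:, 1] + 1e-9):
        raise ValueError("point lies outside the box")
    g = gradient_quadratic(model, x)
    maximize = goal == "maximize"
    report = []
    ok = True
    for i in range(model.d):
        pos = _classify_active(x[i : i + 1], box[i : i + 1, 0], box[i : i + 1, 1])[0]
        if pos == "interior":
            good = abs(g[i]) <= tol
        elif pos == "at_lower":
            good = g[i] <= tol if maximize else g[i] >= -tol
        else:
            good = g[i] >= -tol if maximize else g[i] <= tol
        ok = ok and good
        report.append({"index": i, "position": pos, "gradient": float(g[i]), "ok": bool(good)})
    return ok, report


def grid_search(problem: BoundedProblem, resolution: int):
    """Brute-force lattice search: evaluate the objective on a full grid of
    ``resolution`` points per dimension (boundaries included) and return
    ``(best_point, best_value)``.

    Refuses lattices beyond 10^7 points; lower the resolution instead.
    """
    if resolution < 2:
        raise ValueError("resolution must be at least 2")
    d = problem.d
    total = resolution**d
    if total > _GRID_BUDGET:
        raise ValueError(
            f"lattice of {total} points exceeds the {_GRID_BUDGET} budget; "
            "lower the resolution"
        )
    axes = [
        np.linspace(problem.coded_box[i, 0], problem.coded_box[i, 1], resolution)
        for i in range(d)
    ]
    maximize = problem.maximize
    best_v = -math.inf if maximize else math.inf
    best_x = None
    shape = (resolution,) * d
    chunk = 200_000
    for start in range(0, total, chunk):
        idx = np.arange(start, min(start + chunk, total))
        coords = np.unravel_index(idx, shape)
        X = np.column_stack([axes[i][coords[i]] for i in range(d)])
        vals = np.atleast_1d(problem.evaluate(X))
        k = int(np.argmax(vals) if maximize else np.argmin(vals))
        if (vals[k] > best_v) if maximize else (vals[k] < best_v):
            best_v = float(vals[k])
            best_x = X[k].copy()
    return best_x, best_v
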