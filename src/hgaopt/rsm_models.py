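"""Objective functions for process optimization: RSM quadratics and the Ackley benchmark.

Response surface methodology (RSM) summarizes designed experiments as a
second-order polynomial in *coded* process variables (levels rescaled so the
factorial design maps to ±1, axial points to ±alpha).  This module represents
such models, the affine coded<->natural variable maps that accompany them, the
Ackley benchmark used to validate the optimizer, and the bundled case-study
problems: anthocyanin extraction yield from purple sweet potato, fatty acid
methyl ester (biodiesel) yield from transesterification, and xylanase
production on a wheat-bran substrate.

Problems can also be defined in a small YAML format (see :func:`load_problem`);
the built-in case studies are shipped in that same format so external and
built-in problems go through one loader.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import yaml

__all__ = [
    "AckleyParams",
    "QuadraticResponseModel",
    "VariableCoding",
    "BoundedProblem",
    "evaluate_ackley",
    "evaluate_quadratic",
    "gradient_quadratic",
    "encode",
    "decode",
    "case_study",
    "CASE_STUDY_NAMES",
    "load_problem",
    "save_problem",
]

CASE_STUDY_NAMES = ("ackley", "anthocyanin", "fame", "xylanase")


class CodingRangeWarning(UserWarning):
    """A point was transformed outside its declared variable range (not clipped)."""


def _check_dim(x: np.ndarray, d: int, what: str) -> None:
    if x.shape[-1] != d:
        raise ValueError(
            f"{what}: expected point(s) with {d} components, got shape {x.shape}"
        )


# ---------------------------------------------------------------------------
# Ackley benchmark
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AckleyParams:
    """Constants of the Ackley test function.

    f(x) = -a exp(-b sqrt(mean(x_i^2))) - exp(mean(cos(c x_i))) + a + e

    The default instance is the standard 2-D benchmark: a=20, b=0.2, c=2*pi,
    each coordinate bounded in [-20, 20].  The global minimum is f(0)=0; the
    surface carries a dense field of shallow local minima that trap pure
    gradient methods.
    """

    n_dims: int = 2
    a: float = 20.0
    b: float = 0.2
    c: float = 2.0 * math.pi
    box: np.ndarray = field(
        default_factory=lambda: np.array([[-20.0, 20.0], [-20.0, 20.0]])
    )

    def __post_init__(self) -> None:
        if self.n_dims < 1:
            raise ValueError("n_dims must be >= 1")
        box = np.asarray(self.box, dtype=float).reshape(self.n_dims, 2)
        if np.any(box[:, 0] >= box[:, 1]):
            raise ValueError("each lower bound must be < its upper bound")
        object.__setattr__(self, "box", box)


def evaluate_ackley(params: AckleyParams, x) -> Union[float, np.ndarray]:
    """Evaluate the Ackley function at ``x`` (shape ``(d,)`` or ``(n, d)``).

    Even in every coordinate and invariant under coordinate permutation;
    non-negative, and zero exactly at the origin.
    """
    n = params.n_dims
    if isinstance(x, np.ndarray) and x.ndim == 2:
        _check_dim(x, n, "evaluate_ackley")
        sq = np.mean(x * x, axis=1)
        cs = np.mean(np.cos(params.c * x), axis=1)
        return (
            -params.a * np.exp(-params.b * np.sqrt(sq))
            - np.exp(cs)
            + params.a
            + math.e
        )
    # scalar fast path: called tens of thousands of times during refinement
    xs = x if isinstance(x, (list, tuple)) else np.asarray(x, dtype=float).ravel()
    if len(xs) != n:
        raise ValueError(
            f"evaluate_ackley: expected {n} components, got {len(xs)}"
        )
    sq = 0.0
    cs = 0.0
    c = params.c
    for v in xs:
        sq += v * v
        cs += math.cos(c * v)
    return (
        -params.a * math.exp(-params.b * math.sqrt(sq / n))
        - math.exp(cs / n)
        + params.a
        + math.e
    )


# ---------------------------------------------------------------------------
# Quadratic response-surface models
# ---------------------------------------------------------------------------

class QuadraticResponseModel:
    """Second-order polynomial response surface in coded variables.

    Y(x) = intercept + sum_i linear_i x_i + sum_i pure_quadratic_i x_i^2
         + sum_{i<j} interaction_ij x_i x_j

    Each cross term is counted once (``i < j``); the interaction table is kept
    as an upper-triangular matrix internally so double counting is impossible,
    with :attr:`interaction` exposing the symmetric view.
    """

    def __init__(
        self,
        intercept: float,
        linear: Sequence[float],
        pure_quadratic: Sequence[float],
        interactions: Union[Mapping[tuple, float], np.ndarray, None] = None,
        response_name: str = "response",
        response_units: str = "",
    ) -> None:
        self.intercept = float(intercept)
        self.linear = np.asarray(linear, dtype=float).ravel()
        self.pure_quadratic = np.asarray(pure_quadratic, dtype=float).ravel()
        d = self.linear.size
        if self.pure_quadratic.size != d:
            raise ValueError("linear and pure_quadratic must have equal length")
        upper = np.zeros((d, d))
        if interactions is not None:
            if isinstance(interactions, Mapping):
                for (i, j), v in interactions.items():
                    if i == j:
                        raise ValueError(
                            "diagonal interaction terms belong in pure_quadratic"
                        )
                    lo, hi = (i, j) if i < j else (j, i)
                    upper[lo, hi] += float(v)
            else:
                m = np.asarray(interactions, dtype=float)
                if m.shape != (d, d):
                    raise ValueError(f"interaction matrix must be {d}x{d}")
                if np.any(np.diag(m) != 0.0):
                    raise ValueError("interaction matrix must have zero diagonal")
                low = np.tril(m, -1)
                if np.any(low):
                    if not np.allclose(m, m.T):
                        raise ValueError(
                            "interaction matrix must be symmetric or upper-triangular"
                        )
                    upper = np.triu(m, 1)
                else:
                    upper = np.triu(m, 1)
        self._upper = upper
        self.response_name = response_name
        self.response_units = response_units

    @property
    def d(self) -> int:
        return self.linear.size

    @property
    def interaction(self) -> np.ndarray:
        """Symmetric interaction table with zero diagonal."""
        return self._upper + self._upper.T

    @property
    def interaction_upper(self) -> np.ndarray:
        """Upper-triangular storage: coefficient of x_i x_j at [i, j], i < j."""
        return self._upper

    def hessian(self) -> np.ndarray:
        """Constant Hessian matrix: 2*diag(pure_quadratic) + symmetric interactions."""
        return 2.0 * np.diag(self.pure_quadratic) + self.interaction

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"QuadraticResponseModel(d={self.d}, response_name={self.response_name!r})"
        )


def evaluate_quadratic(model: QuadraticResponseModel, x) -> Union[float, np.ndarray]:
    """Evaluate the model at coded point(s) ``x`` (shape ``(d,)`` or ``(n, d)``)."""
    x = np.asarray(x, dtype=float)
    _check_dim(x, model.d, "evaluate_quadratic")
    if x.ndim == 1:
        return float(
            model.intercept
            + model.linear @ x
            + model.pure_quadratic @ (x * x)
            + x @ model.interaction_upper @ x
        )
    return (
        model.intercept
        + x @ model.linear
        + (x * x) @ model.pure_quadratic
        + np.einsum("ni,ij,nj->n", x, model.interaction_upper, x)
    )


def gradient_quadratic(model: QuadraticResponseModel, x) -> np.ndarray:
    """Analytic gradient dY/dx_i = linear_i + 2 q_i x_i + sum_{j!=i} b_ij x_j."""
    x = np.asarray(x, dtype=float)
    _check_dim(x, model.d, "gradient_quadratic")
    return model.linear + 2.0 * model.pure_quadratic * x + model.interaction @ x


# ---------------------------------------------------------------------------
# Coded <-> natural variable transforms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariableCoding:
    """Per-variable affine maps between natural process units and coded levels.

    Construction normalizes each variable so ``natural_low < natural_high``
    pairs with ``coded_low < coded_high`` (design tables are sometimes printed
    with the limit rows swapped; a central-composite coding is only consistent
    when the smaller natural value carries the smaller coded level, which is
    what keeps the design center at coded zero).
    """

    names: tuple
    natural_low: np.ndarray
    natural_high: np.ndarray
    coded_low: np.ndarray
    coded_high: np.ndarray
    units: tuple = ()

    @classmethod
    def from_records(cls, records: Iterable[Mapping]) -> "VariableCoding":
        """Build a coding from dicts with keys name, natural_low/high, coded_low/high."""
        names, units, nlo, nhi, clo, chi = [], [], [], [], [], []
        for rec in records:
            a, b = float(rec["natural_low"]), float(rec["natural_high"])
            p, q = float(rec["coded_low"]), float(rec["coded_high"])
            if a == b:
                raise ValueError(
                    f"variable {rec.get('name', '?')!r}: degenerate natural range {a}"
                )
            if p == q:
                raise ValueError(
                    f"variable {rec.get('name', '?')!r}: degenerate coded range {p}"
                )
            # normalize so low < high on both scales
            if a > b:
                a, b = b, a
            if p > q:
                p, q = q, p
            names.append(str(rec.get("name", f"x{len(names) + 1}")))
            units.append(str(rec.get("units", "")))
            nlo.append(a)
            nhi.append(b)
            clo.append(p)
            chi.append(q)
        return cls(
            names=tuple(names),
            natural_low=np.array(nlo),
            natural_high=np.array(nhi),
            coded_low=np.array(clo),
            coded_high=np.array(chi),
            units=tuple(units),
        )

    @property
    def d(self) -> int:
        return len(self.names)

    def to_records(self) -> list:
        return [
            {
                "name": self.names[i],
                "units": self.units[i] if self.units else "",
                "natural_low": float(self.natural_low[i]),
                "natural_high": float(self.natural_high[i]),
                "coded_low": float(self.coded_low[i]),
                "coded_high": float(self.coded_high[i]),
            }
            for i in range(self.d)
        ]


def encode(coding: VariableCoding, natural_point) -> np.ndarray:
    """Map a natural-unit point to coded units (affine, no clipping).

    Points outside the declared natural range are transformed anyway but a
    :class:`CodingRangeWarning` is emitted.
    """
    v = np.asarray(natural_point, dtype=float)
    _check_dim(v, coding.d, "encode")
    if np.any(v < coding.natural_low - 1e-9) or np.any(v > coding.natural_high + 1e-9):
        warnings.warn(
            "natural point lies outside the declared variable range; "
            "transformed without clipping",
            CodingRangeWarning,
            stacklevel=2,
        )
    scale = (coding.coded_high - coding.coded_low) / (
        coding.natural_high - coding.natural_low
    )
    return coding.coded_low + (v - coding.natural_low) * scale


def decode(coding: VariableCoding, coded_point) -> np.ndarray:
    """Inverse of :func:`encode`: coded units back to natural process units."""
    u = np.asarray(coded_point, dtype=float)
    _check_dim(u, coding.d, "decode")
    if np.any(u < coding.coded_low - 1e-9) or np.any(u > coding.coded_high + 1e-9):
        warnings.warn(
            "coded point lies outside the declared coded range; "
            "transformed without clipping",
            CodingRangeWarning,
            stacklevel=2,
        )
    scale = (coding.natural_high - coding.natural_low) / (
        coding.coded_high - coding.coded_low
    )
    return coding.natural_low + (u - coding.coded_low) * scale


# ---------------------------------------------------------------------------
# Bounded optimization problems
# ---------------------------------------------------------------------------

Objective = Union[AckleyParams, QuadraticResponseModel]


@dataclass(frozen=True)
class BoundedProblem:
    """A box-constrained optimization problem over one or more objectives.

    Quadratic response models are evaluated (and optimized) in coded space,
    with :meth:`decode_point` recovering natural units for reporting.  The
    Ackley benchmark carries no coding and is optimized directly in natural
    units.  ``objective`` may be a tuple of models sharing one coding, in
    which case evaluation takes a weighted sum (equal weights by default) —
    the scalarized form of a multi-response optimization.
    """

    name: str
    objective: Union[Objective, tuple]
    goal: str  # "maximize" | "minimize"
    coded_box: np.ndarray  # (d, 2) lower/upper in the optimization space
    coding: VariableCoding = None

    def __post_init__(self) -> None:
        if self.goal not in ("maximize", "minimize"):
            raise ValueError("goal must be 'maximize' or 'minimize'")
        box = np.asarray(self.coded_box, dtype=float).reshape(-1, 2)
        if np.any(box[:, 0] >= box[:, 1]):
            raise ValueError("each lower bound must be < its upper bound")
        object.__setattr__(self, "coded_box", box)
        for obj in self.objectives:
            d = obj.n_dims if isinstance(obj, AckleyParams) else obj.d
            if d != box.shape[0]:
                raise ValueError("objective dimensionality does not match the box")

    @property
    def objectives(self) -> tuple:
        return self.objective if isinstance(self.objective, tuple) else (self.objective,)

    @property
    def d(self) -> int:
        return self.coded_box.shape[0]

    @property
    def maximize(self) -> bool:
        return self.goal == "maximize"

    def _eval_one(self, obj: Objective, x):
        if isinstance(obj, AckleyParams):
            return evaluate_ackley(obj, x)
        return evaluate_quadratic(obj, x)

    def evaluate(self, x, objective_weights=None):
        """Scalar fitness at ``x``; multiple objectives are weight-summed."""
        objs = self.objectives
        if len(objs) == 1 and objective_weights is None:
            return self._eval_one(objs[0], x)
        w = (
            np.ones(len(objs))
            if objective_weights is None
            else np.asarray(objective_weights, dtype=float)
        )
        if w.size != len(objs):
            raise ValueError("one objective weight per objective is required")
        vals = [self._eval_one(o, x) for o in objs]
        out = sum(wi * vi for wi, vi in zip(w, vals))
        return out

    def gradient(self, x, objective_weights=None, fd_rel_step: float = 1e-6) -> np.ndarray:
        """Gradient of the scalar fitness: analytic for quadratics, central
        finite differences (step ``fd_rel_step`` x box width per dimension)
        otherwise."""
        objs = self.objectives
        w = (
            np.ones(len(objs))
            if objective_weights is None
            else np.asarray(objective_weights, dtype=float)
        )
        g = np.zeros(self.d)
        for wi, obj in zip(w, objs):
            if isinstance(obj, QuadraticResponseModel):
                g += wi * gradient_quadratic(obj, x)
            else:
                g += wi * self._fd_gradient(obj, np.asarray(x, dtype=float), fd_rel_step)
        return g

    def _fd_gradient(self, obj, x: np.ndarray, rel_step: float) -> np.ndarray:
        h = rel_step * (self.coded_box[:, 1] - self.coded_box[:, 0])
        g = np.empty(self.d)
        for i in range(self.d):
            xp = x.copy()
            xm = x.copy()
            xp[i] += h[i]
            xm[i] -= h[i]
            g[i] = (self._eval_one(obj, xp) - self._eval_one(obj, xm)) / (2.0 * h[i])
        return g

    def decode_point(self, x) -> np.ndarray:
        """Coded point -> natural units (identity when no coding is attached)."""
        if self.coding is None:
            return np.asarray(x, dtype=float).copy()
        return decode(self.coding, x)

    def encode_point(self, v) -> np.ndarray:
        if self.coding is None:
            return np.asarray(v, dtype=float).copy()
        return encode(self.coding, v)

    def variable_names(self) -> list:
        if self.coding is not None:
            return list(self.coding.names)
        return [f"x{i + 1}" for i in range(self.d)]


# ---------------------------------------------------------------------------
# Problem-definition files and the built-in case studies
# ---------------------------------------------------------------------------

def _problem_from_dict(doc: Mapping, source: str) -> BoundedProblem:
    try:
        name = str(doc.get("name", Path(source).stem))
        goal = str(doc["goal"])
        obj = doc["objective"]
        kind = obj["kind"]
    except KeyError as exc:
        raise ValueError(f"{source}: missing required key {exc}") from exc

    if kind == "ackley":
        n = int(obj.get("n_dims", 2))
        lower = float(obj.get("lower", -20.0))
        upper = float(obj.get("upper", 20.0))
        params = AckleyParams(
            n_dims=n,
            a=float(obj.get("a", 20.0)),
            b=float(obj.get("b", 0.2)),
            c=float(obj.get("c", 2.0 * math.pi)),
            box=np.tile([lower, upper], (n, 1)),
        )
        return BoundedProblem(
            name=name, objective=params, goal=goal, coded_box=params.box, coding=None
        )
    if kind == "quadratic":
        variables = doc.get("variables")
        if not variables:
            raise ValueError(f"{source}: quadratic problems require 'variables'")
        coding = VariableCoding.from_records(variables)
        inter = {}
        for triple in obj.get("interactions", []):
            i, j, v = triple
            inter[(int(i) - 1, int(j) - 1)] = float(v)  # file indices are 1-based
        model = QuadraticResponseModel(
            intercept=float(obj["intercept"]),
            linear=obj["linear"],
            pure_quadratic=obj["quadratic"],
            interactions=inter,
            response_name=str(obj.get("response_name", "response")),
            response_units=str(obj.get("response_units", "")),
        )
        box = np.column_stack([coding.coded_low, coding.coded_high])
        return BoundedProblem(
            name=name, objective=model, goal=goal, coded_box=box, coding=coding
        )
    raise ValueError(f"{source}: unknown objective kind {kind!r}")


def load_problem(path) -> BoundedProblem:
    """Load a :class:`BoundedProblem` from a YAML problem-definition file."""
    p = Path(path)
    with open(p) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise ValueError(f"{p}: problem file must contain a mapping")
    return _problem_from_dict(doc, str(p))


def problem_to_dict(problem: BoundedProblem) -> dict:
    """Serializable representation in the problem-definition schema."""
    objs = problem.objectives
    if len(objs) != 1:
        raise ValueError("only single-objective problems can be serialized")
    obj = objs[0]
    doc: dict = {"name": problem.name, "goal": problem.goal}
    if isinstance(obj, AckleyParams):
        doc["objective"] = {
            "kind": "ackley",
            "n_dims": obj.n_dims,
            "a": obj.a,
            "b": obj.b,
            "c": obj.c,
            "lower": float(obj.box[0, 0]),
            "upper": float(obj.box[0, 1]),
        }
        return doc
    upper = obj.interaction_upper
    triples = [
        [int(i) + 1, int(j) + 1, float(upper[i, j])]
        for i, j in zip(*np.nonzero(upper))
    ]
    doc["objective"] = {
        "kind": "quadratic",
        "response_name": obj.response_name,
        "response_units": obj.response_units,
        "intercept": obj.intercept,
        "linear": [float(v) for v in obj.linear],
        "quadratic": [float(v) for v in obj.pure_quadratic],
        "interactions": triples,
    }
    doc["variables"] = problem.coding.to_records()
    return doc


def save_problem(problem: BoundedProblem, path) -> None:
    """Write a problem to the YAML problem-definition format."""
    with open(path, "w") as fh:
        yaml.safe_dump(problem_to_dict(problem), fh, sort_keys=False)


def case_study(name: str) -> BoundedProblem:
    """Return one of the built-in problems: ackley, anthocyanin, fame, xylanase."""
    key = str(name).lower()
    if key not in CASE_STUDY_NAMES:
        raise ValueError(
            f"unknown case study {name!r}; valid names: {', '.join(CASE_STUDY_NAMES)}"
        )
    ref = resources.files("hgaopt").joinpath(f"problems/{key}.yaml")
    doc = yaml.safe_load(ref.read_text())
    return _problem_from_dict(doc, f"builtin:{key}")
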