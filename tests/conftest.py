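import numpy as np
import pytest

from hgaopt import BoundedProblem, HGAConfig, QuadraticResponseModel, case_study


@pytest.fixture(scope="session")
def problems():
    """All four bundled case-study problems, loaded once."""
    return {name: case_study(name) for name in ("ackley", "anthocyanin", "fame", "xylanase")}


@pytest.fixture(scope="session")
def quadratic_problems(problems):
    return {k: v for k, v in problems.items() if k != "ackley"}


@pytest.fixture
def fast_config():
    """A small configuration for property runs where convergence quality is
    not under test."""
    return HGAConfig(
        population_size=20,
        generations=10,
        refine_max_evals=60,
        seed=0,
    )


@pytest.fixture
def parabola_1d():
    """Y = -(x - 0.3)^2 on [-1, 1], maximized at x = 0.3."""
    model = QuadraticResponseModel(
        intercept=-0.09, linear=[0.6], pure_quadratic=[-1.0], response_name="parabola"
    )
    return BoundedProblem(
        name="parabola", objective=model, goal="maximize", coded_box=np.array([[-1.0, 1.0]])
    )


def random_quadratic(rng: np.random.Generator, d: int) -> QuadraticResponseModel:
    """A random quadratic response model for property tests."""
    inter = {}
    for i in range(d):
        for j in range(i + 1, d):
            inter[(i, j)] = float(rng.normal(scale=2.0))
    return QuadraticResponseModel(
        intercept=float(rng.normal(scale=10.0)),
        linear=rng.normal(scale=3.0, size=d),
        pure_quadratic=rng.normal(scale=3.0, size=d),
        interactions=inter,
    )
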