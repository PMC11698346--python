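import numpy as np
import pytest

from fracprey import (
    CaputoProblem,
    ModelParams,
    abm_solve,
    vector_field,
)

# The three published experimental parameter sets.
SET1 = ModelParams(r=0.528, rho=8.0, a=0.627, alpha=0.289, beta=0.7290, b=0.276, c=0.567)
SET2 = ModelParams(r=0.067, rho=7.65, a=0.289, alpha=0.31, beta=0.02, b=0.482, c=0.467)
SET3 = ModelParams(r=0.077, rho=9.56, a=0.289, alpha=-0.01, beta=0.5, b=0.682, c=0.67)


@pytest.fixture(scope="session")
def set1() -> ModelParams:
    return SET1


@pytest.fixture(scope="session")
def set2() -> ModelParams:
    return SET2


@pytest.fixture(scope="session")
def set3() -> ModelParams:
    return SET3


def simulate(p: ModelParams, zeta: float, y0, t_end: float, h: float = 0.05):
    problem = CaputoProblem(
        order=zeta,
        rhs=lambda t, y: vector_field(p, y),
        initial_state=np.asarray(y0, dtype=float),
        t_end=t_end,
        h=h,
    )
    return abm_solve(problem)


@pytest.fixture(scope="session")
def set1_traj_z095():
    """Converging trajectory for the first parameter set at zeta = 0.95."""
    return simulate(SET1, 0.95, [2.1, 0.40], t_end=500.0)
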