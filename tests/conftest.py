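import numpy as np
import pytest

from ffsim import Parameters, State, study_initial_state, study_parameters


@pytest.fixture(scope="session")
def study_params() -> Parameters:
    return study_parameters()


@pytest.fixture(scope="session")
def study_init() -> State:
    return study_initial_state()


@pytest.fixture(scope="session")
def constructed_params() -> Parameters:
    """Parameter set with the known interior fixed point (1, 0.5, 1, 1, 1)."""
    return Parameters(alpha=2, beta=0.5, gamma=0.5, phi=1, kappa=2, mu=1,
                      rho=1, omega=0.3, lambda_il2=0.2, d=0.2, a=0.2)


def random_parameters(rng: np.random.Generator) -> Parameters:
    """Log-uniform positive parameter draw (all rates in [1e-2, 10])."""
    return Parameters(*(10.0 ** rng.uniform(-2, 1, size=11)))
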