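import numpy as np
import pytest

from twosho.fixtures import sensitivity_nominal, verification_regimes
from twosho.params import InitialState, derive_dependent_parameters


@pytest.fixture(scope="session")
def nominal():
    """The reconciled sensitivity-study oscillator (k4 = 41.75)."""
    return sensitivity_nominal("reconciled")


@pytest.fixture(scope="session")
def printed():
    """The as-printed variant with k4 = 4.77 (infeasible fixed point)."""
    return sensitivity_nominal("printed")


@pytest.fixture(scope="session")
def regimes():
    return verification_regimes()


def random_oscillator(rng: np.random.Generator):
    """A random valid parameter set spanning a few orders of magnitude."""
    k1 = rng.uniform(0.0, 2.0)
    k2 = float(np.exp(rng.uniform(np.log(0.1), np.log(10.0))))
    kd = float(np.exp(rng.uniform(np.log(0.1), np.log(10.0))))
    k4 = rng.uniform(0.0, 20.0)
    k6 = rng.uniform(0.0, 50.0)
    p = derive_dependent_parameters(k1, k2, kd, k4=k4, k6=k6)
    x0 = InitialState(rng.uniform(0.0, 20.0), rng.uniform(0.0, 20.0))
    return p, x0
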