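import numpy as np
import pytest

from mowg import (
    GeneratorParams,
    MOWGDistribution,
    exponential_baseline,
    weibull_baseline,
)


@pytest.fixture(scope="session")
def exp1():
    """Unit-exponential baseline."""
    return exponential_baseline(1.0)


@pytest.fixture(scope="session")
def plain_exp(exp1):
    """alpha = c = beta = 1 with Exp(1): reduces exactly to Exp(1)."""
    return MOWGDistribution(GeneratorParams(1.0, 1.0, 1.0), exp1)


@pytest.fixture(scope="session")
def tilted_exp(exp1):
    """alpha = 2, c = beta = 1 with Exp(1): pure-tilt member."""
    return MOWGDistribution(GeneratorParams(2.0, 1.0, 1.0), exp1)


def param_grid():
    """Small deterministic sweep over both baselines."""
    gens = [(0.05, 0.7, 1.3), (0.5, 2.0, 1.0), (1.0, 1.0, 1.0),
            (2.5, 1.4, 0.6), (5.0, 0.5, 2.0)]
    out = []
    for a, c, b in gens:
        out.append(MOWGDistribution(GeneratorParams(a, c, b),
                                    exponential_baseline(0.8)))
        out.append(MOWGDistribution(GeneratorParams(a, c, b),
                                    weibull_baseline(1.7, 1.2)))
    return out


@pytest.fixture(scope="session")
def sweep():
    return param_grid()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
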