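import numpy as np
import pytest

import v1circuit as v
from v1circuit.linear import LinearResponseModel
from v1circuit.meanfield import operating_point


@pytest.fixture(scope="session")
def toy_real():
    """Small eight-population network (200 neurons) for desk-scale checks."""
    spec = v.toy_spec(n_per_pop=25)
    return v.build(spec, structure_seed=42)


@pytest.fixture(scope="session")
def toy_op(toy_real):
    return operating_point(toy_real)


@pytest.fixture(scope="session")
def toy_lin(toy_real, toy_op):
    return LinearResponseModel(toy_real).fit(op=toy_op)


@pytest.fixture(scope="session")
def real01():
    """Downscale-0.1 standard network shared by the heavier end-to-end tests."""
    return v.build(v.downscale(v.standard_spec(), 0.1), structure_seed=12345)


@pytest.fixture(scope="session")
def lin01(real01):
    from v1circuit.meanfield import population_rates
    x0 = population_rates(real01.spec, "operating")[real01.pop_of]
    return LinearResponseModel(real01).fit(op=operating_point(real01, x0=x0))


@pytest.fixture(scope="session")
def cosine_grid():
    """The standard 12-angle grid with a perfect cosine tuning curve factory."""
    angles = np.arange(0.0, 180.0, 15.0)

    def make(f0=10.0, m=0.3, phi=30.0):
        return f0 * (1.0 + m * np.cos(2.0 * np.radians(angles - phi)))

    return angles, make
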