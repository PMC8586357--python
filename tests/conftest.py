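import numpy as np
import pytest

from bekinet import RateSet, ReducedParams

#: Calibrated A3A-style parameter set used throughout the tests:
#: gamma1=2.1, gamma2=11.4, gamma3=2.9e-5, m=0, ddE0=6 k_B*T.
CALIBRATION = dict(gamma1=2.1, gamma2=11.4, gamma3=2.9e-5, m=0.0, ddE0=6.0, ddEm=0.0)


@pytest.fixture
def calib_params() -> ReducedParams:
    return ReducedParams(**CALIBRATION)


def random_rate_set(rng: np.random.Generator, low: float = -2.0, high: float = 2.0) -> RateSet:
    """Log-uniform random rate set with u1 == u2 not enforced."""
    v = 10.0 ** rng.uniform(low, high, size=8)
    return RateSet(
        u0=v[0], u1=v[1], u2=v[2], u3=v[3], u4=v[4],
        w0=v[5], w1=v[6], w2=v[7], m=float(rng.uniform(0.0, 1.0)),
    )


def random_reduced(rng: np.random.Generator) -> ReducedParams:
    return ReducedParams(
        gamma1=10.0 ** rng.uniform(-3, 2),
        gamma2=10.0 ** rng.uniform(-3, 2),
        gamma3=10.0 ** rng.uniform(-6, 1),
        m=float(rng.uniform(0.0, 1.0)),
        ddE0=float(rng.uniform(-20, 20)),
        ddEm=float(rng.uniform(-20, 20)),
    )
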