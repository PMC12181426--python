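import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import rnasilencing as rs

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture
def params():
    """Reference rate constants (the defaults)."""
    return rs.ModelParameters()


@pytest.fixture
def table_initial():
    """Reference low-dose initial state (S, R, C, M) = (10, 0, 0, 1000)."""
    return rs.State(10.0, 0.0, 0.0, 1000.0)


def random_parameters(rng: np.random.Generator) -> rs.ModelParameters:
    """Log-uniform draw over [0.3x, 3x] each default rate; n in [1.2, 15]."""
    base = rs.ModelParameters()
    kwargs = {}
    for name in ("iota_a", "iota_b", "iota_c", "iota_h", "iota_g",
                 "iota_m", "iota_r"):
        v = getattr(base, name)
        kwargs[name] = float(np.exp(rng.uniform(np.log(0.3 * v), np.log(3.0 * v))))
    kwargs["n"] = float(np.exp(rng.uniform(np.log(1.2), np.log(15.0))))
    return rs.ModelParameters(**kwargs)
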