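import numpy as np
import pytest

from gaitadapt.events import AsymmetrySeries
from gaitadapt.fitting import PSOConfig
from gaitadapt.protocol import TrialType, build_protocol


@pytest.fixture
def ts_protocol():
    return build_protocol(TrialType.TS, 1.1, 1.1)


@pytest.fixture
def tc_protocol():
    return build_protocol(TrialType.TC, 1.1, 1.1)


@pytest.fixture
def fast_pso():
    """Reduced-budget optimizer for structural tests where speed matters
    more than tight convergence."""
    return PSOConfig(swarm_size=20, max_iterations=150, restarts=2, seed=0)


def exponential_series(a, b, d, f, c, noise_sd, seed, duration=900.0,
                       stride_time=1.1, parameter="step_length"):
    """Jittered-stride double-exponential series with known truth."""
    rng = np.random.default_rng(seed)
    n = int(duration / stride_time)
    t = np.cumsum(stride_time
                  * (1 + 0.02 * rng.standard_normal(n))) - stride_time
    y = a * np.exp(-b * t) + d * np.exp(-f * t) + c
    y = y + noise_sd * rng.standard_normal(n)
    return AsymmetrySeries(parameter, t, y)
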