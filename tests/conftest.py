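import numpy as np
import pytest

from qpspindle import QPSParams, simulate_spindle

# The benchmark simulated spindle: symmetric Gaussian envelope, 75 rad/s
# (~11.94 Hz) carrier, no frequency sweep, on the standard 256-sample
# centered 1 s axis at 256 Hz.
BENCHMARK = QPSParams(0.0, 0.0, -20.0, 0.0, 75.0, 0.0)
# The skewed high-amplitude spindle used in the delta-background study.
DELTA_TRUE = QPSParams(5.0, 4.0, -30.0, 1.0, 70.0, 5.0)


@pytest.fixture
def benchmark_params():
    return BENCHMARK


@pytest.fixture
def benchmark_segment():
    return simulate_spindle(BENCHMARK, n=256, fs=256.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_spindle_params(rng, n=1):
    """Draw canonical spindle-range parameter sets (the identifiability box)."""
    draws = [
        QPSParams(
            rng.uniform(0.0, 4.0),
            rng.uniform(-3.0, 3.0),
            rng.uniform(-60.0, -10.0),
            rng.uniform(-np.pi, np.pi),
            2.0 * np.pi * rng.uniform(11.0, 16.0),
            rng.uniform(-20.0, 20.0),
        )
        for _ in range(n)
    ]
    return draws[0] if n == 1 else draws
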