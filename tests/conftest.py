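import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tacdec as td

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def collapse_params():
    """High deception efficiency: deceivers dominate conditional cooperators."""
    return td.GameParams(b=1.5, c=0.5, s=0.2, d=0.1, q_mode="constant", q=0.8)


@pytest.fixture
def bistable_params():
    """Low efficiency, high deception cost: deceivers cannot invade."""
    return td.GameParams(b=1.5, c=0.5, s=0.2, d=0.45, q_mode="constant", q=0.5)


@pytest.fixture
def freq_dep_params():
    """Frequency-dependent detection (q = 1 - x_TD) with a stable mixture."""
    return td.GameParams(b=1.5, c=0.5, s=0.2, d=0.1, q_mode="freq_dependent")


def random_valid_params(rng: np.random.Generator, q_mode: str) -> td.GameParams:
    """Sample parameters satisfying b - c > s b > 0, 0 < s < 1, c > d > 0."""
    while True:
        s = rng.uniform(0.05, 0.6)
        b = rng.uniform(0.5, 3.0)
        c_hi = b * (1.0 - s)
        c = rng.uniform(0.05 * c_hi, 0.95 * c_hi)
        d = rng.uniform(0.05 * c, 0.95 * c)
        try:
            if q_mode == "constant":
                return td.GameParams(b=b, c=c, s=s, d=d, q_mode="constant",
                                     q=rng.uniform(0.05, 1.0))
            return td.GameParams(b=b, c=c, s=s, d=d, q_mode="freq_dependent")
        except td.game.GameParameterError:  # pragma: no cover - resample
            continue


def euler_replicator(starts: np.ndarray, params: td.GameParams,
                     t_end: float, h: float = 1e-4) -> np.ndarray:
    """Naive fixed-step (forward Euler) replicator map, vectorized over rows.

    Independent oracle for the adaptive integrator: nothing here is shared
    with tacdec.game beyond the payoff definition written out explicitly.
    """
    X = np.array(starts, dtype=float)
    b, c, s, d = params.b, params.c, params.s, params.d
    for _ in range(int(round(t_end / h))):
        q = params.q if params.q_mode == "constant" else 1.0 - X[:, 1]
        eff = q + s - q * s
        pi = np.empty_like(X)
        pi[:, 0] = (b - c) * X[:, 0] - c * eff * X[:, 1] - c * s * X[:, 2]
        pi[:, 1] = b * eff * X[:, 0] - d
        pi[:, 2] = b * s * X[:, 0]
        mean = np.sum(pi * X, axis=1, keepdims=True)
        X = X + h * X * (pi - mean)
    return X
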