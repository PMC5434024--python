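import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from socialbandit import ModelParams, StrategyProfile

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: reference parameter set used throughout (the regime case with a clearly
#: interior equilibrium)
REF = dict(N=10, q_C=0.2, q_I=0.3, q_O=0.8)


@pytest.fixture
def ref_params() -> ModelParams:
    return ModelParams(**REF)


def draw_valid_params(rng: np.random.Generator, N: int | None = None) -> ModelParams:
    """A random admissible parameter set (no regime constraint)."""
    if N is None:
        N = int(rng.integers(1, 11))
    q_C = float(rng.uniform(0.05, min(0.9, 0.9 * N)))
    q_I = float(rng.uniform(0.05, 1.0))
    q_O = float(rng.uniform(0.05, 1.0))
    return ModelParams(N=N, q_C=q_C, q_I=q_I, q_O=q_O)


def draw_profile(rng: np.random.Generator, N: int) -> StrategyProfile:
    return StrategyProfile(rng.uniform(0.0, 0.95, size=N))


def regime_threshold(N: int, q_C: float, q_O: float) -> float:
    """q_I value at which the equilibrium social-learning rate vanishes."""
    a = q_C / (1 - q_C / N)
    return ((N - 1) * q_O - a) / N


def draw_regime_params(rng: np.random.Generator, slack: float = 0.05) -> ModelParams:
    """Random parameters strictly inside the positive-equilibrium regime."""
    for _ in range(1000):
        N = int(rng.integers(2, 11))
        q_C = float(rng.uniform(0.05, 0.8))
        q_O = float(rng.uniform(0.3, 1.0))
        thr = regime_threshold(N, q_C, q_O)
        if thr <= 0.06:
            continue
        q_I = float(rng.uniform(0.05, (1 - slack) * thr))
        if q_I >= 0.05:
            return ModelParams(N=N, q_C=q_C, q_I=q_I, q_O=q_O)
    raise RuntimeError("could not draw regime parameters")


def golden_section_max(fn, lo: float, hi: float, tol: float = 1e-10) -> float:
    """Golden-section maximiser of a unimodal scalar function; independent
    oracle for the closed-form optimum.

    Pure golden-section stalls near sqrt(eps) because the function is flat
    at the peak, so once the interval is small the position is polished by
    bisecting on the sign of a central difference, which stays resolvable
    down to ~1e-10.
    """
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    while b - a > 1e-6:
        if fn(c) > fn(d):
            b, d = d, c
            c = b - invphi * (b - a)
        else:
            a, c = c, d
            d = a + invphi * (b - a)
    h = 1e-5
    a, b = max(lo + h, a - 1e-4), min(hi - h, b + 1e-4)
    if fn(a + h) - fn(a - h) <= 0:
        # still decreasing at the left edge: the maximum is the boundary
        return lo if a - lo <= h + 1e-4 else a
    if fn(b + h) - fn(b - h) >= 0:
        return hi if hi - b <= h + 1e-4 else b
    while b - a > tol:
        mid = 0.5 * (a + b)
        if fn(mid + h) - fn(mid - h) > 0:
            a = mid
        else:
            b = mid
    return 0.5 * (a + b)
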