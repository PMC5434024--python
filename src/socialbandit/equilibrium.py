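"""Best response, Nash/ESS and Pareto solvers, and auxiliary certificates.

An agent maximising its own steady-state fitness against a mean opponent
strategy ``rbar`` has a unique best response ``f(rbar)``: zero whenever
copying is no better than searching (``q_O <= q_I``), otherwise the clamp
to [0, 1] of

    fbar(rbar) = ( -zeta + sqrt(q_O (N-1)(1-rbar)) * sqrt(zeta) )
                 / (q_O - q_I),
    zeta       = a + q_I + q_I (N-1)(1-rbar).

The best-response map has a unique fixed point, homogeneous across agents,
which is both the unique Nash equilibrium and an evolutionarily stable
strategy (in the strong, Thomas sense).  It is positive exactly when
``(q_O - q_I) N > a + q_O``; in that regime the welfare-maximising
(Pareto) point lies strictly below it, and the common fitness values order
as ``w_P > w_N > w_I``.  Everything here is closed form; the numeric
solvers (bisection and damped fixed-point iteration) exist as independent
cross-checks, and the auxiliary quantities (``r*``, ``r_*``, the quadratic
``k`` and the point ``r_I`` with ``w(r_I, r_I) = w_I``) certify the
uniqueness and ordering arguments numerically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .model import (
    InvalidParameterError,
    ModelParams,
    StrategyProfile,
    fitness_closed,
)

__all__ = [
    "EquilibriumSolution",
    "AuxiliaryCurves",
    "ESSCertificate",
    "best_response",
    "best_response_unclamped",
    "response_map",
    "solve_nash_closed",
    "solve_nash_bisection",
    "solve_nash_fixed_point",
    "pareto_closed",
    "auxiliary_points",
    "verify_ess",
    "fitness_ordering",
    "solve",
    "fixed_point_cells",
]


class SolverError(RuntimeError):
    """A numeric guarantee failed (negative radicand, no convergence)."""


def _sqrt_checked(x: float, what: str) -> float:
    # raise instead of clamping: a negative radicand means a transcription bug
    if x < 0:
        raise SolverError(f"negative radicand in {what}: {x}")
    return math.sqrt(x)


def zeta(params: ModelParams, rbar: float) -> float:
    """``zeta = a + q_I + q_I (N-1)(1-rbar)``, the denominator scale of the
    unclamped best response."""
    return params.a + params.q_I + params.q_I * (params.N - 1) * (1.0 - rbar)


def best_response_unclamped(params: ModelParams, rbar: float) -> float:
    """Unclamped best response ``fbar(rbar)`` (only defined for q_O > q_I)."""
    if params.q_O <= params.q_I:
        raise InvalidParameterError("fbar is defined only for q_O > q_I")
    z = zeta(params, rbar)
    root = _sqrt_checked(
        params.q_O * (params.N - 1) * (1.0 - rbar), "fbar"
    ) * _sqrt_checked(z, "fbar")
    return (-z + root) / (params.q_O - params.q_I)


def best_response(params: ModelParams, rbar: float) -> float:
    """Unique fitness-maximising social-learning probability ``f(rbar)``.

    Zero when ``q_O <= q_I``; otherwise ``fbar`` clamped to [0, 1].
    Non-increasing in ``rbar``: the more the others copy, the less there is
    worth copying.
    """
    if not (0.0 <= rbar <= 1.0):
        raise InvalidParameterError(f"rbar={rbar} outside [0, 1]")
    if params.q_O <= params.q_I:
        return 0.0
    return min(1.0, max(0.0, best_response_unclamped(params, rbar)))


def response_map(params: ModelParams, profile: StrategyProfile) -> np.ndarray:
    """Simultaneous best-response map: component ``n`` is
    ``f(rbar_n)``.  Returns a plain vector (its entries may hit 1, which a
    StrategyProfile would reject)."""
    return np.array([best_response(params, rb) for rb in profile.rbar_all()])


# --------------------------------------------------------------------------
# Nash equilibrium


@dataclass(frozen=True)
class EquilibriumSolution:
    """Nash and Pareto points with the intermediates used to compute them."""

    r_nash: float
    eta: float | None
    D1: float | None
    r_pareto: float
    X: float | None
    Y: float | None
    r_I: float | None
    regime: bool
    w_I: float
    w_N: float
    w_P: float

    def to_dict(self) -> dict:
        return {
            "r_Nash": self.r_nash,
            "eta": self.eta,
            "D1": self.D1,
            "r_Pareto": self.r_pareto,
            "X": self.X,
            "Y": self.Y,
            "r_I": self.r_I,
            "regime": self.regime,
            "w_I": self.w_I,
            "w_N": self.w_N,
            "w_P": self.w_P,
        }


def _nash_intermediates(params: ModelParams) -> tuple[float, float]:
    a, N, q_I, q_O = params.a, params.N, params.q_I, params.q_O
    D1 = (
        (N - 1)
        * q_O
        * (
            -(4 * a * N + 3 * q_O * N + q_O) * q_I**2
            + 2 * (3 * a * q_O * N + 2 * q_O**2 * N - 2 * a**2 - 3 * a * q_O) * q_I
            + a * q_O * (a * N + 3 * a + 4 * q_O)
        )
    )
    if D1 < 0:
        raise SolverError(f"discriminant D1 negative in the regime: {D1}")
    eta = (
        2 * (a + q_O) ** 2
        / (
            (q_O - q_I * N) * (a + q_O)
            + (a * N + q_O) * (q_O - q_I)
            + math.sqrt(D1)
        )
    )
    return eta, D1


def solve_nash_closed(params: ModelParams) -> tuple[float, float | None, float | None]:
    """Closed-form Nash social-learning probability.

    Returns ``(r_nash, eta, D1)``; ``r_nash = 1 - eta`` in the regime
    ``(q_O - q_I) N > a + q_O``, otherwise 0 with the intermediates None.
    The boundary case is classified as outside the regime.
    """
    if not params.regime:
        return 0.0, None, None
    eta, D1 = _nash_intermediates(params)
    r = 1.0 - eta
    if not (0.0 <= r < 1.0):
        raise SolverError(f"closed-form r_Nash={r} escaped [0, 1)")
    return r, eta, D1


def solve_nash_bisection(
    params: ModelParams, tol: float = 1e-10, max_iter: int = 200
) -> float:
    """Nash point as the unique root of ``h(r) = r - f(r)`` on [0, 1).

    ``f`` is non-increasing, so ``h`` is strictly increasing and bisection
    converges unconditionally; ``h(0) <= 0 <= h(1)`` is verified before
    iterating.
    """
    if tol <= 0:
        raise InvalidParameterError("tol must be positive")
    f = lambda r: best_response(params, r)
    lo, hi = 0.0, 1.0
    h_lo = lo - f(lo)
    h_hi = hi - f(hi)
    if h_lo > 0 or h_hi < 0:
        raise SolverError("bracketing h(0) <= 0 <= h(1) failed")
    if h_lo == 0.0:
        return 0.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if mid - f(mid) <= 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            return 0.5 * (lo + hi)
    raise SolverError(f"bisection did not reach tol={tol} in {max_iter} iterations")


def solve_nash_fixed_point(
    params: ModelParams,
    tol: float = 1e-12,
    damping: float | None = None,
    max_iter: int = 100_000,
) -> float:
    """Nash point by damped fixed-point iteration ``r <- (1-d) r + d f(r)``.

    A secondary cross-check of the closed form.  The slope of the
    unclamped response is bounded by ``(N-1)/2`` in magnitude (the
    self-consistency map's slope peaks at 1/2), so the default damping
    ``d = 2/(N+1)`` makes the damped map a contraction; a fixed damping
    would oscillate for steep response curves.
    """
    if damping is None:
        damping = min(0.5, 2.0 / (params.N + 1))
    if tol <= 0 or not (0 < damping <= 1):
        raise InvalidParameterError("need tol > 0 and damping in (0, 1]")
    r = 0.5
    for _ in range(max_iter):
        r_new = (1.0 - damping) * r + damping * best_response(params, r)
        if abs(r_new - r) < tol * damping:
            return r_new
        r = r_new
    raise SolverError(f"fixed-point iteration did not converge to tol={tol}")


# --------------------------------------------------------------------------
# Pareto optimum


def pareto_closed(params: ModelParams) -> tuple[float, float | None, float | None]:
    """Closed-form welfare optimum on the diagonal.

    Returns ``(r_pareto, X, Y)`` with
    ``r_pareto = ((a + q_I N) X - (a + q_I) Y) / (q_I N X + (q_O - q_I) Y)``,
    ``X = sqrt((N-1)(a + q_O)(q_O - q_I))`` and
    ``Y = sqrt((a + N q_I) N q_O)`` in the regime, else 0.
    """
    if not params.regime:
        return 0.0, None, None
    a, N, q_I, q_O = params.a, params.N, params.q_I, params.q_O
    X = _sqrt_checked((N - 1) * (a + q_O) * (q_O - q_I), "X")
    Y = _sqrt_checked((a + N * q_I) * N * q_O, "Y")
    r = ((a + q_I * N) * X - (a + q_I) * Y) / (q_I * N * X + (q_O - q_I) * Y)
    if not (0.0 <= r < 1.0):
        raise SolverError(f"closed-form r_Pareto={r} escaped [0, 1)")
    return r, X, Y


# --------------------------------------------------------------------------
# Auxiliary curves used by the uniqueness/ordering arguments


@dataclass(frozen=True)
class AuxiliaryCurves:
    """Certificate material for uniqueness and fitness ordering.

    ``r_star_hi`` (written r*) is where the unclamped best response
    crosses zero and ``r_star_lo`` (r_*) where it crosses one, so the
    clamp-free band of mean strategies is ``[r_star_lo, r_star_hi]`` with
    ``r_star_lo < r_star_hi < 1``.  ``k`` is the quadratic in
    ``u = 1/(1-r)`` whose larger root sits at the Nash point, and ``r_I``
    is the homogeneous strategy whose common fitness equals the pure
    individual learner's (``w(r_I, r_I) = w_I``).
    """

    r_star_hi: float
    r_star_lo: float
    D2: float
    r_I: float
    k: Callable[[float], float]
    defined: bool

    def g(self, s: float) -> Callable[[float], float]:
        """Self-consistency map ``g(r) = f((s - r)/(N - 1))`` for a profile
        with entry sum ``s`` (attached at construction time)."""
        return self._g_factory(s)

    # set post-construction to keep the dataclass frozen and simple
    _g_factory: Callable[[float], Callable[[float], float]] = None  # type: ignore

    def g_domain(self, s: float) -> tuple[float, float]:
        """Clamp-free interval ``[s - (N-1) r*, s - (N-1) r_*]`` on which
        ``g`` is strictly increasing and concave."""
        return (
            s - self._N_minus_1 * self.r_star_hi,
            s - self._N_minus_1 * self.r_star_lo,
        )

    _N_minus_1: int = 0


def auxiliary_points(params: ModelParams) -> AuxiliaryCurves:
    """Compute ``r*``, ``r_*`` (with discriminant ``D2``), the quadratic
    ``k`` and the individual-learner-equivalent point ``r_I``.

    Requires ``q_O > q_I``; otherwise the curves are undefined and the
    returned object is flagged accordingly.
    """
    a, N, q_I, q_O = params.a, params.N, params.q_I, params.q_O

    def k(u: float) -> float:
        # derived by squaring the interior fixed-point equation r = fbar(r)
        # in the variable u = 1/(1-r); the constant coefficient factors as
        # (q_O - q_I)(q_O - q_I N^2)
        return (
            (a + q_O) ** 2 * u**2
            - ((q_O - q_I * N) * (a + q_O) + (a * N + q_O) * (q_O - q_I)) * u
            + (q_O - q_I) * (q_O - q_I * N**2)
        )

    if q_O <= q_I or N < 2:
        curves = AuxiliaryCurves(
            r_star_hi=math.nan,
            r_star_lo=math.nan,
            D2=math.nan,
            r_I=math.nan,
            k=k,
            defined=False,
        )
        object.__setattr__(curves, "_N_minus_1", N - 1)
        object.__setattr__(curves, "_g_factory", lambda s: (lambda r: 0.0))
        return curves

    r_star_hi = 1.0 - (a + q_I) / ((N - 1) * (q_O - q_I))
    b = q_O * (a - q_I) - 2 * a * q_I
    D2 = b**2 + 4 * q_I * (q_O - q_I) * (a + q_O) ** 2
    if D2 < 0:
        raise SolverError(f"discriminant D2 negative: {D2}")
    r_star_lo = 1.0 - (-b + math.sqrt(D2)) / (2 * (N - 1) * q_I * (q_O - q_I))
    r_I = 1.0 - (a + q_O) / ((q_O - q_I) * N)

    def g_factory(s: float) -> Callable[[float], float]:
        def g(r: float) -> float:
            return best_response(params, min(1.0, max(0.0, (s - r) / (N - 1))))

        return g

    curves = AuxiliaryCurves(
        r_star_hi=r_star_hi,
        r_star_lo=r_star_lo,
        D2=D2,
        r_I=r_I,
        k=k,
        defined=True,
    )
    object.__setattr__(curves, "_N_minus_1", N - 1)
    object.__setattr__(curves, "_g_factory", g_factory)
    return curves


def g_unclamped(params: ModelParams, s: float, r: float) -> float:
    """Self-consistency map ``g(r) = fbar((s - r)/(N - 1))`` without the
    [0, 1] clamp, for slope studies on the clamp-free band."""
    return best_response_unclamped(params, (s - r) / (params.N - 1))


# --------------------------------------------------------------------------
# Certificates


@dataclass(frozen=True)
class ESSCertificate:
    """Grid certificate of the two strict equilibrium inequalities:
    no unilateral deviation pays (``w(r_N, r_N) > w(r, r_N)``) and the
    equilibrium strategy invades any monomorphic deviant population
    (``w(r_N, r) > w(r, r)``), checked away from a small exclusion ball
    around the equilibrium."""

    grid_size: int
    margin: float
    r_nash: float
    worst_slack_nash: float
    worst_slack_ess: float
    passed: bool


def verify_ess(
    params: ModelParams, grid_size: int = 1001, margin: float = 1e-9
) -> ESSCertificate:
    """Check the strict Nash and ESS inequalities on a uniform grid.

    The grid spans [0, 1); points within two grid steps of the equilibrium
    are excluded (the slack vanishes quadratically there).  ``passed`` is
    True when both worst-case slacks exceed ``margin``.
    """
    if margin <= 0:
        raise InvalidParameterError("margin must be positive")
    r_nash, _, _ = solve_nash_closed(params)
    grid = np.linspace(0.0, 1.0 - 1e-9, grid_size)
    step = grid[1] - grid[0]
    w_nn = fitness_closed(params, r_nash, r_nash)
    slack_nash = math.inf
    slack_ess = math.inf
    for r in grid:
        if abs(r - r_nash) <= 2 * step:
            continue
        slack_nash = min(slack_nash, w_nn - fitness_closed(params, float(r), r_nash))
        slack_ess = min(
            slack_ess,
            fitness_closed(params, r_nash, float(r))
            - fitness_closed(params, float(r), float(r)),
        )
    passed = slack_nash > margin and slack_ess > margin
    return ESSCertificate(
        grid_size=grid_size,
        margin=margin,
        r_nash=r_nash,
        worst_slack_nash=slack_nash,
        worst_slack_ess=slack_ess,
        passed=passed,
    )


def fitness_ordering(params: ModelParams) -> tuple[float, float, float, bool]:
    """Common fitness at the Pareto, Nash and individual-learning points.

    Returns ``(w_P, w_N, w_I, regime)``.  In the regime the three are
    strictly ordered ``w_P > w_N > w_I``; otherwise all equal
    ``q_I / (a + q_I)``.
    """
    r_nash, _, _ = solve_nash_closed(params)
    r_pareto, _, _ = pareto_closed(params)
    w_I = params.q_I / (params.a + params.q_I)
    w_N = fitness_closed(params, r_nash, r_nash)
    w_P = fitness_closed(params, r_pareto, r_pareto)
    return w_P, w_N, w_I, params.regime


def solve(params: ModelParams) -> EquilibriumSolution:
    """Full equilibrium report: Nash and Pareto points, intermediates and
    the three ordered fitness values."""
    r_nash, eta, D1 = solve_nash_closed(params)
    r_pareto, X, Y = pareto_closed(params)
    w_P, w_N, w_I, regime = fitness_ordering(params)
    r_I = None
    if params.q_O > params.q_I and params.N >= 2:
        r_I = auxiliary_points(params).r_I
    return EquilibriumSolution(
        r_nash=r_nash,
        eta=eta,
        D1=D1,
        r_pareto=r_pareto,
        X=X,
        Y=Y,
        r_I=r_I,
        regime=regime,
        w_I=w_I,
        w_N=w_N,
        w_P=w_P,
    )


def fixed_point_cells(
    params: ModelParams, grid_size: int = 201
) -> list[tuple[int, int]]:
    """Scan the two-agent best-response vector field
    ``(f(r_2) - r_1, f(r_1) - r_2)`` on a ``grid_size``² lattice and return
    the cells where both components change sign — the discrete fixed-point
    candidates.  For valid parameters exactly one cell is found, at the
    homogeneous equilibrium."""
    if params.N != 2:
        raise InvalidParameterError("the vector-field scan is defined for N = 2")
    grid = np.linspace(0.0, 1.0, grid_size)
    f_vals = np.array([best_response(params, g) for g in grid])
    # component fields on the lattice: U[i, j] = f(r2_j) - r1_i
    U = f_vals[None, :] - grid[:, None]
    V = f_vals[:, None] - grid[None, :]
    cells = []
    for i in range(grid_size - 1):
        for j in range(grid_size - 1):
            u = U[i : i + 2, j : j + 2]
            v = V[i : i + 2, j : j + 2]
            if u.min() <= 0 <= u.max() and v.min() <= 0 <= v.max():
                cells.append((i, j))
    return cells
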