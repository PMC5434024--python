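"""Parameter/strategy data model and closed-form steady-state fitness.

The system is a population of ``N`` agents facing a restless bandit with a
single good arm.  Per turn one agent acts; an uninformed agent searches on
its own (success probability ``q_I``) or copies an informed agent (success
probability ``q_O``, possible only while somebody is informed), choosing
the social option with its personal probability ``r_n``.  The good arm
resets with probability ``q_C / N`` per turn, wiping everyone's knowledge.

An agent's fitness is the steady-state probability that it knows the good
arm.  For agent ``n`` playing ``r_n`` against a leave-one-out mean strategy
``rbar_n`` it has the closed form::

    w(r, rbar) = [ q_I + (q_O - q_I) r
                   - a q_O r / (a + (N-1) q_I (1-rbar) + q_I (1-r)) ]
                 / (a + q_I + (q_O - q_I) r)

with the effective turnover rate ``a = q_C / (1 - q_C / N)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ModelParams",
    "StrategyProfile",
    "FitnessReport",
    "GroupFitness",
    "effective_rate",
    "fitness_closed",
    "fitness_profile",
    "group_fitness",
    "asymptotic_fitness",
]

#: slack used when validating probabilities against open boundaries
BOUNDARY_TOL = 1e-12


class InvalidParameterError(ValueError):
    """A model parameter violates the admissible region."""


@dataclass(frozen=True)
class ModelParams:
    """Environment and population parameters.

    Parameters
    ----------
    N : int
        Number of agents, at least 1.
    q_C : float
        Arm-turnover scale; the good arm resets with probability ``q_C/N``
        per turn.  Must satisfy ``0 < q_C`` and ``q_C / N < 1``.
    q_I : float
        Individual-learning (random search) success probability, in (0, 1].
    q_O : float
        Social-learning (copy) success probability, in (0, 1].
    """

    N: int
    q_C: float
    q_I: float
    q_O: float

    def __post_init__(self) -> None:
        if int(self.N) != self.N or self.N < 1:
            raise InvalidParameterError(f"N must be a positive integer, got {self.N}")
        object.__setattr__(self, "N", int(self.N))
        if not self.q_C > 0:
            raise InvalidParameterError(f"q_C must be positive, got {self.q_C}")
        if not self.q_C / self.N < 1:
            raise InvalidParameterError(
                f"q_C/N must be below 1 (q_C={self.q_C}, N={self.N})"
            )
        for name in ("q_I", "q_O"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise InvalidParameterError(f"{name} must lie in (0, 1], got {v}")

    @property
    def a(self) -> float:
        """Effective turnover rate ``a = q_C / (1 - q_C/N)``; recomputed on access."""
        return self.q_C / (1.0 - self.q_C / self.N)

    @property
    def regime(self) -> bool:
        """True when ``(q_O - q_I) N > a + q_O``, the region with a positive
        equilibrium social-learning probability."""
        return (self.q_O - self.q_I) * self.N > self.a + self.q_O

    def to_dict(self) -> dict:
        return {"N": self.N, "q_C": self.q_C, "q_I": self.q_I, "q_O": self.q_O}

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(N=d["N"], q_C=d["q_C"], q_I=d["q_I"], q_O=d["q_O"])

    @classmethod
    def from_json(cls, s: str) -> "ModelParams":
        return cls.from_dict(json.loads(s))


def effective_rate(params: ModelParams) -> float:
    """Effective per-turn turnover rate ``a = q_C / (1 - q_C/N)``.

    Strictly increasing in ``q_C``, strictly decreasing in ``N``; tends to
    ``q_C`` as ``N`` grows.
    """
    return params.a


@dataclass(frozen=True)
class StrategyProfile:
    """A point ``(r_1, ..., r_N)`` in the mixed-strategy cube.

    Each ``r_n`` is the probability that agent ``n``, when uninformed,
    attempts to copy rather than search.  Entries must lie in ``[0, 1)``;
    ``r_n = 1`` (a pure social learner) breaks ergodicity of the chain and
    is rejected at construction.
    """

    r: np.ndarray

    def __post_init__(self) -> None:
        r = np.atleast_1d(np.asarray(self.r, dtype=float))
        if r.ndim != 1 or r.size < 1:
            raise InvalidParameterError("profile must be a non-empty vector")
        if np.any(r < -BOUNDARY_TOL) or np.any(r >= 1.0 - BOUNDARY_TOL):
            raise InvalidParameterError(
                "strategy entries must lie in [0, 1); pure social learning "
                "(r = 1) is outside the admissible region"
            )
        r = np.clip(r, 0.0, None)
        r.setflags(write=False)
        object.__setattr__(self, "r", r)

    @classmethod
    def homogeneous(cls, r: float, N: int) -> "StrategyProfile":
        return cls(np.full(N, float(r)))

    @property
    def N(self) -> int:
        return self.r.size

    @property
    def s(self) -> float:
        """Sum of all entries."""
        return float(self.r.sum())

    def rbar(self, n: int) -> float:
        """Leave-one-out mean strategy ``(s - r_n) / (N - 1)`` seen by agent
        ``n`` (0-based).  Defined as 0 for a single agent, where the mean
        over others is vacuous and never enters the fitness."""
        if self.N == 1:
            return 0.0
        return (self.s - self.r[n]) / (self.N - 1)

    def rbar_all(self) -> np.ndarray:
        if self.N == 1:
            return np.zeros(1)
        return (self.s - self.r) / (self.N - 1)

    @property
    def is_homogeneous(self) -> bool:
        return bool(np.all(self.r == self.r[0]))

    def to_dict(self) -> dict:
        if self.is_homogeneous:
            return {"r": float(self.r[0]), "N": self.N}
        return {"r": [float(x) for x in self.r]}

    @classmethod
    def from_dict(cls, d: dict, N: int | None = None) -> "StrategyProfile":
        r = d["r"]
        if np.isscalar(r):
            n = d.get("N", N)
            if n is None:
                raise InvalidParameterError(
                    "scalar r requires N to expand a homogeneous profile"
                )
            return cls.homogeneous(float(r), int(n))
        return cls(np.asarray(r, dtype=float))


@dataclass(frozen=True)
class FitnessReport:
    """Per-agent steady-state fitness values, each the probability of
    knowing the good arm, hence in [0, 1]."""

    w: np.ndarray
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        w.setflags(write=False)
        object.__setattr__(self, "w", w)


def fitness_closed(
    params: ModelParams, r: float, rbar: float, *, allow_boundary: bool = False
) -> float:
    """Closed-form steady-state fitness ``w(r, rbar)``.

    ``r`` is the focal agent's social-learning probability and ``rbar``
    the mean over the other ``N - 1`` agents.  The admissible domain is
    ``[0, 1)^2``; with ``allow_boundary=True`` the formula is also evaluated
    at ``r = 1`` or ``rbar = 1`` (used for pure-strategy cross-checks, where
    the limit is still well defined).
    """
    hi = 1.0 + BOUNDARY_TOL if allow_boundary else 1.0 - BOUNDARY_TOL
    if not (-BOUNDARY_TOL <= r <= hi) or not (-BOUNDARY_TOL <= rbar <= hi):
        raise InvalidParameterError(f"(r, rbar)=({r}, {rbar}) outside the domain")
    a, N, q_I, q_O = params.a, params.N, params.q_I, params.q_O
    inner_den = a + (N - 1) * q_I * (1.0 - rbar) + q_I * (1.0 - r)
    if inner_den <= 0:  # impossible for valid parameters
        raise ArithmeticError("non-positive inner denominator in fitness")
    num = q_I + (q_O - q_I) * r - a * q_O * r / inner_den
    return num / (a + q_I + (q_O - q_I) * r)


def fitness_profile(params: ModelParams, profile: StrategyProfile) -> FitnessReport:
    """Per-agent fitness ``w_n = w(r_n, rbar_n)`` for a full profile."""
    if profile.N != params.N:
        raise InvalidParameterError(
            f"profile length {profile.N} does not match N={params.N}"
        )
    rb = profile.rbar_all()
    w = np.array(
        [fitness_closed(params, float(profile.r[n]), float(rb[n])) for n in range(params.N)]
    )
    return FitnessReport(w=w)


@dataclass(frozen=True)
class GroupFitness:
    """Pure-strategy fitness pair for a split population: ``N_I``
    individual learners (r = 0) against ``N - N_I`` social learners
    (r = 1).  ``vacuous_social`` flags ``N_I = N``, where no social learner
    exists and ``w_S`` is reported only formally."""

    w_I: float
    w_S: float
    N_I: int
    vacuous_social: bool


def group_fitness(params: ModelParams, N_I: int) -> GroupFitness:
    """Fitness of individual and social learners under pure strategies.

    ``w_I = q_I / (a + q_I)`` and
    ``w_S = N_I q_I q_O / ((a + N_I q_I)(a + q_O))``.  Social learners can
    only ever be informed if somebody searches, so ``w_S = 0`` at
    ``N_I = 0``; ``w_S`` increases with every extra individual learner.
    """
    if not (0 <= N_I <= params.N):
        raise InvalidParameterError(f"N_I must lie in [0, N], got {N_I}")
    a = params.a
    w_I = params.q_I / (a + params.q_I)
    w_S = (N_I * params.q_I * params.q_O) / ((a + N_I * params.q_I) * (a + params.q_O))
    return GroupFitness(w_I=w_I, w_S=w_S, N_I=N_I, vacuous_social=(N_I == params.N))


def asymptotic_fitness(params: ModelParams) -> tuple[float, float]:
    """Large-population limits of the pure-strategy fitness values:
    ``w_I -> q_I/(q_C+q_I)`` and ``w_S -> q_O/(q_C+q_O)`` as N grows with
    the learner fractions held fixed."""
    return (
        params.q_I / (params.q_C + params.q_I),
        params.q_O / (params.q_C + params.q_O),
    )
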