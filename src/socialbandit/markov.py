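"""Exact finite Markov chain over the agents' knowledge states.

The joint state is the vector of knowledge indicators, encoded as a
bitmask (agent ``n`` <-> bit ``n``), giving a dense ``2^N x 2^N`` chain.
One turn either resets the world (probability ``q_C/N``: the good arm
moves, every agent forgets) or lets one uniformly chosen agent act; an
uninformed chosen agent gains knowledge with probability ``q_O`` via a
copy attempt (possible only while someone is informed) or ``q_I`` via
search.  In matrix form::

    T(s'|s) = (1 - q_C/N) [ (1 - sum_n p_n(s)) d(s', s)
                            + sum_n p_n(s) d(s', s + e_n) ]
              + (q_C/N) d(s', 0)

    p_n(s)  = [sigma_n == 0] / N * ( r_n [N1 >= 1] q_O + (1 - r_n) q_I )

Columns index the source state, so distributions evolve as ``P' = T P``.
For positive rates and every ``r_n < 1`` the chain is irreducible and
aperiodic, so the stationary distribution is unique and convergence to it
is exponential with rate given by the subdominant eigenvalue modulus.

This module is the brute-force oracle for every closed form in the
package: the stationary marginals ``P(bit n set)`` are the exact per-agent
fitness values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import FitnessReport, InvalidParameterError, ModelParams, StrategyProfile

__all__ = ["MarkovChain", "build_transition", "DEFAULT_STATE_CAP"]

#: largest N for which a dense 2^N transition matrix is built by default
DEFAULT_STATE_CAP = 14


def build_transition(
    params: ModelParams, profile: StrategyProfile, cap: int = DEFAULT_STATE_CAP
) -> np.ndarray:
    """Dense column-stochastic transition matrix ``T[target, source]``.

    Raises for ``N`` above ``cap`` (the matrix is ``4^N`` entries).
    """
    N = params.N
    if profile.N != N:
        raise InvalidParameterError("profile length must equal N")
    if N > cap:
        raise InvalidParameterError(
            f"dense chain limited to N <= {cap} (requested N={N})"
        )
    n_states = 1 << N
    reset = params.q_C / N
    stay = 1.0 - reset
    r = profile.r
    T = np.zeros((n_states, n_states))
    for s in range(n_states):
        n1 = bin(s).count("1")
        informed_somewhere = n1 >= 1
        p_total = 0.0
        for n in range(N):
            if s >> n & 1:
                continue  # informed agents only exploit
            p_n = (
                (r[n] * params.q_O if informed_somewhere else 0.0)
                + (1.0 - r[n]) * params.q_I
            ) / N
            T[s | (1 << n), s] += stay * p_n
            p_total += p_n
        T[s, s] += stay * (1.0 - p_total)
        T[0, s] += reset
    return T


@dataclass
class MarkovChain:
    """Exact chain for a parameter set and strategy profile.

    The transition matrix is built eagerly; the stationary distribution
    and spectral quantities are computed lazily and cached.
    """

    params: ModelParams
    profile: StrategyProfile
    cap: int = DEFAULT_STATE_CAP
    T: np.ndarray = field(init=False, repr=False)
    _steady: np.ndarray | None = field(default=None, init=False, repr=False)
    _spectrum: tuple[float, float] | None = field(default=None, init=False, repr=False)

    def __post_init__(self) -> None:
        self.T = build_transition(self.params, self.profile, cap=self.cap)

    @property
    def n_states(self) -> int:
        return self.T.shape[0]

    def step(self, P: np.ndarray) -> np.ndarray:
        """One application of the Chapman-Kolmogorov update ``P' = T P``."""
        P = np.asarray(P, dtype=float)
        if P.shape != (self.n_states,):
            raise InvalidParameterError(
                f"distribution must have length {self.n_states}"
            )
        return self.T @ P

    def steady_state(self, tol: float = 1e-12) -> np.ndarray:
        """Unique stationary distribution of the chain.

        Solved as the linear system ``(T - I) P = 0`` with one balance row
        replaced by the normalisation constraint; falls back to power
        iteration if the solve is singular to working precision.
        """
        if self._steady is not None:
            return self._steady
        n = self.n_states
        A = self.T - np.eye(n)
        A[-1, :] = 1.0
        b = np.zeros(n)
        b[-1] = 1.0
        try:
            P = np.linalg.solve(A, b)
            if np.any(P < -1e-9):
                raise np.linalg.LinAlgError("negative stationary entries")
        except np.linalg.LinAlgError:
            P = np.full(n, 1.0 / n)
            for _ in range(1_000_000):
                P_next = self.T @ P
                if np.max(np.abs(P_next - P)) < tol:
                    P = P_next
                    break
                P = P_next
            else:
                raise RuntimeError("power iteration did not converge")
        P = np.clip(P, 0.0, None)
        P /= P.sum()
        self._steady = P
        return P

    def marginal_fitness(self) -> FitnessReport:
        """Exact per-agent fitness: stationary probability that each
        agent's knowledge bit is set."""
        P = self.steady_state()
        states = np.arange(self.n_states)
        w = np.array(
            [P[(states >> n & 1) == 1].sum() for n in range(self.params.N)]
        )
        return FitnessReport(w=w)

    def spectral_gap(self) -> tuple[float, float]:
        """Subdominant eigenvalue modulus ``rho`` and relaxation time
        ``tau = -1 / log(rho)``.

        Verifies that the unit eigenvalue is simple (Perron-Frobenius for
        an irreducible aperiodic chain).
        """
        if self._spectrum is not None:
            return self._spectrum
        eigvals = np.linalg.eigvals(self.T)
        near_one = np.abs(eigvals - 1.0) < 1e-8
        if near_one.sum() != 1:
            raise RuntimeError(
                f"unit eigenvalue multiplicity {near_one.sum()} != 1"
            )
        rest = np.abs(eigvals[~near_one])
        rho = float(rest.max()) if rest.size else 0.0
        if rho >= 1.0:
            raise RuntimeError(f"subdominant modulus rho={rho} not below 1")
        tau = -1.0 / np.log(rho) if rho > 0 else 0.0
        self._spectrum = (rho, float(tau))
        return self._spectrum

    def steady_frame(self) -> pd.DataFrame:
        """Stationary distribution as a table with columns
        ``state_bitmask``, ``N1`` (informed count) and ``probability``."""
        P = self.steady_state()
        states = np.arange(self.n_states)
        return pd.DataFrame(
            {
                "state_bitmask": states,
                "N1": [bin(int(s)).count("1") for s in states],
                "probability": P,
            }
        )
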