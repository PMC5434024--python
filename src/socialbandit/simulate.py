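"""Turn-by-turn stochastic simulation of the agent system.

The simulator replays the model narrative exactly as the transition
matrix encodes it: each turn is either a global reset (probability
``q_C/N``; the good arm moves and all knowledge is lost) or an action by
one uniformly chosen agent.  An informed agent exploits (no state
change); an uninformed one copies with probability ``r_n`` (success
``q_O``, possible only while at least one agent is informed) or searches
(success ``q_I``).  Reset and action are mutually exclusive within a
turn, matching the matrix decomposition rather than the looser
act-then-maybe-reset reading of the narrative.

Randomness comes from a single seeded generator.  Four decision streams
(reset, agent index, copy-vs-search choice, success) are pre-drawn as
per-turn arrays in that fixed order, so identical seeds give identical
traces and the stream layout is reproducible across runs and platforms.

Time averages of the knowledge indicators after a burn-in estimate the
steady-state fitness; batch means give standard errors that are honest
in the presence of the chain's autocorrelation as long as batches are
long relative to the relaxation time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import InvalidParameterError, ModelParams, StrategyProfile
from .markov import DEFAULT_STATE_CAP, MarkovChain

__all__ = [
    "SimulationTrace",
    "FitnessEstimate",
    "simulate",
    "estimate_fitness",
    "suggest_burn_in",
]

ACTION_EXPLOIT, ACTION_SEARCH, ACTION_COPY, ACTION_NONE = 0, 1, 2, -1
ACTION_LABELS = {
    ACTION_EXPLOIT: "exploit",
    ACTION_SEARCH: "search",
    ACTION_COPY: "copy",
    ACTION_NONE: "",
}


@dataclass(frozen=True)
class SimulationTrace:
    """Seeded per-turn record of a run.

    ``states[t]`` is the knowledge bitmask after turn ``t`` (agent ``n``
    <-> bit ``n``).  The event arrays describe what happened during the
    turn: ``reset`` flags a global reset, ``agent`` is the acting agent
    (-1 on reset turns), ``action`` the chosen learning mode and
    ``success`` whether the attempt paid off.
    """

    params: ModelParams
    profile: StrategyProfile
    seed: int
    turns: int
    states: np.ndarray
    reset: np.ndarray
    agent: np.ndarray
    action: np.ndarray
    success: np.ndarray

    def occupancy(self) -> np.ndarray:
        """Knowledge indicator matrix of shape (turns, N)."""
        bits = np.arange(self.params.N, dtype=np.uint64)
        return ((self.states[:, None] >> bits) & 1).astype(np.uint8)

    def n_informed(self) -> np.ndarray:
        """Informed count per turn."""
        return self.occupancy().sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Event log as a table: turn, reset_flag, chosen_agent, action,
        success, N1 (informed count after the turn)."""
        return pd.DataFrame(
            {
                "turn": np.arange(self.turns),
                "reset_flag": self.reset.astype(int),
                "chosen_agent": self.agent,
                "action": [ACTION_LABELS[int(x)] for x in self.action],
                "success": self.success.astype(int),
                "N1": self.n_informed(),
            }
        )


def simulate(
    params: ModelParams,
    profile: StrategyProfile,
    turns: int,
    seed: int,
    initial_state: int = 0,
) -> SimulationTrace:
    """Run the chain for ``turns`` turns from ``initial_state``.

    Knowledge can only be gained one agent at a time and is lost only
    through a global reset, so the trace is a faithful sample path of the
    exact transition matrix.
    """
    if turns < 1:
        raise InvalidParameterError("turns must be at least 1")
    N = params.N
    if profile.N != N:
        raise InvalidParameterError("profile length must equal N")
    if N > 64:
        raise InvalidParameterError("bitmask trace storage supports N <= 64")
    if not (0 <= initial_state < (1 << N)):
        raise InvalidParameterError("initial_state outside the state space")

    rng = np.random.default_rng(seed)
    # fixed stream order: reset, agent index, action choice, success
    u_reset = rng.random(turns)
    agents = rng.integers(0, N, size=turns)
    u_action = rng.random(turns)
    u_success = rng.random(turns)

    r = profile.r
    q_reset = params.q_C / N
    q_I, q_O = params.q_I, params.q_O

    states = np.empty(turns, dtype=np.uint64)
    reset = np.zeros(turns, dtype=bool)
    agent_rec = np.full(turns, -1, dtype=np.int32)
    action = np.full(turns, ACTION_NONE, dtype=np.int8)
    success = np.zeros(turns, dtype=bool)

    state = int(initial_state)
    full_reset = 0
    for t in range(turns):
        if u_reset[t] < q_reset:
            state = full_reset
            reset[t] = True
        else:
            n = int(agents[t])
            agent_rec[t] = n
            if state >> n & 1:
                action[t] = ACTION_EXPLOIT
            elif u_action[t] < r[n]:
                action[t] = ACTION_COPY
                if state != 0 and u_success[t] < q_O:
                    state |= 1 << n
                    success[t] = True
            else:
                action[t] = ACTION_SEARCH
                if u_success[t] < q_I:
                    state |= 1 << n
                    success[t] = True
        states[t] = state

    return SimulationTrace(
        params=params,
        profile=profile,
        seed=int(seed),
        turns=int(turns),
        states=states,
        reset=reset,
        agent=agent_rec,
        action=action,
        success=success,
    )


@dataclass(frozen=True)
class FitnessEstimate:
    """Monte Carlo fitness estimate with batch-means errors.

    ``w_hat[n]`` is the post-burn-in time average of agent ``n``'s
    knowledge indicator — an estimate of the steady-state fitness — and
    ``se[n]`` its batch-means standard error.  ``degenerate`` flags agents
    whose indicator never varied across batches (e.g. a frozen
    all-informed trace), for which the batch-means error is vacuous.
    """

    w_hat: np.ndarray
    se: np.ndarray
    n_batches: int
    n_samples: int
    degenerate: np.ndarray

    def to_dict(self) -> dict:
        return {
            "w_hat": [float(x) for x in self.w_hat],
            "se": [float(x) for x in self.se],
            "n_batches": self.n_batches,
            "n_samples": self.n_samples,
            "degenerate": [bool(x) for x in self.degenerate],
        }


def estimate_fitness(
    trace: SimulationTrace, burn_in: int, n_batches: int = 20
) -> FitnessEstimate:
    """Per-agent occupancy estimate over the post-burn-in window.

    The window is split into ``n_batches`` contiguous batches; the spread
    of batch means gives the standard error.  Raises when fewer than
    ``n_batches`` post-burn-in turns remain.
    """
    if not (0 <= burn_in < trace.turns):
        raise InvalidParameterError(
            f"burn_in must lie in [0, turns); got {burn_in} of {trace.turns}"
        )
    post = trace.occupancy()[burn_in:]
    n_samples = post.shape[0]
    if n_samples < n_batches:
        raise InvalidParameterError(
            f"{n_samples} post-burn-in turns cannot fill {n_batches} batches"
        )
    usable = (n_samples // n_batches) * n_batches
    batches = post[:usable].reshape(n_batches, usable // n_batches, -1)
    batch_means = batches.mean(axis=1)
    w_hat = post.mean(axis=0)
    se = batch_means.std(axis=0, ddof=1) / np.sqrt(n_batches)
    degenerate = se == 0.0
    return FitnessEstimate(
        w_hat=w_hat,
        se=se,
        n_batches=n_batches,
        n_samples=n_samples,
        degenerate=degenerate,
    )


def suggest_burn_in(params: ModelParams, profile: StrategyProfile) -> int:
    """Burn-in long enough to forget the initial state: 20 relaxation
    times when the exact chain is affordable, else a conservative
    ``20 N / q_C`` (the reset timescale bounds the memory of the chain)."""
    if params.N <= DEFAULT_STATE_CAP:
        _, tau = MarkovChain(params, profile).spectral_gap()
        return max(1, int(np.ceil(20.0 * tau)))
    return max(1, int(np.ceil(20.0 * params.N / params.q_C)))
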