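"""Seeded Monte Carlo run versus the closed-form prediction.

Simulates the turn-by-turn agent system at the equilibrium strategy and
checks that the time-averaged occupancy reproduces the closed-form
fitness within its batch-means standard error.
"""

import numpy as np

from socialbandit import (
    ModelParams,
    StrategyProfile,
    estimate_fitness,
    fitness_closed,
    simulate,
    solve_nash_closed,
    suggest_burn_in,
)

params = ModelParams(N=10, q_C=0.2, q_I=0.3, q_O=0.8)
r_nash = solve_nash_closed(params)[0]
profile = StrategyProfile.homogeneous(r_nash, params.N)

burn_in = suggest_burn_in(params, profile)
trace = simulate(params, profile, turns=300_000, seed=42)
est = estimate_fitness(trace, burn_in=burn_in)

reference = fitness_closed(params, r_nash, r_nash)
print(f"strategy: homogeneous r = r_Nash = {r_nash:.5f}")
print(f"burn-in:  {burn_in} turns (20 relaxation times)")
print(f"closed-form fitness w_N = {reference:.5f}\n")
print("agent  w_hat     se       z")
for n in range(params.N):
    z = (est.w_hat[n] - reference) / est.se[n]
    print(f"{n + 1:4d}  {est.w_hat[n]:.5f}  {est.se[n]:.5f}  {z:+.2f}")
print(
    "\nEach z-score compares the simulated occupancy with the closed form"
    " in units of its standard error; values within a few units confirm"
    " the analytic steady state."
)
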