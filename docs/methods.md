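# Methods

## Model

`N` agents face a restless bandit with one good arm among infinitely many
bad ones. Time is discrete; per turn exactly one of two things happens:

- with probability `q_C/N` the good arm moves and every agent's knowledge
  of it is erased (the `1/N` scaling keeps the turnover rate per agent
  action constant as the population grows);
- otherwise one agent, chosen uniformly, acts. An informed agent exploits
  its arm. An uninformed agent attempts a copy with its personal
  probability `r_n` (success `q_O`, possible only while at least one
  agent is informed) and otherwise searches (success `q_I`).

The joint knowledge state `σ ∈ {0,1}^N` is a finite Markov chain. For
`q_C, q_I, q_O > 0` and every `r_n < 1` the chain is irreducible and
aperiodic, so it has a unique stationary distribution, and the fitness of
agent `n` is defined as the stationary mean `w_n = E[σ_n]` — a
probability, not a cumulative reward. This steady-state notion is the
model's central simplification: it is meaningful when strategies change
slowly relative to the relaxation time `τ = −1/log ρ` (with `ρ` the
subdominant eigenvalue modulus), which the Markov module computes
exactly. A time-dependent theory of strategy dynamics is out of scope.

With `a = q_C/(1 − q_C/N)` and `r̄_n` the leave-one-out mean strategy,
`w_n = w(r_n, r̄_n)` has the closed form given in the README. Useful
special cases: `w(0, ·) = q_I/(a + q_I)` (a pure searcher is indifferent
to the others), and at `N = 1` the formula collapses to the two-state
chain value `(1−r) q_I / (a + (1−r) q_I)`.

## Equilibrium theory

The best response `f(r̄)` is zero when `q_O ≤ q_I` (copying cannot beat
searching) and otherwise the clamp to `[0, 1]` of

```
f̄(r̄) = ( −ζ + √(q_O (N−1)(1−r̄)) √ζ ) / (q_O − q_I),
ζ     = a + q_I + q_I (N−1)(1−r̄).
```

`f` is non-increasing: social information is a congestible resource. The
simultaneous best-response map has a unique fixed point, homogeneous by a
self-consistency argument: all components of a fixed point satisfy
`r = g(r) = f((s − r)/(N − 1))` for the common sum `s`, `g` is increasing
with slope at most `1/2` on its clamp-free band, so `r − g(r)` has a
single zero. The band is `[r_*, r*]` in the mean-strategy variable, where
`f̄(r*) = 0` and `f̄(r_*) = 1`; both points are computed with their
discriminant and the slope bound is verified numerically (it is attained
exactly at the `r*` end).

`r_Nash` is evaluated three independent ways: the closed form
`1 − η` (with its discriminant `D1`), bisection on the strictly
increasing `h(r) = r − f(r)` (bracketing `h(0) ≤ 0 ≤ h(1)` checked first;
tolerance `1e−10`, ≤ 200 iterations), and damped fixed-point iteration.
The Pareto point maximises the common diagonal fitness `w(r, r)` and has
its own closed form with intermediates `X, Y`.

Certificates, all numeric by design (no symbolic proofs):

- **ESS.** Strict inequalities `w(r_N, r_N) > w(r, r_N)` and
  `w(r_N, r) > w(r, r)` on a 1001-point grid, excluding two grid steps
  around the equilibrium where the slack vanishes quadratically; the
  certificate demands slack above `1e−9` and is only claimed for
  parameters inside the regime.
- **Ordering.** `u = 1/(1 − r_Nash)` is the larger root of the quadratic
  `k(u) = (a+q_O)² u² − [(q_O − q_I N)(a+q_O) + (aN+q_O)(q_O−q_I)] u +
  (q_O−q_I)(q_O − q_I N²)` (obtained by squaring the interior fixed-point
  equation in `u`), with `k(1) < 0`, `k(1/(1−r_I)) > 0` and
  `k(1/(1−r_Pareto)) < 0`, where `r_I = 1 − (a+q_O)/((q_O−q_I)N)`
  satisfies `w(r_I, r_I) = w_I`. Together these pin
  `r_Pareto < r_Nash < r_I` and hence `w_P > w_N > w_I` in the regime
  `(q_O − q_I) N > a + q_O`; the boundary case is classified as outside
  the regime (all three values collapse to `w_I`).

## Numerical choices

- Probabilities are validated with strict open-boundary checks at
  tolerance `1e−12`; `r_n = 1` (pure copying) is rejected at profile
  construction because it breaks ergodicity, but the fitness formula
  accepts it for evaluating pure-strategy cross-checks.
- `a` is a derived property recomputed on access, never stored.
- Negative radicands in any closed form raise instead of clamping, to
  surface transcription errors rather than mask them.
- The fixed-point solver damps with `d = 2/(N+1)` by default: the
  unclamped response slope is bounded by `(N−1)/2` in magnitude (the
  self-consistency map's slope bound of `1/2` times `N−1`), so this
  damping makes the iteration a guaranteed contraction; a fixed constant
  would oscillate for steep response curves.
- The stationary distribution is obtained by replacing one redundant
  balance equation with the normalisation row in a dense linear solve,
  with power iteration as a fallback; stationarity residuals are below
  `1e−10`. Eigenvalues are taken on the full matrix, complex ones by
  modulus, and the solver asserts the unit eigenvalue is simple.
- The dense chain is capped at `N = 14` (16384 states); a reduced chain
  over the informed count alone would only be valid for homogeneous
  profiles and is deliberately not implemented.

## Simulator

The simulator realises the transition-matrix decomposition literally:
the reset event preempts the agent action within a turn (the narrative
"act, then maybe reset" composition differs from this mixture only at
second order in one turn and not at all in the steady state; the matrix
form is the model's mathematical definition and is what the code
implements). One seeded NumPy generator supplies four pre-drawn per-turn
streams in a fixed order — reset, agent index, copy-vs-search choice,
success — so traces are bit-reproducible given (seed, turns). States are
stored as per-turn bitmasks (`N ≤ 64`).

Estimation uses the post-burn-in time average per agent with batch-means
standard errors (20 contiguous batches by default; an error is raised if
fewer than 20 post-burn-in turns remain, and agents whose indicator never
varies across batches are flagged degenerate). The default burn-in is 20
relaxation times from the exact chain when `N ≤ 14`, else `20 N / q_C`
(the reset timescale bounds the chain's memory). Batch means are honest
only when batches are long relative to `τ`; at the defaults (≥ 10⁴ turns,
`τ` of order 10) this holds comfortably. Because global resets correlate
all agents, the per-agent z-scores in an agreement check are themselves
strongly correlated — a whole run can drift a couple of standard errors
in one direction without indicating bias.

There is no synthetic-data generator in the usual sense: the model has no
external data, so the study conditions are simply the reference parameter
set `N = 10, q_C = 0.2, q_I = 0.3, q_O = 0.8` used throughout (a regime
case with an interior equilibrium), plus randomized parameter draws for
property checks. Test problem sizes — populations up to `N = 10` against
the exact chain, simulations of 10⁵–10⁶ turns — were chosen so the exact
oracle stays dense-affordable while sampling error sits well below the
effects being measured.

## Limitations

- The equilibrium analysis assumes the steady state; fast strategy
  dynamics would need the time-dependent theory this package does not
  attempt.
- The ESS inequalities are certified on a grid with a slack margin, not
  proven; near the regime boundary the slack genuinely degenerates and no
  certificate is claimed.
- Strictness of the invasion inequality at a boundary equilibrium
  (`r_Nash = 0`, i.e. `q_O ≤ q_I` or outside the regime) is checked only
  weakly (`≥`), matching what holds there.
- Fitness is an occupancy probability; per-turn realised reward scales as
  `w_n/N` (one agent acts per turn) and cumulative-reward or regret
  accounting is intentionally out of scope, as are spatial or
  multi-population extensions.
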