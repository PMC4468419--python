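# Methods

`dualproc` simulates the evolution of *cognitive control* in a population of
dual-process agents that gather and consume a single resource. This note
records the model, the numerical choices behind the implementation, and what
the synthetic scenarios do and do not establish.

## The agent model

Each agent carries an energy level `E ∈ [0, E_max]` and a store of
unconsumed resource `S ≥ 0`. One timestep consists of:

1. **Drain** — `E ← max(0, E − d)`, the cost of subsistence.
2. **Acquisition** — a resource of size `ρ` is acquired with a per-mode
   probability (below).
3. **Consumption** — some amount `x` of the available pool is consumed;
   energy follows the saturating utility
   `E' = E_max − (E_max − E)·exp(−u·x/E_max)`, the closed form of the
   marginal-gain law `dE/dx = u·(1 − E/E_max)`. The remainder of the pool
   (for controlled acts) is stored.

An agent's heritable trait `C ∈ [0, 1]` is its per-step probability of
acting in a **controlled** manner; otherwise it acts **automatically**:

* *automatic*: consume the entire encountered resource immediately; no
  access to the store.
* *controlled*: choose `x` from the pool `S + acquired` using an optimal
  consumption policy (below); store the rest.

Fitness is the mean of `E` over a lifetime.

### Parameter defaults and why

| parameter | default | meaning / rationale |
|---|---|---|
| `d` (drain) | 1 | sets the energy unit: one subsistence cost per step |
| `ρ` (resource size) | 10·d | one find covers ten steps of subsistence |
| `E_max` | 100·d | satiety ceiling; ~100 steps of subsistence |
| `u` (utility rate) | 30 | see below |
| `R` | 0.005 | "scarce" default; study values are 0.005 / 0.025 / 0.125 |

`u` controls how hard the satiety curve bends over one resource:
consuming `ρ = 10` from the floor reaches `E_max·(1 − e^{−uρ/E_max})`, i.e.
95% of the ceiling at `u = 30`. This is the single most consequential
calibration in the package. At small `u` (≲ 10) the utility is nearly
linear over one resource, storage buys almost nothing, and the
controlled strategy barely beats — or even loses to — immediate full
consumption once estimator noise is accounted for; none of the
qualitative structure of interest exists. At `u = 30` the controlled
agent's fitness advantage in isolation is ≈ 45% under scarcity
(R = 0.005) and ≈ 4% under abundance (R = 0.125), which produces the
intended tension: flexibility is decisively favoured when resources are
scarce and nearly worthless when they are plentiful.

## Optimal consumption (the controlled policy)

The controlled consumption problem is a discounted MDP on the state
`(E, S)`: each step drains, acquires with probability `p`, then picks `x`
from `n_x = 11` evenly spaced fractions of the pool. The per-step reward is
the post-step energy, so the optimized objective is the expected discounted
stream of `E` — a proxy for the fitness measure (lifetime mean `E`) that
becomes exact as the discount `γ → 1`.

Numerical choices:

* **Discretization** — 33 energy bins × 33 store bins, store capped at
  `S_cap = 50` (five resources). Successor states are projected by
  bilinear interpolation of the value function; a nearest-neighbour
  projection is available and is used by the brute-force test oracles,
  because it makes the discretized problem an exact finite MDP.
* **Discount** `γ = 0.997` (effective horizon ≈ 330 steps). `γ = 0.99`
  (horizon ≈ 100) measurably undervalues storage at `R = 0.005`, where
  inter-arrival times are ~200 steps.
* **Convergence** — value iteration to sup-norm change `< 10⁻³`
  (value-scale error bound ≈ 0.3 energy units; the greedy policy is
  insensitive at this level). Non-convergence raises with the residual.
* **Tie-break** — among value-equal consumption levels the smallest is
  chosen (prefer storage); deterministic.
* **Availability ladder** — policies are pre-solved at 21 acquisition
  probabilities: 0 plus a geometric ladder from 10⁻³ to 1. Geometric
  spacing matters: all study richness values live in [0.002, 0.125], where
  a uniform 21-level grid would provide essentially no resolution.
* **Availability estimate** — agents track their acquisition probability
  with an exponential moving average (`λ = 0.01`, i.e. ~100-step memory),
  initialized at the agent's true expected acquisition rate, and use the
  policy at the nearest ladder level. `λ = 0.05` makes the estimate so
  noisy (sd comparable to the estimate itself at scarce rates) that policy
  routing destroys most of the controlled advantage; `λ = 0.01` keeps the
  estimator adaptive while preserving it. Because the estimate is built
  only from the agent's own outcomes, competition biases it downward
  exactly as intended: resources lost to faster competitors are simply
  never experienced.

## Competition and access probabilities

Competition is folded into per-mode acquisition probabilities rather than
simulated pairwise. A contest requires that some other agent encounter the
focal agent's resource in the same timestep, so the contest probability
grows with both crowding and abundance:
`p_contest = min(1, κ(N−1)R)` by default, or the gentler per-competitor
saturating form `1 − (1 − κR)^(N−1)`. The `R` factor matters: without it,
rich environments would impose no extra competition, and because satiety
makes marginal access nearly worthless when `R` is large, no amount of
contest pressure short of totality would ever favor automatic processing
there — the richness axis of the equilibrium structure, and the collapse
phase of the limit cycle, both hinge on contests intensifying with `R`.
With an opponent that is automatic with probability `m` (the population
mean of `1 − C`):

```
p_auto = R·[(1 − p_contest) + p_contest·(m/2 + (1−m)·w_auto)]
p_ctrl = R·[(1 − p_contest) + p_contest·((1−m)/2 + m·(1−w_auto))]
```

`w_auto = 1` by default (the automatic actor always wins mixed contests);
any value in (0.5, 1] preserves the speed advantage. Same-mode contests are
split evenly, so winner probabilities always sum to one. The default
collision rate `κ = 0.2` makes competition negligible at `N = 10` for
every study richness, moderate at `(N = 100, R = 0.005)`, and total at
`(N = 100, R = 0.125)` or `N = 1000` — which is what generates the joint
(N, R) dependence of the evolutionary outcome.

The two demographic-feedback scenarios (variable `N`) use the saturating
form with `κ = 0.1`. This is a structural requirement, not a tuning
nicety: with the hard-capped linear form, the range of `N` over which the
contest probability transitions from rare to total spans less than
`1/(κR) ≈ 1000` individuals, so a population growing or shrinking by
`delta_N ≥ 1` per generation crosses the entire competitive window faster
than the mutational climb of `C` (~10³ generations) can respond, and no
boom can form. The saturating form spreads the same transition over
several thousand individuals.

## The fitness table and its noise floor

Fitness is precomputed on a grid over `(C, p_auto, p_ctrl)` by Monte-Carlo
lifetimes (default 30,000 lifetimes of 1,000 steps, split evenly over
cells) and looked up by trilinear interpolation during evolution. The grid
is the full product cube (including the physically unreachable corner
`p_ctrl > p_auto`) so interpolation is defined everywhere.

One finding deserves emphasis: **table noise is not benign**. A cell
estimated from ~20 lifetimes has a standard error of 1–2 energy units at
scarce access rates (lifetime means are dominated by a handful of Poisson
arrivals), while the fitness difference between adjacent `C` levels is of
the same order. A table that noisy contains spurious local optima in `C`
that trap a mutation-limited Wright-Fisher population for tens of
thousands of generations. The equilibrium analyses therefore use a
reduced axis set (11 `C` levels × 8 access levels spanning [0, 0.125])
with ~1,200 replicates per cell (≈ 845k lifetimes), which brings the cell
standard error below ~0.3 energy units — comfortably under the adjacent-
level fitness differences. The budgeted build takes a couple of minutes;
the per-generation lookup cost is unchanged.

## Evolution

Standard Wright-Fisher: each generation the `N` offspring draw parents
with replacement proportionally to fitness; each offspring mutates with
probability 0.05 by ±0.02 on `C` (sign equiprobable), clamped to [0, 1].
Populations are initialized homogeneous at `C = 0`. Access probabilities
are recomputed every generation from the current `(R, N, mean(1 − C))`,
which is what makes selection frequency-dependent. A generation with zero
total fitness reproduces by uniform (pure-drift) sampling: a starving
fixed-size population is not yet extinct. A single seeded generator drives
a whole run; identical seeds give identical trajectories.

Time scales worth knowing: with mutational steps of 0.02, a single step is
nearly neutral (`N·s_step < 1`) for N ≲ 100, so the climb from `C = 0` to
fixation takes on the order of 10³–10⁴ generations depending on `N`, and
an `N = 10` population never stops wandering (its tail-averaged mean `C`
has a drift sd of a few hundredths to ~0.1). Equilibrium summaries in the
tests therefore use generation counts scaled by population size
(60k / 30k / 15k generations for N = 10 / 100 / 1000) and compare ordered
equilibria with a 0.1 tolerance fixed from that drift analysis.

### Evolvable automatic policy (variant)

A second heritable trait can give automatic acts a *target energy level*
`T_E`: an automatic act consumes from everything at hand (resource plus
store) exactly enough to reach `T_E` — the inverse of the utility closed
form — and stores the rest; `T_E = E_max` with an empty store reproduces
the rigid full-consumption rule. The trait mutates like `C` at the same
rate with step `0.02·E_max` (the same relative step on its scale), and
fitness comes from a four-axis table over `(T_E, C, p_auto, p_ctrl)`.

## Feedback scenarios

* **Variable population size** (richness fixed): `N` grows by `delta_N`
  when mean energy exceeds `T_N + ε`, shrinks by `delta_N` below
  `T_N − ε`, else holds; `N = 0` is extinction. `delta_N` is an absolute
  count (default 5), *not* a fraction of `N₀`: the survival-versus-
  extinction contrast between small and large founding populations exists
  precisely because a larger population can absorb more absolute losses
  before disappearing. Growth adds extra fitness-proportional offspring of
  the same parent generation; shrinkage removes uniformly at random.
* **Variable richness** (size fixed): `R` rises by `delta_R` when
  `mean E · mean C` exceeds `T_R + ε` (deliberation plus surplus energy
  producing environmental enrichment), falls below `T_R − ε`, and is
  floored at the baseline `R₀` and capped at 1.

The dead band `ε` (default 2% of the driving statistic's scale) prevents
one-increment oscillation around the threshold. Feedback increments are
deliberately slow relative to selection so the trajectories are smooth.

The documented scenario conditions (used by the test suite and by
`scripts/acceptance.py`) are, at `R = 0.005` and the saturating contest
model for the variable-`N` runs:

* *boom-bust*: `T_N = 12`, `ε = 0.24`, `delta_N = 1`, `N₀ = 30`,
  12,000 generations. `T_N` sits well below the fitness an automatic
  population earns while uncrowded (~19), so the population grows from the
  start; control rises to ~0.9 while the population is small, the grown
  population (~3,000) turns contests frequent, and control collapses to
  ~0.02 while `N` keeps rising.
* *extinction/survival split*: `T_N = 22`, `ε = 0.44`, `delta_N = 2`,
  4,000 generations. `T_N` exceeds any automatic population's fitness, so
  every founding population shrinks; `N₀ = 200` founders die out before
  control can establish, while `N₀ = 2000` founders lose roughly half
  their size, fixate control (final mean `C ≈ 0.9`), and stabilize.
* *limit cycles* (fixed `N = 300`, linear contest model): `T_R = 6`,
  `ε = 0.12`, `delta_R = 2×10⁻⁴`, baseline `R₀ ∈ {0.001, 0.005, 0.05}`,
  14,000 generations. At `R₀ = 0.005` the system cycles with period
  ~1,100 generations and smoothed amplitude ~0.26 in mean `C`; at lean
  `R₀` the enrichment product `mean E · mean C` never reaches the
  threshold, and at rich `R₀` contests are already total so control never
  rises.

**Cycle detection**: after discarding a burn-in fraction (default 20%),
the mean-`C` series is smoothed by a centered moving average (window 2% of
the remaining length) and peaks/troughs are found with a prominence of
half the amplitude threshold; the run is classified as cycling when at
least `min_cycles = 3` peak/trough alternations swing by at least
`min_amplitude = 0.2`. The period is the mean peak-to-peak spacing.

## What the scenarios show — and what they do not

The simulations are synthetic end to end: the environment is a Bernoulli
resource stream, competition is mean-field (no spatial or network
structure, at most an implicit pairwise contest), and the controlled
policy is exactly optimal for its discretized model. Passing scenario
checks therefore demonstrates the *internal* logic — that flexible
consumption is individually superior, that its advantage is eroded by the
competition and abundance it produces, and that this feedback yields
boom-bust trajectories and limit cycles — not that any particular natural
population behaves this way. Quantities such as `κ`, `T_N`, `T_R`, and the
feedback increments have no empirical anchoring; only the qualitative
regime structure (orderings, existence of thresholds and cycles) is
meaningful.

## Known limitations

* The consumption MDP is solved per availability level and indexed by a
  noisy estimate; agents near a ladder midpoint alternate between two
  policies. Finer ladders trade solve time for routing error.
* The fitness table ignores within-generation feedback: an agent's
  competitive environment is summarized by the population mean of
  `1 − C`, not by who it actually meets (the realized-mode option the
  table-free simulator supports is not wired into the evolutionary loop).
* Mean-field competition admits at most two contestants per resource.
* Store capacity is truncated at `S_cap` inside the policy solver; in the
  scarce regimes that matter the store rarely approaches the cap.
* `N = 10` equilibria are drift-dominated; single runs at that size are
  reproducible (seeded) but not representative without averaging.
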