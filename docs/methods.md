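# Methods

## The game

A group of `N` players is sampled without replacement from a well-mixed
population of `Z` individuals, `k` of whom are cooperators (C); the rest
defect (D). Each cooperator contributes `c·B` of the endowment `B`
(`0 ≤ c ≤ 1`). A group with `j ≥ M` cooperators is safe; one below the
threshold loses the remaining endowment with probability `r`, so the
baseline payoffs are

    Π_D(j) = B·[θ(j − M) + (1 − r)(1 − θ(j − M))],   Π_C(j) = Π_D(j) − cB,

with the step-function convention `θ(0) = 1`: meeting the threshold
exactly is a success.

An institution holds a fixed budget `N·δ` per group and splits it with
weight `w ∈ [0, 1]` between rewards and sanctions. The budget is divided
among the individuals actually present — each of `j` cooperators gains
`a·w·N·δ/j`, each of `N − j` defectors loses `b·(1−w)·N·δ/(N − j)` — and
no cap is applied as shares grow when recipients become scarce. The
blow-up is deliberate: severe per-defector sanctions when defectors are
rare is precisely what creates a new equilibrium near full cooperation
under pure punishment at large budgets. The weight is a *population-level*
rule `w(k)`: groups do not observe their own composition to set it.

## Fitness and the evolutionary chain

Fitness is the expected payoff over the hypergeometric distribution of a
focal individual's `N − 1` co-players (drawn from the remaining `Z − 1`;
the focal cooperator's group holds `j + 1` cooperators in total).
Binomial coefficients with out-of-range arguments are zero, which
realizes the support limits without case analysis; the pmf is evaluated
by `scipy.stats.hypergeom` (log-gamma based, no overflow at any `Z`
considered).

Strategy revision follows the pairwise-comparison rule: a focal
individual adopts a role model's strategy with the Fermi probability
`[1 + exp(−β Δf)]⁻¹` (computed via `scipy.special.expit`, which
saturates instead of overflowing). With exploration rate `μ` the
population state performs a birth–death Markov chain with

    T±(k)   = (k/Z)((Z−k)/Z)·[1 + e^{∓β(f_C(k) − f_D(k))}]⁻¹,
    T_μ+(k) = (1 − μ)·T+(k) + μ·(Z − k)/Z,
    T_μ−(k) = (1 − μ)·T−(k) + μ·k/Z.

The demographic prefactor vanishes at `k ∈ {0, Z}`, and the
implementation short-circuits there so the fitness of an absent strategy
is never evaluated (it is mathematically undefined; the corresponding
entries of a chain profile are NaN).

The **gradient of selection** `G(k) = T+(k) − T−(k)` is reported without
the exploration terms by default — it describes the direction selection
alone favours — with a `with_mutation` flag for the μ-augmented variant.
Adjacent interior states with opposite gradient signs are the
finite-population analogues of fixed points: a +→− change is a stable
coexistence point, a −→+ change an unstable coordination barrier.

The **stationary distribution** requires `μ > 0` (otherwise the
monomorphic states absorb). Birth–death chains are reversible, so the
closed form `p̄_k ∝ Π_{i=1..k} T_μ+(i−1)/T_μ−(i)` applies; it is
accumulated in log space and normalized at the end, which stays exact to
machine precision even at strong selection (`β = 50` is tested), where a
naive product would under/overflow. An eigenvector route (leading left
eigenvector of the tridiagonal transition matrix) exists in the test
suite purely as an independent oracle. Two analytic limits serve as
further oracles: at `μ = 1` the chain is the Ehrenfest urn with a
binomial(Z, 1/2) stationary law, and with `c = 0`, `δ = 0`, `r = 0` the
strategies earn identical, composition-independent payoffs, so relabeling
C↔D is an exact symmetry and `p̄_k = p̄_{Z−k}`. Note the symmetry needs
payoffs constant across group compositions, not merely equal between
strategies: with `c = 0` but `r > 0` a cooperator's group stochastically
contains more cooperators, so `f_C > f_D` and the stationary law skews
toward cooperation.

## Group achievement

`a_G(k)` is the probability that a group of `N` sampled from the *whole*
population (no focal exclusion — it is a census quantity) contains at
least `M` cooperators: the hypergeometric upper tail. `η_G = Σ p̄_k a_G(k)`
is its stationary average, the headline measure of how often the
population overcomes the dilemma. Success is defined as *reaching the
threshold*; sub-threshold groups that happen to dodge the risk are not
counted. The alternative reading (`a_G + (1 − a_G)(1 − r)`) is available
behind the `count_risk_survival` flag, but is not the default: it would
drive `η_G → 1` as `r → 0` regardless of behaviour, making the metric
insensitive exactly where the dilemma is hardest, whereas the default
vanishes when nobody cooperates at low risk.

## The optimal switching policy

`f_D − f_C` is linear in `w`, so the advantage-minimising split at each
state is at a boundary (bang-bang). The sign of

    Σ_{j=0}^{N−1}  [C(k−1, j)·C(Z−k, N−1−j)/C(Z−1, N−1)] ×
                   [a/(j+1) − (b/(N−j))·(k/(k−j))·((Z−k−N+1+j)/(Z−k))]

decides it: positive ⇒ reward (`w = 1`), negative ⇒ punishment
(`w = 0`), with ties broken toward reward. On the hypergeometric support
`j ≤ k−1` and `N−1−j ≤ Z−k`, so no factor is singular. The sum decreases
in `k` with a single root; this is enforced as a runtime check (a
violation raises rather than silently returning a wrong root). The
optimal switching point is reported as the largest cooperator fraction
still rewarded, `s* = max{k : objective(k) ≥ 0}/Z` — strictly above `s*`
the policy punishes — with 1.0 meaning "always reward" (e.g. `b = 0`) and
0.0 "always punish" (`a = 0`). For `Z = 50`, `N = 10`, `a = b = 1` the
objective is exactly zero at `k = 25` and negative from `k = 26`, giving
`s* = 0.5`. A `SwitchingPolicy(s)` applies `w(k) = 1` for `k/Z ≤ s`,
which makes the `s = s*` rule agree with the objective sign state by
state, and makes `s = 0` / `s = 1` collapse bit-identically onto pure
punishment / pure reward.

The objective is homogeneous of degree 1 in `(a, b)`; the implementation
normalizes the pair by its maximum before evaluation so that the root
location — all that matters — is invariant under joint rescaling *in
floating point as well as in exact arithmetic*. `s*` depends on nothing
but `Z`, `N` and `a/b`; in particular `M`, `r`, `c`, `δ` and `β` never
enter the sum. The half-point at `a/b = 1` is specific to `Z = 50`,
`N = 10` (e.g. `Z = 30`, `N = 6` gives `14/30 ≈ 0.467`); population and
group size have a real but limited effect.

## Monte Carlo cross-check

The simulator realizes the social-learning process one elementary event
at a time: a focal individual is drawn uniformly; with probability `μ` it
explores by adopting the *other* strategy; otherwise a role model is
drawn uniformly from the whole population (self-imitation is a no-op)
and imitated with the Fermi probability. These two conventions —
exploration as a strategy flip, and the role model drawn with the focal
included — are chosen so that the event-level probabilities of `k → k±1`
equal `T_μ±(k)` *exactly*, for every `μ` up to and including the
Ehrenfest limit `μ = 1`. (Exploration by uniform redraw from {C, D}
would halve the mutation flux relative to `T_μ±`; a role model drawn
from the `Z − 1` others would replace one `k/Z` factor by `k/(Z−1)`.)
The generator is `numpy.random.default_rng`; the seed is stored in every
trajectory and manifest.

The simulation validates the analytic machinery two ways: the long-run
occupancy histogram converges to `p̄` in total variation (≈ 0.015–0.02
after 10⁶ events at the `Z = 50`, `M = 5`, `δ = 0`, `r = 0.5` baseline —
mixing is slow because the population must cross the coordination
barrier), and per-state one-step frequencies are binomial samples of
`T_μ±`. The frequency check is aggregate: across ~40–100 simultaneous
per-state comparisons an isolated chance excursion just past 3σ is
expected, so the tests bound the rate of >3σ excursions and reject any
deviation approaching 5σ, which would indicate genuine bias.

What the simulation does and does not share with reality: it emulates
the model's assumptions (well-mixed population, two fixed strategies,
one revision per event, payoff-monotone imitation), so agreement with
the analytic chain validates the mathematics, not the behavioural
realism of Fermi imitation or of a population-level incentive budget.

## Default parameters and problem sizes

| symbol | meaning | default |
|---|---|---|
| Z | population size | 50 |
| N | group size | 10 |
| M | success threshold | 3 (low) / 5 (high) |
| B | endowment | 1 |
| c | cost fraction | 0.1 |
| r | risk | swept over [0, 1] |
| δ | per-capita budget | 0.025 (sweeps), {0, 0.005, 0.01, 0.02} (profiles) |
| a, b | incentive efficiencies | 1 |
| β | selection intensity | 5 |
| μ | exploration rate | 0.01 |

Risk and switching-point sweeps default to 21 evenly spaced grid points
on [0, 1]. Exhaustive-enumeration oracles (all `C(Z−1, N−1)` co-player
subsets, all `C(Z, N)` groups) are run at `Z ≤ 12`, `N ≤ 5`, where they
are exact and fast; Monte Carlo validation uses 10⁶ events after 10⁵
burn-in at `Z = 50` and 4·10⁵ events at `Z = 20`.

## Known limitations

- Well-mixed populations only: no network or group structure, no
  wealth or behavioural heterogeneity beyond the two strategies.
- The chain updates one individual per event; a synchronous
  whole-population revision scheme would have the same stationary
  tendencies but is not what the transition probabilities describe.
- The single-root property of the switching objective is checked
  numerically per parameter set, not proven for every corner of
  parameter space.
- The infinite-population replicator limit is out of scope; all
  quantities are finite-`Z`.
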