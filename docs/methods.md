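# Methods

## Model and assumptions

The state process is a time-inhomogeneous continuous-time Markov chain
on `{0,1}^n`: passive nodes activate at rate `λ(a_i)`, active nodes
deactivate at rate `μ(a_i)`, with `a_i` the active fraction of node
*i*'s neighbourhood.  Two approximations make the triggering question
tractable:

* **Mean field** — replace `a_i(t)` by the expected global fraction
  `â(t)`, turning the node dynamics into the scalar autonomous ODE
  `dâ/dt = (1−â)λ(â) − âμ(â)`, `â(0)=0`.  Appropriate when the network
  is large, scale-free and disassortative, so that neighbourhoods of
  different nodes are nearly independent samples of the whole network.
* **Homogeneity** — lump network states by the number of active key
  nodes into a `(k+1)`-state birth–death chain driven by `â(t)`, with
  the all-active state absorbing.  `E[τ_k]` is the integral of the
  survival probability `1 − p_k(t)`.

Both are approximations, not bounds; the `simulate` module quantifies
their error against the exact chain.

## Rate families

`λ` and `μ` map the activation fraction to rates (1/time).  The
qualitative modelling assumption is `λ` non-increasing and `μ`
non-decreasing (activity begets activity), plus `λ < μ` on `(0,1]` so
that activation saturates below 1.  These are deliberately *advisory*:
`check_rate_properties` reports violations but nothing enforces them,
because the Gompertz-type aging pair

    λ(a) = Γ₀ e^{r₊ a},   μ(a) = (Γ₀/R) e^{−r₋ a}
    (defaults Γ₀ = 0.00113, r₊ = 10.27, r₋ = 6.5, R = 1.5)

is a central use case and breaks both patterns (damage accelerates
damage).  Γ₀ sets the basal damage rate (≈ 1/900 per time unit, so the
interesting dynamics play out over ~100 time units ≈ a lifespan in
years), `R` the initial repair advantage, and `r₊`, `r₋` the
sensitivity of damage/repair to the damage fraction.  The `custom`
family parses small arithmetic expressions in `a` (`+ − * / ^ exp
log`) so arbitrary shapes can be explored from a config file.

## Numerical policies

* **Integrator**: DOP853 (high-order adaptive Runge–Kutta) with dense
  output, `rtol 1e−10`, `atol 1e−12`.  The reference tables are printed
  to 2 decimals, and the hitting-time integral accumulates ODE error
  over hundreds of time units, so tolerances are kept several orders
  below the reporting precision.
* **Horizon selection**: with `t_end="auto"` the activation ODE is
  integrated until `|dâ/dt|` falls below a *saturation threshold*.  A
  fixed threshold cannot work across families: the solver's error floor
  keeps the computed derivative near `(λ+μ)·atol`, which for the aging
  pair (`λ+μ ≈ 33` at saturation) is ~3e−11.  The threshold is
  therefore `max(1e−12, 100·atol·(λ(â)+μ(â)))`.  Beyond the saturated
  horizon `â` is treated as constant; the residual drift is below
  1e−9 per time unit for every built-in family.
* **Trigger time**: first solver step bracketing `â = γ`, refined by
  Brent's method to absolute time tolerance 1e−8.  Returns none when
  the trajectory saturates strictly below γ.
* **Hitting-time integral**: the survival integral is carried as an
  augmented ODE state `dz/dt = 1 − p_k` integrated with the same
  tolerances, terminated by a solver event at `1 − p_k < 1e−8`
  (tail bound `(1−p_k(T))/inf λ` reported).  This replaces a separate
  quadrature pass over the dense output: it is one fewer approximation
  layer and its error is controlled by the same `rtol`/`atol` as the
  probabilities themselves.
* **Fixed-horizon truncation**: `expected_hitting_time(...,
  truncate_at=300)` cuts the integral at a fixed time instead.  The
  published reference grid was evidently produced with a 300-time-unit
  horizon: with it every printed cell is matched to 2 decimals, while
  the converged integrals are visibly larger in the slowest cells
  (k = 6: 65.67 vs the printed 65.08 for the constant pair — the
  converged value is confirmed independently by the birth–death
  closed form).  `reproduce_table` uses the truncated route; everything
  else defaults to the converged one.
* **Equilibria**: sign-bracketed scan of the ODE right-hand side on a
  1001-point grid, refined by Brent to 1e−14.

## The k = 1 "literal" anomaly

The printed ODE system keeps a `μ`-inflow from `p_1` into `p_0` even
when `k = 1`, although `S_1` is then the absorbing state.  Mass is not
conserved (`p_1` grows past 1) and `∫(1−p_1)dt` diverges.  The
reference tables are nevertheless reproduced *only* by this literal
system with the integral truncated at the first root of `p_1(t) = 1`
(constant pair: 1.37, against `1/λ = 2.22` for the proper absorbing
chain).  Both behaviours are implemented: `mode="literal"` (default,
reproduction-faithful) and `mode="consistent"` (mass-conserving
correction).  For `k ≥ 2` the two coincide exactly.  The aggregated
simulator draws from the true chain and therefore sides with
`consistent` at `k = 1` — a deliberate property that exposes the
anomaly rather than hiding it.

## Optimal k

`optimal_key_count` computes the ladder `E[τ_1], E[τ_2], …`
incrementally and stops at the first value exceeding `τ̂^γ` (the ladder
is strictly increasing), applies the sup/inf conventions (`∨1`, `∧
k_max`) and the tie rule favouring `k_c⁻` with an absolute tie
tolerance of 1e−9 on the distance comparison.  `k_max` (default 10)
stands in for the network size n, which never enters the mean-field
computation.  Default `γ = 0.4`, a conservative Pareto-style estimate
of the fraction of nodes whose activity constitutes a global trigger.

## Synthetic graphs

The generator realises the structural assumptions the mean-field
argument rests on, not any particular empirical network: a discrete
power-law degree sequence (`P(d) ∝ d^(−exponent)`, minimum degree 1,
maximum degree capped at `2√n`), configuration-model stub matching
with collision repair by degree-preserving edge swaps, then greedy
Maslov–Sneppen rewiring that accepts only swaps lowering the
degree–degree product sum until the assortativity target (default
−0.1) is met.  Because degrees are fixed during rewiring, the Pearson
assortativity depends on the edge set only through that product sum,
which makes the acceptance test O(1) per swap.  Key nodes are the
top-k degrees with id tie-break.  Regular graphs have undefined
assortativity and are reported as NaN, never as 0.

What the generator does *not* emulate: clustering/small-world
structure, degree-degree correlations beyond the Pearson coefficient,
spatial embedding, community structure.  Agreement of simulation with
mean-field on these graphs therefore shows the approximation works
under the stated structural assumptions, not on any real brain or
social network.

## Stochastic validation

* Full-network runs are exact: between flips all rates are constant,
  so competing exponentials (total-rate waiting time + categorical
  node choice) sample the chain without discretisation error.  Only
  the flipped node and its neighbours are re-rated per event.
* The aggregated chain is time-inhomogeneous and is sampled by
  Lewis–Shedler thinning.  Lookahead windows of length
  `1/(k(sup λ + sup μ))` use endpoint bounds per rate component —
  valid because `â` is monotone in t and each rate function is
  monotone in a, so each component's supremum sits at a window
  endpoint; windows halve if the internal bound check ever fails.
  `λ(â(t))` and `μ(â(t))` are tabulated once per trajectory on an
  8001-point grid and interpolated linearly (error ≪ Monte-Carlo
  noise), rather than re-evaluating the dense output per proposal.
* Replicate r uses seed `base_seed + r`; censored (horizon-limited)
  hitting times are excluded from means and counted, never imputed.

Validation scales: 2×10⁴ aggregated replicates per (family, k) give
standard errors ≈ 0.03–0.05 time units, comfortably resolving the ODE
expectations; network runs use n ∈ {500, 2000} with 200 replicates
each, enough to show the finite-size discrepancy of the mean trigger
time shrinking with n.  For the constant pair at γ = 0.4 the threshold
sits only 0.009 below the equilibrium fraction 0.409, so finite-n
fluctuations cross it early and the mean simulated τ^γ approaches the
mean-field 3.46 from below as n grows.

## Known limitations

* `E[τ_k]` only; the variance/distribution of τ_k is out of scope.
* No bifurcation analysis of the mean-field ODE; only the smallest
  equilibrium is located.
* The thinning bound argument relies on monotone rate functions; a
  non-monotone `custom` rate pair may trigger window-halving or, in
  pathological cases, the explicit bound-violation error.
* Gompertz fitting (`fit_exponential_rate`) is a plain log-linear
  least squares on a user-chosen window; it does not select the window
  or calibrate to demographic data.
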