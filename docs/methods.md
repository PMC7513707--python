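# Methods

## Model and assumptions

The vessel is a perfectly mixed chemostat: fresh medium with toxin
concentration `T_in` enters at dilution rate `alpha`, and cells and toxin
wash out at the same rate. Four strategies compete, defined by two binary
traits. Cooperation (enzyme secretion) is a public good: it lowers the
ambient toxin level, and hence everyone's death rate, at growth cost `c_d`
to the producer. Resistance is a private good: it shifts only the carrier's
death response, at growth cost `c_r`. Costs are additive, so the intrinsic
growth rates are `r`, `r(1-c_d)`, `r(1-c_r)` and `r(1-c_d-c_r)`; validation
requires `c_d + c_r < 1` so all four stay positive. Death by toxin follows
a Hill curve with half-point `K_s` (sensitive) or `K_r > K_s` (resistant)
and shared steepness `n`; degradation follows a Michaelis–Menten law in the
*total* cooperator density (resistance does not affect secretion). Strategies
do not mutate within the ODE layer; mutation and inoculation enter only
through the discrete-time Markov layer. All quantities are in arbitrary
units with carrying capacity scaled to one.

Parameter ranges follow the model's canonical table: rates and costs in
(0, 1], `n > 0`, `0 <= K_s < K_r <= 1`. One deliberate exception: `alpha`
admits 0, the closed-vessel limit, which is needed to express the
logistic-saturation check (toxin-free, no dilution, density → 1) and the
`phi = 0` boundary of the efficiency objective.

## Equilibria and stability

Cheater mono-cultures leave `T = T_in` exactly, giving the closed form
`x* = 1 - (delta(T_in)+alpha)/r_i` when the persistence condition
`W_i(T_in) > 1` holds (strict). Cooperator mono-cultures reduce to the
scalar problem `g(T) = T(alpha + f(x*(T))) - alpha T_in = 0` on `(0, T_in]`,
where `x*(T)` is the density branch above; branches with `x*(T) <= 0` carry
no equilibrium. `g` is evaluated on a 60-point seed grid, sign changes are
bracketed and solved with Brent's method (xtol 1e-10), and roots are
deduplicated at 1e-8. Multiple nontrivial roots are possible and all are
returned. Stability is classified from the eigenvalues of the analytic
Jacobian restricted to the active densities plus the toxin coordinate;
`|max Re(lambda)| < 1e-8` is reported as neutral to avoid noise-driven flips
at bifurcation boundaries. For a trivial equilibrium the focal strategy's
own (zero-density) direction is included, so invasibility by the strategy
itself registers as instability.

Coexistence of a cooperator with an opposite-resistance cheater requires
their fitness proxies to cross: `W_coop(T†) = W_cheat(T†)` is solved for
`T†` in `(0, T_in)`; total density then follows from the cooperator's
zero-growth condition and the cooperator's share from inverting the
Michaelis–Menten law against the required degradation
`alpha (T_in - T†)/T†`. The point is returned only when both densities are
positive and the required degradation is below `f_max`; when several roots
qualify, the stable one with the lowest toxin level is reported.
Same-resistance cooperator/cheater pairs are rejected outright (the cheater
always excludes), as are pairs differing only in resistance (no stable
coexistence exists for them).

## Time integration

`scipy.integrate.solve_ivp` with LSODA, analytic Jacobian, rtol 1e-8 and
atol 1e-10. The right-hand side clips densities at zero: trial steps may
undershoot, and a negative density feeds back through the shared
`(1 - sum x)` term and diverges; clipping also enforces the boundary
invariance that extinct strategies stay extinct. "Equilibrium reached"
means the RHS max-norm falls below 1e-8, checked on geometrically growing
time chunks (500, 1000, 2000, ... up to 2e5).

## Invasion analysis

The invasion fitness of a rare strategy at a resident equilibrium is
`W_invader(T*) - W_resident(T*)`; values within 1e-9 of zero are treated as
neutral (resident resists — neutral drift is out of scope). When the sign
predicts invasion, the final composition is resolved by integrating the
two-strategy ODE from the resident equilibrium plus an invader inoculum of
1e-4 — small enough to test growth from rarity, large enough for solver
robustness. Exclusion is declared when the loser drops below 1e-8. The
residual test alone can stop while a rare strategy is still decaying
exponentially (its density times a small negative per-capita growth rate can
sit below the residual tolerance); a strategy that is rare (< 1e-3) with
per-capita growth below -1e-9 at the converged state is therefore counted as
on its way out. Resident equilibria are those reached by growing the
resident from low density (1e-3) at `T(0) = T_in`; when a single stable
root exists the simulation is skipped and the root used directly.

Invasion maps substitute each grid cell's `(alpha, T_in)` into the analysis;
cells whose resident cannot establish from rarity are marked
`resident_not_viable`, which also traces the persistence boundary. Outcome
codes in the CSV export: 0 not viable, 1 resident resists, 2 invader
excludes, 3 coexistence.

## Efficiency over culture conditions

For a fixed composition, each `(alpha, T_in)` cell is scored by
`phi = alpha (T_in - T_eq)`: zero for cheaters-only, the stable mono-culture
root for a cooperator alone (lowest toxin level if several; alternatives in
the diagnostics), the fitness-crossing point for coexistence. Mono-culture
cells are feasible whenever a stable root *exists*, including beyond the
persistence-from-rarity boundary: a dense established culture degrades
enough toxin to sustain itself where it could not have grown from rarity,
and such cells are reachable by the two-phase protocol (establish the
culture under permissive conditions, then shift to the optimum). The
persistence flag is reported per cell so the boundary can be drawn. This
choice is what makes the mono-culture optimum dominate the coexistence
optimum on the steep-Hill parameter set (0.102 vs 0.091); gating on
persistence would truncate the mono-culture map at high `T_in` and invert
the comparison.

## Markov chain over population states

States and transitions encode the short-term invasion rules as a one-step
lookup: an arriving strategy wins exactly when it is a same-resistance
cheater facing a cooperator, or a cooperator facing an opposite-resistance
resident (the regime in which the culture conditions are assumed to be
held). Enumerating all pairs gives 4 mono-cultures, 6 transient
(resident ← invader) states resolving to the invader in one step, and 4
unfavorable-inoculation states (cooperator poured into its own mono-culture
or into a cheater population it cannot invade) returning to the resident in
one step — 14 states. The one-step sojourn reflects the assumption that
ecological dynamics are fast relative to mutation and inoculation.

Within a step, the three mutation classes (probabilities `mu1(1-mu2)`,
`(1-mu1)mu2`, `mu1 mu2`) and the two inoculations (`m1`, `m2`) are mutually
exclusive alternatives with an explicit no-event complement; configurations
whose probabilities sum above one are rejected, which in particular caps
`m1 + m2` by the mutation budget. A winning arrival establishes with
probability `epsilon` (default 1, deterministic establishment) and otherwise
the population stays put; failed mutants leave no trace, failed inoculations
occupy their unfavorable state for one step regardless of `epsilon` (the
cost is incurred by the act of inoculating). Two modeling choices close
gaps the baseline rule set leaves open: resistance-flip mutants inside
cheater mono-cultures (sCh ↔ rCh) have no transient state and are treated
as failing to establish, and transient/unfavorable states always resolve
(they are not fixed points, so only the degenerate mono-culture-only chain
is exactly the identity when no events fire).

The per-state efficiency vector ships with an illustrative 14-value fixture
whose zeros are pinned to the two cheater mono-cultures (forced: `T = T_in`
with no degraders) and to the unfavorable states of cheater residents;
transients heading toward cooperators carry the larger values. The mapping
is an explicit, documented convention and any 14-vector can be supplied
instead.

## Stationary analysis and optimization

Ergodicity is checked as irreducibility plus aperiodicity of the
positive-entry digraph (networkx). Stationary distributions come from the
least-squares solve of `pi (P - I) = 0` with the normalization row appended;
the fixed-point residual is at machine precision and is cross-checked
against power iteration in the tests. Non-ergodic chains are evaluated by
their exact Cesàro limit from the initial distribution: recurrent classes
and absorption probabilities by linear solves, stationary vectors within
each class, then the absorption-weighted average — no long simulation
involved.

`optimize_stationary` grid-searches constant inoculation pairs (default
21×21, step 0.05) with ties broken toward smaller `(m1, m2)` — fewer
interventions. The finite-horizon schedule is an *open-loop* problem: the
operator cannot observe the population state, so the action depends on time
only. A single backward-induction pass (per-state value function, then
greedily marginalized forward actions) turns out to be insufficient — on the
illustrative inputs it produces a schedule worse than the best constant
pair — so it is used only as a seed. Forward-backward coordinate-ascent
sweeps with exact open-loop costates `lambda(s) = phi + P(a_s) lambda(s+1)`
refine it; a second seed, the best constant action by finite-horizon
rollout, guards against poor local optima, and the better refined schedule
is returned. On the illustrative inputs the optimum is an initial hands-off
phase (the culture starts clean, so inoculating is wasteful) followed by
periodic purge bursts whose average efficiency exceeds the best stationary
value — time-varying schedules genuinely beat constant ones here, because a
deterministic purge resynchronizes the state distribution. The DP schedule
is verified against exhaustive policy enumeration on a small chain in the
test suite.

## Problem sizes and defaults

Published figure-caption parameter sets ship as scenarios and are the test
conditions throughout. Dynamics tolerances: root residual 1e-10, ODE rtol
1e-8 / atol 1e-10, equilibrium max-norm 1e-8, neutrality 1e-8. Efficiency
maps default to 100×100 over `(0, 1]²`; invasion structural checks use a
5×5 grid; the DP illustration uses horizon 2000 with the 0.05 action grid;
stationary-vs-power-iteration checks use random ergodic 14-state chains and
the cumulative-rate check uses 10⁵ steps.

## Limitations

The model omits spatial structure, toxin absorption by non-degraders,
intracellular degradation, growth on the toxin as substrate, and evolution
of `n` or `c_r`; the Markov layer assumes events fire only in mono-cultures
and that culture conditions are held where cooperators exclude
opposite-resistance cheaters. Analytic bifurcation continuation is not
attempted — equilibria are grid-seeded root enumerations, so roots separated
by less than the seed spacing could in principle be missed. The equal-fitness
boundaries of the invasion maps are computed numerically as sign changes of
the invasion fitness, not in closed form.
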