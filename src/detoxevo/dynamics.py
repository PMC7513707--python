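"""Time integration, persistence conditions and equilibria of the chemostat.

A mono-culture of strategy *i* persists iff ``W_i(T_in) > 1`` (its intrinsic
growth beats death-plus-dilution at the worst-case toxin level).  Cheater
mono-cultures leave the toxin at the inflow level, so their equilibrium is
the closed form ``x* = 1 - (delta_i(T_in) + alpha)/r_i``.  Cooperator
mono-cultures couple density and toxin: the equilibrium toxin level solves

    T* (alpha + f(x*(T*))) = alpha T_in,   x*(T) = 1 - (delta_i(T)+alpha)/r_i,

a scalar root problem which may have several solutions; all roots found from
a dense seed grid are returned with a linear-stability classification.
A cooperator and a cheater of *opposite* resistance can coexist where their
fitness proxies cross, ``W_coop(T†) = W_cheat(T†)``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .core_model import (
    STRATEGY_ORDER,
    ChemostatState,
    ModelParams,
    Strategy,
    death_rate,
    degradation_rate,
    detox_efficiency,
    fitness_proxy,
    intrinsic_growth_rate,
    jacobian,
    rhs,
)

__all__ = [
    "ROOT_TOL",
    "ODE_RTOL",
    "ODE_ATOL",
    "EQUILIBRIUM_TOL",
    "NEUTRAL_TOL",
    "Stability",
    "Trajectory",
    "EquilibriumResult",
    "SolverError",
    "simulate",
    "simulate_to_equilibrium",
    "persistence_condition",
    "cheater_monoculture_equilibrium",
    "cooperator_monoculture_equilibria",
    "stability",
    "coexistence_equilibrium",
]

# Numerical tolerances.  The invasion maps hinge on small fitness
# differences, so the defaults are tight.
ROOT_TOL = 1e-10        # residual for scalar root finding
ODE_RTOL = 1e-8
ODE_ATOL = 1e-10
EQUILIBRIUM_TOL = 1e-8  # max-norm of the RHS defining "equilibrium reached"
NEUTRAL_TOL = 1e-8      # |Re(lambda)| below this is classified neutral
_DEDUP_TOL = 1e-8       # converged roots closer than this are one root


class Stability(enum.Enum):
    STABLE = "stable"
    UNSTABLE = "unstable"
    NEUTRAL = "neutral"


class SolverError(RuntimeError):
    """ODE solver failure; carries the last valid state reached."""

    def __init__(self, message: str, last_state: ChemostatState | None = None):
        super().__init__(message)
        self.last_state = last_state


@dataclass
class Trajectory:
    """Time course of the chemostat state."""

    times: np.ndarray          # (N,), strictly increasing
    states: np.ndarray         # (N, 5): x_sCo, x_rCo, x_sCh, x_rCh, T
    final_residual: float = np.nan  # max-norm of the RHS at the final state

    @property
    def final_state(self) -> ChemostatState:
        return ChemostatState.from_vector(self.states[-1])

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"time": self.times}
        for i, s in enumerate(STRATEGY_ORDER):
            cols[f"x_{s.label}"] = self.states[:, i]
        cols["T"] = self.states[:, 4]
        return pd.DataFrame(cols)


@dataclass
class EquilibriumResult:
    """A fixed point of the chemostat ODE.

    Strategies outside ``composition`` have density exactly zero; for
    cheater-only compositions ``T_star`` equals ``T_in`` exactly.
    """

    composition: frozenset[Strategy]
    densities: dict[Strategy, float]
    T_star: float
    residual: float
    stability: Stability | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def total_density(self) -> float:
        return sum(self.densities.values())

    def state(self) -> ChemostatState:
        return ChemostatState(densities=dict(self.densities), T=self.T_star)

    def efficiency(self, params: ModelParams) -> float:
        return detox_efficiency(params.alpha, params.T_in, self.T_star)

    def to_row(self) -> dict:
        row: dict = {
            "composition": "+".join(
                s.label for s in STRATEGY_ORDER if s in self.composition
            ) or "none",
        }
        for s in STRATEGY_ORDER:
            row[f"x_{s.label}"] = self.densities.get(s, 0.0)
        row["T_star"] = self.T_star
        row["stability"] = self.stability.value if self.stability else ""
        row["residual"] = self.residual
        return row


# ---------------------------------------------------------------------------
# Time integration
# ---------------------------------------------------------------------------

def simulate(
    initial: ChemostatState,
    params: ModelParams,
    t_end: float,
    n_points: int = 200,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the chemostat ODE from ``initial`` to time ``t_end``.

    Uses a stiff-capable solver with the analytic Jacobian; densities and
    toxin are clipped to their invariant box (nonnegative, ``T <= T_in``)
    only through the dynamics themselves, not by projection.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    y0 = initial.to_vector()
    times = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(
        lambda t, y: rhs(y, params),
        (0.0, t_end),
        y0,
        method=method,
        t_eval=times,
        jac=lambda t, y: jacobian(y, params),
        rtol=ODE_RTOL,
        atol=ODE_ATOL,
    )
    if not sol.success:
        last = ChemostatState.from_vector(sol.y[:, -1]) if sol.y.size else initial
        raise SolverError(f"ODE solver failed: {sol.message}", last_state=last)
    states = sol.y.T.copy()
    # solver noise can leave densities a hair below zero
    states[states < 0.0] = 0.0
    resid = float(np.max(np.abs(rhs(states[-1], params))))
    return Trajectory(times=sol.t.copy(), states=states, final_residual=resid)


def simulate_to_equilibrium(
    initial: ChemostatState,
    params: ModelParams,
    t_chunk: float = 500.0,
    max_time: float = 2e5,
    tol: float = EQUILIBRIUM_TOL,
) -> tuple[ChemostatState, float]:
    """Integrate in chunks until the RHS max-norm drops below ``tol``.

    Returns the final state and the achieved residual; raises
    :class:`SolverError` if ``max_time`` is exhausted first.
    """
    state = initial
    elapsed = 0.0
    while elapsed < max_time:
        traj = simulate(state, params, t_chunk, n_points=2)
        state = traj.final_state
        elapsed += t_chunk
        if traj.final_residual < tol:
            return state, traj.final_residual
        t_chunk = min(t_chunk * 2.0, max_time - elapsed) or t_chunk
    raise SolverError(
        f"no equilibrium within t={max_time} (residual {traj.final_residual:.3e})",
        last_state=state,
    )


# ---------------------------------------------------------------------------
# Persistence and equilibria
# ---------------------------------------------------------------------------

def persistence_condition(strategy: Strategy, params: ModelParams) -> bool:
    """True iff ``r_i > delta_i(T_in) + alpha``, i.e. ``W_i(T_in) > 1`` (strict).

    A rare mono-culture introduced at the inflow toxin level grows iff this
    holds.
    """
    return intrinsic_growth_rate(strategy, params) > (
        death_rate(params.T_in, strategy, params) + params.alpha
    )


def _monoculture_density(strategy: Strategy, T: float, params: ModelParams) -> float:
    """x*(T) = 1 - (delta_i(T) + alpha) / r_i (may be negative: no equilibrium)."""
    return 1.0 - (death_rate(T, strategy, params) + params.alpha) / intrinsic_growth_rate(
        strategy, params
    )


def _equilibrium_from_point(
    composition: frozenset[Strategy],
    densities: dict[Strategy, float],
    T_star: float,
    params: ModelParams,
    diagnostics: dict | None = None,
    respect_to: frozenset[Strategy] | None = None,
) -> EquilibriumResult:
    full = {s: densities.get(s, 0.0) for s in STRATEGY_ORDER}
    y = np.array([full[s] for s in STRATEGY_ORDER] + [T_star])
    resid = float(np.max(np.abs(rhs(y, params))))
    eq = EquilibriumResult(
        composition=composition,
        densities=full,
        T_star=T_star,
        residual=resid,
        diagnostics=diagnostics or {},
    )
    eq.stability = stability(eq, params, respect_to=respect_to)
    return eq


def cheater_monoculture_equilibrium(
    strategy: Strategy, params: ModelParams
) -> EquilibriumResult:
    """Closed-form mono-culture equilibrium of a cheater.

    Without cooperators nothing degrades the toxin, so ``T* = T_in`` exactly
    regardless of density; the density is ``1 - (delta(T_in)+alpha)/r_i``
    when the persistence condition holds and zero (trivial equilibrium)
    otherwise.
    """
    if strategy.cooperator:
        raise ValueError(f"{strategy.label} is a cooperator, not a cheater")
    T_star = params.T_in
    if persistence_condition(strategy, params):
        x = _monoculture_density(strategy, T_star, params)
        comp = frozenset({strategy})
    else:
        x, comp = 0.0, frozenset()
    return _equilibrium_from_point(
        comp, {strategy: x}, T_star, params, respect_to=frozenset({strategy})
    )


def cooperator_monoculture_equilibria(
    strategy: Strategy,
    params: ModelParams,
    n_seeds: int = 60,
) -> list[EquilibriumResult]:
    """All nontrivial mono-culture equilibria of a cooperator.

    Substituting the density branch ``x*(T)`` into the toxin balance gives
    the scalar problem ``g(T) = T (alpha + f(x*(T))) - alpha T_in = 0`` on
    (0, T_in].  ``g`` is evaluated on a dense grid of seeds; every sign
    change is bracketed and solved, converged roots are deduplicated, and
    each equilibrium is classified by the eigenvalues of the (x, T)
    linearization.  Branches where ``x*(T) <= 0`` carry no equilibrium and
    are skipped.  May legitimately return an empty list.
    """
    if not strategy.cooperator:
        raise ValueError(f"{strategy.label} is a cheater, not a cooperator")
    alpha, T_in = params.alpha, params.T_in

    def g(T: float) -> float:
        x = _monoculture_density(strategy, T, params)
        if x <= 0.0:
            return np.nan
        return T * (alpha + degradation_rate(x, params)) - alpha * T_in

    Ts = np.linspace(T_in * 1e-6, T_in, n_seeds)
    vals = np.array([g(T) for T in Ts])
    roots: list[float] = []
    failures = 0
    for i in range(len(Ts) - 1):
        a, b = vals[i], vals[i + 1]
        if np.isnan(a) or np.isnan(b):
            continue
        if a == 0.0:
            roots.append(Ts[i])
        elif a * b < 0:
            try:
                roots.append(brentq(g, Ts[i], Ts[i + 1], xtol=ROOT_TOL, rtol=1e-14))
            except (ValueError, RuntimeError):
                failures += 1
    if vals[-1] == 0.0:
        roots.append(Ts[-1])
    if not roots and failures:
        raise SolverError(
            f"root finder failed on {failures} bracket(s) and found no root"
        )
    deduped: list[float] = []
    for Tr in sorted(roots):
        if not deduped or Tr - deduped[-1] > _DEDUP_TOL:
            deduped.append(Tr)
    out = []
    for T_star in deduped:
        x = _monoculture_density(strategy, T_star, params)
        if x <= 0.0:
            continue
        out.append(
            _equilibrium_from_point(
                frozenset({strategy}), {strategy: x}, T_star, params
            )
        )
    return out


def stability(
    eq: EquilibriumResult,
    params: ModelParams,
    respect_to: frozenset[Strategy] | None = None,
) -> Stability:
    """Linear stability of an equilibrium from the active-subsystem Jacobian.

    The Jacobian of the full system is restricted to the coordinates of
    strategies present in the composition (plus any ``respect_to``
    directions, used e.g. to test whether a trivial equilibrium is invadable
    by the focal strategy itself) plus the toxin.  All eigenvalue real parts
    negative means stable, any positive means unstable, and a maximum real
    part within ``NEUTRAL_TOL`` of zero is neutral (avoids noise-driven
    flips at bifurcation boundaries).
    """
    y = np.array(
        [eq.densities.get(s, 0.0) for s in STRATEGY_ORDER] + [eq.T_star]
    )
    J = jacobian(y, params)
    active = eq.composition | (respect_to or frozenset())
    idx = [i for i, s in enumerate(STRATEGY_ORDER) if s in active] + [4]
    sub = J[np.ix_(idx, idx)]
    re = np.real(np.linalg.eigvals(sub))
    if abs(np.max(re)) < NEUTRAL_TOL:
        return Stability.NEUTRAL
    return Stability.STABLE if np.max(re) < 0 else Stability.UNSTABLE


def coexistence_equilibrium(
    coop: Strategy,
    cheat: Strategy,
    params: ModelParams,
    n_seeds: int = 120,
) -> EquilibriumResult | None:
    """Coexistence point of a cooperator with an opposite-resistance cheater.

    Coexistence requires equal fitness proxies, ``W_coop(T†) = W_cheat(T†)``,
    i.e. ``r_coop (delta_cheat(T)+alpha) = r_cheat (delta_coop(T)+alpha)``,
    solved for T† in (0, T_in).  The total density then follows from the
    cooperator's zero-growth condition, and the cooperator density from
    inverting the Michaelis--Menten law against the required degradation
    ``alpha (T_in - T†)/T†``.  Returns ``None`` when no root yields positive
    densities with required degradation below ``f_max``.  Same-resistance
    pairs are rejected: a cheater always excludes the cooperator with its own
    resistance level, and pairs differing only in resistance never coexist.
    """
    if not coop.cooperator or cheat.cooperator:
        raise ValueError("need (cooperator, cheater) in that order")
    if coop.resistant == cheat.resistant:
        raise ValueError(
            "same-resistance cooperator/cheater pairs never coexist; "
            "the cheater always excludes"
        )
    alpha, T_in = params.alpha, params.T_in
    r_co = intrinsic_growth_rate(coop, params)
    r_ch = intrinsic_growth_rate(cheat, params)

    def h(T: float) -> float:
        return r_co * (death_rate(T, cheat, params) + alpha) - r_ch * (
            death_rate(T, coop, params) + alpha
        )

    Ts = np.linspace(T_in * 1e-6, T_in * (1 - 1e-9), n_seeds)
    vals = np.array([h(T) for T in Ts])
    roots: list[float] = []
    for i in range(len(Ts) - 1):
        if vals[i] == 0.0:
            roots.append(Ts[i])
        elif vals[i] * vals[i + 1] < 0:
            roots.append(brentq(h, Ts[i], Ts[i + 1], xtol=ROOT_TOL, rtol=1e-14))
    candidates: list[EquilibriumResult] = []
    for T_dag in roots:
        X = _monoculture_density(coop, T_dag, params)  # total density
        if X <= 0.0:
            continue
        f_needed = alpha * (T_in - T_dag) / T_dag
        if not 0.0 < f_needed < params.f_max:
            continue
        x_co = params.K_d * f_needed / (params.f_max - f_needed)
        x_ch = X - x_co
        if x_co <= 0.0 or x_ch <= 0.0:
            continue
        candidates.append(
            _equilibrium_from_point(
                frozenset({coop, cheat}),
                {coop: x_co, cheat: x_ch},
                T_dag,
                params,
                diagnostics={"T_dagger": T_dag},
            )
        )
    if not candidates:
        return None
    stable = [c for c in candidates if c.stability is Stability.STABLE]
    pool = stable or candidates
    return min(pool, key=lambda c: c.T_star)


def equilibria_to_dataframe(results: list[EquilibriumResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in results])


def _w_consistency(eq: EquilibriumResult, params: ModelParams) -> float:
    """Max deviation of W_i(T*) from 1/(1 - total density) over the composition."""
    target = 1.0 / (1.0 - eq.total_density)
    if not eq.composition:
        return 0.0
    return max(
        abs(fitness_proxy(s, eq.T_star, params) - target) for s in eq.composition
    )
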