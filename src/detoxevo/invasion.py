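"""Pairwise invasion analysis between the four strategies.

A rare mutant (or inoculant) invades a resident mono-culture at its stable
equilibrium iff its fitness proxy exceeds the resident's at the equilibrium
toxin level: ``W_invader(T*) > W_resident(T*)``.  Because cooperation only
costs (the enzyme benefit is public), cheaters invade same-resistance
cooperators at any toxin level and the converse never happens — the tragedy
of the commons.  Resistance, by contrast, is private and its benefit depends
on the toxin level, so invasions between resistance classes succeed only in
toxin windows, which is what the (alpha, T_in) invasion maps chart.

When the fitness criterion predicts invasion, the final composition is
resolved by integrating the two-strategy ODE from the resident equilibrium
plus a small inoculum until equilibrium.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .core_model import (
    ChemostatState,
    ModelParams,
    STRATEGY_ORDER,
    Strategy,
    death_rate,
    fitness_proxy,
    intrinsic_growth_rate,
)
from .dynamics import (
    EQUILIBRIUM_TOL,
    EquilibriumResult,
    Stability,
    cheater_monoculture_equilibrium,
    cooperator_monoculture_equilibria,
    persistence_condition,
    simulate_to_equilibrium,
)

__all__ = [
    "InvasionOutcome",
    "InvasionMap",
    "INOCULUM",
    "FITNESS_TIE_TOL",
    "EXTINCTION_THRESHOLD",
    "resident_equilibrium",
    "invasion_fitness",
    "pairwise_invasion",
    "invasion_map",
    "strategy_transition_diagram",
]

#: Invader density added to the resident equilibrium when resolving outcomes.
INOCULUM = 1e-4
#: |W_invader - W_resident| below this counts as neutral -> resident resists.
FITNESS_TIE_TOL = 1e-9
#: A strategy whose post-invasion density falls below this is excluded.
EXTINCTION_THRESHOLD = 1e-8
#: Initial mono-culture density for the "grown from rarity" resident protocol.
_LOW_DENSITY = 1e-3


class InvasionOutcome(enum.Enum):
    RESIDENT_NOT_VIABLE = 0
    RESIDENT_RESISTS = 1
    INVADER_EXCLUDES = 2
    COEXISTENCE = 3


def resident_equilibrium(
    resident: Strategy, params: ModelParams
) -> EquilibriumResult | None:
    """Stable mono-culture equilibrium used as the resident state.

    Cheaters have the closed form; cooperators use the root enumeration.
    When several stable cooperator roots exist, the one reached by
    simulating from a low-density mono-culture at ``T(0) = T_in`` is chosen
    (the standard grown-from-rarity protocol).  Returns ``None`` when the
    resident is not viable (persistence fails or no stable root).
    """
    if not persistence_condition(resident, params):
        return None
    if not resident.cooperator:
        eq = cheater_monoculture_equilibrium(resident, params)
        return eq if eq.composition else None
    stable = [
        e
        for e in cooperator_monoculture_equilibria(resident, params)
        if e.stability is Stability.STABLE
    ]
    if not stable:
        return None
    if len(stable) == 1:
        return stable[0]
    start = ChemostatState(densities={resident: _LOW_DENSITY}, T=params.T_in)
    final, _ = simulate_to_equilibrium(start, params)
    reached = final.to_vector()
    return min(
        stable,
        key=lambda e: np.max(np.abs(e.state().to_vector() - reached)),
    )


def invasion_fitness(
    invader: Strategy, resident_eq: EquilibriumResult, params: ModelParams
) -> float:
    """``W_invader(T*) - W_resident(T*)`` at the resident equilibrium.

    Positive means a rare invader grows.  For coexistence equilibria the
    resident ``W`` is the common value shared by all extant strategies.
    """
    T = resident_eq.T_star
    residents = resident_eq.composition
    if not residents:
        raise ValueError("resident equilibrium has no extant strategy")
    w_res = fitness_proxy(next(iter(residents)), T, params)
    return fitness_proxy(invader, T, params) - w_res


def pairwise_invasion(
    resident: Strategy,
    invader: Strategy,
    params: ModelParams,
    resident_eq: EquilibriumResult | None = None,
) -> InvasionOutcome:
    """Outcome of introducing a rare ``invader`` into a ``resident`` mono-culture.

    Decided by (a) resident viability, (b) the sign of the invasion fitness
    at the resident's stable equilibrium, and (c) when invasion succeeds,
    the equilibrium composition of the two-strategy dynamics started from
    the resident equilibrium plus an inoculum of ``INOCULUM``.
    """
    if resident is invader:
        raise ValueError("resident and invader must differ")
    if resident_eq is None:
        resident_eq = resident_equilibrium(resident, params)
    if resident_eq is None or resident_eq.total_density <= EXTINCTION_THRESHOLD:
        return InvasionOutcome.RESIDENT_NOT_VIABLE
    s = invasion_fitness(invader, resident_eq, params)
    if s < FITNESS_TIE_TOL:
        return InvasionOutcome.RESIDENT_RESISTS
    dens = dict(resident_eq.densities)
    dens[invader] = dens.get(invader, 0.0) + INOCULUM
    start = ChemostatState(densities=dens, T=resident_eq.T_star)
    final, _ = simulate_to_equilibrium(start, params, tol=EQUILIBRIUM_TOL)

    # The residual tolerance can be met while a rare strategy is still
    # decaying exponentially (its density times a small negative per-capita
    # growth).  A strategy is counted as on its way out when it is rare and
    # its per-capita growth at the converged state is clearly negative.
    total = final.total_density
    def _doomed(s: Strategy) -> bool:
        x = final.densities[s]
        if x < EXTINCTION_THRESHOLD:
            return True
        if x > 1e-3:
            return False
        g = (
            intrinsic_growth_rate(s, params) * (1.0 - total)
            - death_rate(final.T, s, params)
            - params.alpha
        )
        return g < -FITNESS_TIE_TOL
    if _doomed(invader):
        return InvasionOutcome.RESIDENT_RESISTS
    if _doomed(resident):
        return InvasionOutcome.INVADER_EXCLUDES
    return InvasionOutcome.COEXISTENCE


@dataclass
class InvasionMap:
    """Grid of pairwise-invasion outcomes over culture conditions (alpha, T_in)."""

    resident: Strategy
    invader: Strategy
    alpha_grid: np.ndarray
    Tin_grid: np.ndarray
    outcomes: np.ndarray          # (len(alpha_grid), len(Tin_grid)) of InvasionOutcome
    resident_viable: np.ndarray   # same shape, bool

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.alpha_grid):
            for j, t in enumerate(self.Tin_grid):
                rows.append(
                    {
                        "alpha": a,
                        "T_in": t,
                        "outcome_code": self.outcomes[i, j].value,
                    }
                )
        return pd.DataFrame(rows)


def invasion_map(
    resident: Strategy,
    invader: Strategy,
    alpha_grid,
    Tin_grid,
    params: ModelParams,
) -> InvasionMap:
    """Pairwise invasion outcome at every (alpha, T_in) grid cell.

    The other model parameters are held at ``params``; cells where the
    resident mono-culture is not viable are marked accordingly, which also
    traces the resident persistence boundary.
    """
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    Tin_grid = np.asarray(Tin_grid, dtype=float)
    if np.any(alpha_grid <= 0) or np.any(alpha_grid > 1) or np.any(Tin_grid <= 0) or np.any(Tin_grid > 1):
        raise ValueError("grids must lie in (0, 1]")
    outcomes = np.empty((alpha_grid.size, Tin_grid.size), dtype=object)
    viable = np.zeros_like(outcomes, dtype=bool)
    for i, a in enumerate(alpha_grid):
        for j, t in enumerate(Tin_grid):
            p = params.replace(alpha=float(a), T_in=float(t))
            eq = resident_equilibrium(resident, p)
            if eq is None:
                outcomes[i, j] = InvasionOutcome.RESIDENT_NOT_VIABLE
                continue
            viable[i, j] = True
            outcomes[i, j] = pairwise_invasion(resident, invader, p, resident_eq=eq)
    return InvasionMap(
        resident=resident,
        invader=invader,
        alpha_grid=alpha_grid,
        Tin_grid=Tin_grid,
        outcomes=outcomes,
        resident_viable=viable,
    )


def _mutation_label(resident: Strategy, invader: Strategy) -> str:
    """Per-step mutation probability of the resident->invader transition."""
    coop_flip = resident.cooperator != invader.cooperator
    res_flip = resident.resistant != invader.resistant
    if coop_flip and res_flip:
        return "mu1*mu2"
    if coop_flip:
        return "mu1*(1-mu2)"
    return "(1-mu1)*mu2"


def strategy_transition_diagram(params: ModelParams) -> nx.DiGraph:
    """Directed graph of successful invasions among the four strategies.

    An edge resident -> invader exists where the pairwise analysis yields
    exclusion or coexistence; edges carry the outcome, the mutation
    probability expression producing that invader from the resident, and a
    flag marking toxin-dependent transitions (any pair whose resistance
    levels differ).
    """
    g = nx.DiGraph()
    g.add_nodes_from(STRATEGY_ORDER)
    for resident in STRATEGY_ORDER:
        eq = resident_equilibrium(resident, params)
        for invader in STRATEGY_ORDER:
            if invader is resident:
                continue
            outcome = pairwise_invasion(resident, invader, params, resident_eq=eq)
            if outcome in (InvasionOutcome.INVADER_EXCLUDES, InvasionOutcome.COEXISTENCE):
                g.add_edge(
                    resident,
                    invader,
                    outcome=outcome,
                    mutation=_mutation_label(resident, invader),
                    toxin_dependent=resident.resistant != invader.resistant,
                )
    return g
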