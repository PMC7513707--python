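"""Detoxification efficiency over culture conditions and its optimum.

The operator controls two knobs: the dilution rate ``alpha`` and the inflow
toxin concentration ``T_in``.  For a fixed strain composition, each
(alpha, T_in) cell has an equilibrium toxin level and hence an efficiency
``phi = alpha (T_in - T_eq)``: zero for cheaters-only (nothing degrades, so
``T = T_in``), the stable mono-culture root for a cooperator alone, and the
fitness-crossing point for a cooperator coexisting with an
opposite-resistance cheater.  Mapping ``phi`` over a grid and taking the
feasible argmax gives the optimal culture conditions for that composition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_model import ModelParams, Strategy, detox_efficiency
from .dynamics import (
    Stability,
    cheater_monoculture_equilibrium,
    coexistence_equilibrium,
    cooperator_monoculture_equilibria,
    persistence_condition,
)

__all__ = [
    "Composition",
    "EfficiencyMap",
    "efficiency_at_equilibrium",
    "efficiency_map",
]


@dataclass(frozen=True)
class Composition:
    """Which strains are assumed present at the equilibrium being scored.

    ``kind`` is one of ``"cheater"`` (cheater mono-culture), ``"mono"``
    (cooperator mono-culture) or ``"coexist"`` (cooperator with an
    opposite-resistance cheater).
    """

    kind: str
    cooperator: Strategy | None = None
    cheater: Strategy | None = None

    def __post_init__(self):
        if self.kind == "cheater":
            if self.cheater is None or self.cheater.cooperator:
                raise ValueError("cheater composition needs a cheater strategy")
        elif self.kind == "mono":
            if self.cooperator is None or not self.cooperator.cooperator:
                raise ValueError("mono composition needs a cooperator strategy")
        elif self.kind == "coexist":
            if (
                self.cooperator is None
                or self.cheater is None
                or not self.cooperator.cooperator
                or self.cheater.cooperator
                or self.cooperator.resistant == self.cheater.resistant
            ):
                raise ValueError(
                    "coexist composition needs a cooperator and an "
                    "opposite-resistance cheater"
                )
        else:
            raise ValueError(f"unknown composition kind {self.kind!r}")

    @property
    def label(self) -> str:
        if self.kind == "cheater":
            return self.cheater.label
        if self.kind == "mono":
            return self.cooperator.label
        return f"{self.cooperator.label}+{self.cheater.label}"


def efficiency_at_equilibrium(
    composition: Composition,
    alpha: float,
    T_in: float,
    params: ModelParams,
) -> tuple[float, float, bool, dict]:
    """Efficiency of ``composition`` at culture conditions (alpha, T_in).

    Returns ``(phi, T_eq, feasible, diagnostics)``.  Infeasibility (the
    assumed equilibrium does not exist there) is a value, not an error:
    ``phi`` and ``T_eq`` are NaN and ``feasible`` is False.  When a
    cooperator mono-culture has several stable roots, the lowest-toxin
    (highest-efficiency) one is used and the alternatives are reported in
    the diagnostics.
    """
    p = params.replace(alpha=float(alpha), T_in=float(T_in))
    diag: dict = {}
    if composition.kind == "cheater":
        # nothing degrades: T = T_in regardless of the cheater's density
        return 0.0, p.T_in, True, diag
    if composition.kind == "mono":
        coop = composition.cooperator
        # A stable root can exist beyond the persistence boundary: a dense
        # established culture degrades enough toxin to sustain itself even
        # where it could not have grown from rarity.  Such cells are
        # feasible (reachable by the establish-then-shift protocol); the
        # persistence flag is reported so the boundary can be drawn.
        diag["persists_from_rarity"] = persistence_condition(coop, p)
        stable = [
            e
            for e in cooperator_monoculture_equilibria(coop, p)
            if e.stability is Stability.STABLE
        ]
        if not stable:
            return np.nan, np.nan, False, diag
        stable.sort(key=lambda e: e.T_star)
        if len(stable) > 1:
            diag["alternative_T_star"] = [e.T_star for e in stable[1:]]
        T_eq = stable[0].T_star
        return detox_efficiency(p.alpha, p.T_in, T_eq), T_eq, True, diag
    # coexistence
    eq = coexistence_equilibrium(composition.cooperator, composition.cheater, p)
    if eq is None:
        return np.nan, np.nan, False, diag
    diag["stability"] = eq.stability.value
    return detox_efficiency(p.alpha, p.T_in, eq.T_star), eq.T_star, True, diag


@dataclass
class EfficiencyMap:
    """Efficiency surface over an (alpha, T_in) grid for one composition."""

    composition: Composition
    alpha_grid: np.ndarray
    Tin_grid: np.ndarray
    phi: np.ndarray        # (|alpha|, |Tin|); NaN where infeasible
    T_eq: np.ndarray       # equilibrium toxin level per cell; NaN where infeasible
    optimum: tuple[float, float, float] | None  # (alpha*, T_in*, phi*)

    @property
    def feasible(self) -> np.ndarray:
        return ~np.isnan(self.phi)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.alpha_grid):
            for j, t in enumerate(self.Tin_grid):
                rows.append(
                    {
                        "alpha": a,
                        "T_in": t,
                        "phi": self.phi[i, j],
                        "feasible": bool(self.feasible[i, j]),
                        "T_eq": self.T_eq[i, j],
                    }
                )
        return pd.DataFrame(rows)


def efficiency_map(
    composition: Composition,
    alpha_grid,
    Tin_grid,
    params: ModelParams,
) -> EfficiencyMap:
    """Cell-wise efficiency over the grid, with the feasible argmax recorded.

    ``optimum`` is ``None`` when every cell is infeasible (the assumed
    equilibrium exists nowhere on the grid).
    """
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    Tin_grid = np.asarray(Tin_grid, dtype=float)
    if np.any(alpha_grid <= 0) or np.any(alpha_grid > 1) or np.any(Tin_grid <= 0) or np.any(Tin_grid > 1):
        raise ValueError("grids must lie in (0, 1]")
    phi = np.full((alpha_grid.size, Tin_grid.size), np.nan)
    T_eq = np.full_like(phi, np.nan)
    for i, a in enumerate(alpha_grid):
        for j, t in enumerate(Tin_grid):
            val, Te, ok, _ = efficiency_at_equilibrium(composition, a, t, params)
            if ok:
                phi[i, j] = val
                T_eq[i, j] = Te
    if np.all(np.isnan(phi)):
        optimum = None
    else:
        i, j = np.unravel_index(np.nanargmax(phi), phi.shape)
        optimum = (float(alpha_grid[i]), float(Tin_grid[j]), float(phi[i, j]))
    return EfficiencyMap(
        composition=composition,
        alpha_grid=alpha_grid,
        Tin_grid=Tin_grid,
        phi=phi,
        T_eq=T_eq,
        optimum=optimum,
    )
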