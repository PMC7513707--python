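"""Chemostat model of cooperative toxin degradation.

A single microbial species grows in a chemostat fed with a toxic compound
(inflow concentration ``T_in``, dilution rate ``alpha``).  Cells carry two
binary traits: *cooperation* (secretion of a toxin-degrading enzyme, a public
good that lowers everyone's death rate at growth cost ``c_d``) and
*resistance* (a private mechanism such as efflux pumps that raises the cell's
own toxin tolerance at growth cost ``c_r``).  The four resulting strategies
are sensitive/resistant cooperators and cheaters (sCo, rCo, sCh, rCh).

This module holds the parameter container, the strategy type, and the
closed-form rate functions: intrinsic growth with additive costs, Hill-type
death by toxin, Michaelis--Menten enzymatic degradation, the fitness proxy
``W_i(T) = r_i / (delta_i(T) + alpha)``, the full ODE right-hand side, its
analytic Jacobian, and the detoxification-efficiency objective
``phi = alpha (T_in - T)``.

All quantities are in the model's arbitrary units; densities are scaled so
the carrying capacity equals one.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, fields

import numpy as np

__all__ = [
    "Strategy",
    "STRATEGY_ORDER",
    "ModelParams",
    "ChemostatState",
    "intrinsic_growth_rate",
    "death_rate",
    "death_rate_derivative",
    "degradation_rate",
    "degradation_rate_derivative",
    "fitness_proxy",
    "derivatives",
    "jacobian",
    "detox_efficiency",
]


class Strategy(enum.Enum):
    """One of the four strategies, defined by the (cooperator, resistant) pair."""

    SCO = ("sCo", True, False)
    RCO = ("rCo", True, True)
    SCH = ("sCh", False, False)
    RCH = ("rCh", False, True)

    def __init__(self, label: str, cooperator: bool, resistant: bool):
        self.label = label
        self.cooperator = cooperator
        self.resistant = resistant

    @classmethod
    def from_label(cls, label: str) -> "Strategy":
        for s in cls:
            if s.label == label:
                return s
        raise ValueError(f"unknown strategy label {label!r}")

    @classmethod
    def from_traits(cls, cooperator: bool, resistant: bool) -> "Strategy":
        for s in cls:
            if s.cooperator == cooperator and s.resistant == resistant:
                return s
        raise AssertionError("unreachable")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Strategy.{self.name}"


#: Canonical global ordering used for every vector, table and CSV column.
STRATEGY_ORDER: tuple[Strategy, ...] = (
    Strategy.SCO,
    Strategy.RCO,
    Strategy.SCH,
    Strategy.RCH,
)

_INDEX = {s: i for i, s in enumerate(STRATEGY_ORDER)}


# (low, high, low_open, high_open) validation ranges.  alpha admits 0 (the
# closed-vessel limit used by the carrying-capacity check); all other rate
# parameters are strictly positive and at most one, n is any positive number.
_RANGES = {
    "alpha": (0.0, 1.0, False, False),
    "T_in": (0.0, 1.0, True, False),
    "r": (0.0, 1.0, True, False),
    "c_d": (0.0, 1.0, True, False),
    "c_r": (0.0, 1.0, True, False),
    "d_max": (0.0, 1.0, True, False),
    "f_max": (0.0, 1.0, True, False),
    "K_d": (0.0, 1.0, True, False),
    "n": (0.0, math.inf, True, False),
}


@dataclass(frozen=True)
class ModelParams:
    """All rate, cost and shape parameters of the chemostat model.

    Parameters
    ----------
    alpha : float
        Dilution rate of the chemostat, in [0, 1].
    T_in : float
        Toxin concentration flowing into the chemostat, in (0, 1].
    r : float
        Maximum intrinsic growth rate, in (0, 1].
    c_d : float
        Cost of cooperation (enzyme production), fraction of ``r``.
    c_r : float
        Cost of private resistance, fraction of ``r``.
    d_max : float
        Maximum death rate by toxin.
    K_s, K_r : float
        Half-maximal toxin concentrations of sensitive and resistant cells;
        resistance means ``K_s < K_r``.
    n : float
        Hill coefficient of the death response (> 0).
    f_max : float
        Maximum enzymatic degradation rate.
    K_d : float
        Cooperator density giving half-maximal degradation.
    """

    alpha: float = 0.1
    T_in: float = 0.3
    r: float = 1.0
    c_d: float = 0.15
    c_r: float = 0.3
    d_max: float = 1.0
    K_s: float = 0.3
    K_r: float = 0.6
    n: float = 3.0
    f_max: float = 0.5
    K_d: float = 0.2

    def __post_init__(self) -> None:
        for name, (lo, hi, lo_open, hi_open) in _RANGES.items():
            v = getattr(self, name)
            if not np.isfinite(v) and name != "n":
                raise ValueError(f"{name}={v!r} is not finite")
            if (v < lo or (lo_open and v == lo)) or (v > hi or (hi_open and v == hi)):
                lob, hib = "(" if lo_open else "[", ")" if hi_open else "]"
                raise ValueError(
                    f"{name}={v!r} outside allowed range {lob}{lo}, {hi}{hib}"
                )
        if not 0.0 <= self.K_s < self.K_r <= 1.0:
            raise ValueError(
                f"require 0 <= K_s < K_r <= 1 (resistant cells tolerate more "
                f"toxin); got K_s={self.K_s!r}, K_r={self.K_r!r}"
            )
        if self.c_d + self.c_r >= 1.0:
            raise ValueError(
                f"c_d + c_r = {self.c_d + self.c_r!r} must stay below 1 so all "
                "four intrinsic growth rates remain positive"
            )

    def K(self, strategy: Strategy) -> float:
        """Half-maximal toxin concentration of ``strategy``."""
        return self.K_r if strategy.resistant else self.K_s

    def replace(self, **kwargs) -> "ModelParams":
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d.update(kwargs)
        return ModelParams(**d)

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class ChemostatState:
    """Densities of the four strategies plus the toxin concentration.

    ``densities`` maps :class:`Strategy` to a nonnegative density (carrying
    capacity is one); ``T`` is the toxin concentration in the vessel.
    """

    densities: dict[Strategy, float] = field(default_factory=dict)
    T: float = 0.0

    def __post_init__(self) -> None:
        full = {s: float(self.densities.get(s, 0.0)) for s in STRATEGY_ORDER}
        for s, x in full.items():
            if x < 0:
                raise ValueError(f"density of {s.label} is negative: {x}")
        if sum(full.values()) > 1.0 + 1e-9:
            raise ValueError("total density exceeds the carrying capacity of one")
        if self.T < 0:
            raise ValueError(f"toxin concentration is negative: {self.T}")
        self.densities = full

    @classmethod
    def from_vector(cls, y: np.ndarray) -> "ChemostatState":
        """Build a state from ``[x_sCo, x_rCo, x_sCh, x_rCh, T]``."""
        y = np.asarray(y, dtype=float)
        dens = {s: max(float(y[i]), 0.0) for s, i in _INDEX.items()}
        return cls(densities=dens, T=max(float(y[4]), 0.0))

    def to_vector(self) -> np.ndarray:
        """State as ``[x_sCo, x_rCo, x_sCh, x_rCh, T]``."""
        return np.array(
            [self.densities[s] for s in STRATEGY_ORDER] + [self.T], dtype=float
        )

    @property
    def total_density(self) -> float:
        return sum(self.densities.values())

    @property
    def cooperator_density(self) -> float:
        return sum(x for s, x in self.densities.items() if s.cooperator)


# ---------------------------------------------------------------------------
# Rate functions
# ---------------------------------------------------------------------------

def intrinsic_growth_rate(strategy: Strategy, params: ModelParams) -> float:
    """Intrinsic growth rate ``r_i`` with additive trait costs.

    sCh pays nothing; cooperation subtracts ``c_d * r`` and resistance
    subtracts ``c_r * r``, so rCo grows at ``r (1 - c_d - c_r)``.
    """
    cost = 0.0
    if strategy.cooperator:
        cost += params.c_d
    if strategy.resistant:
        cost += params.c_r
    return params.r * (1.0 - cost)


def death_rate(T, strategy: Strategy, params: ModelParams):
    """Hill-type death rate ``delta_i(T) = d_max T^n / (T^n + K_i^n)``.

    ``K_i`` is ``K_s`` for sensitive and ``K_r`` for resistant cells, so
    resistant cells reach the maximum death rate only at higher toxin levels.
    Accepts scalar or array ``T``; negative toxin concentrations are rejected.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T < 0):
        raise ValueError("toxin concentration must be nonnegative")
    K = params.K(strategy)
    Tn = np.power(T, params.n)
    out = params.d_max * Tn / (Tn + K**params.n)
    return out.item() if out.ndim == 0 else out


def death_rate_derivative(T: float, strategy: Strategy, params: ModelParams) -> float:
    """d(delta_i)/dT, used by the analytic Jacobian."""
    if T < 0:
        raise ValueError("toxin concentration must be nonnegative")
    K, n = params.K(strategy), params.n
    if T == 0.0:
        # derivative at the origin: 0 for n > 1, d_max/K for n == 1, inf for n < 1
        if n > 1:
            return 0.0
        if n == 1:
            return params.d_max / K
        return math.inf
    Tn, Kn = T**n, K**n
    return params.d_max * n * T ** (n - 1) * Kn / (Tn + Kn) ** 2


def degradation_rate(x_Co, params: ModelParams):
    """Michaelis--Menten degradation rate ``f(x_Co) = f_max x_Co / (x_Co + K_d)``.

    ``x_Co`` is the *total* cooperator density (sensitive plus resistant);
    the resistance trait has no effect on enzyme secretion.
    """
    x_Co = np.asarray(x_Co, dtype=float)
    if np.any(x_Co < 0):
        raise ValueError("cooperator density must be nonnegative")
    out = params.f_max * x_Co / (x_Co + params.K_d)
    return out.item() if out.ndim == 0 else out


def degradation_rate_derivative(x_Co: float, params: ModelParams) -> float:
    """d f / d x_Co."""
    if x_Co < 0:
        raise ValueError("cooperator density must be nonnegative")
    return params.f_max * params.K_d / (x_Co + params.K_d) ** 2


def fitness_proxy(strategy: Strategy, T, params: ModelParams):
    """Fitness proxy ``W_i(T) = r_i / (delta_i(T) + alpha)``.

    ``W_i(T) > 1`` means the strategy increases from rarity at toxin level
    ``T``; at any equilibrium every extant strategy satisfies
    ``W_i(T*) = 1 / (1 - sum_j x_j)``.
    """
    return intrinsic_growth_rate(strategy, params) / (
        death_rate(T, strategy, params) + params.alpha
    )


# ---------------------------------------------------------------------------
# ODE right-hand side
# ---------------------------------------------------------------------------

def rhs(y: np.ndarray, params: ModelParams) -> np.ndarray:
    """Time derivative of the packed state vector ``[x_sCo, x_rCo, x_sCh, x_rCh, T]``.

    dx_i/dt = x_i [ r_i (1 - sum_j x_j) - delta_i(T) - alpha ]
    dT/dt   = alpha T_in - f(x_Co) T - alpha T

    Densities are clipped at zero before evaluation: solver trial steps may
    undershoot, and a negative density would otherwise feed back through
    the shared ``(1 - sum_j x_j)`` term and blow up.  Extinct strategies
    therefore stay extinct (boundary invariance).
    """
    x = np.clip(y[:4], 0.0, None)
    T = max(float(y[4]), 0.0)
    total = float(np.sum(x))
    dx = np.empty(4)
    for s, i in _INDEX.items():
        dx[i] = x[i] * (
            intrinsic_growth_rate(s, params) * (1.0 - total)
            - death_rate(T, s, params)
            - params.alpha
        )
    x_Co = float(x[0] + x[1])
    dT = params.alpha * params.T_in - degradation_rate(x_Co, params) * T - params.alpha * T
    return np.concatenate([dx, [dT]])


def derivatives(state: ChemostatState, params: ModelParams) -> ChemostatState:
    """Time derivative of a :class:`ChemostatState`, returned with the same layout.

    The returned object's ``densities``/``T`` hold derivatives, so its own
    nonnegativity invariants do not apply; it is built without re-validation.
    """
    dy = rhs(state.to_vector(), params)
    out = ChemostatState.__new__(ChemostatState)
    out.densities = {s: float(dy[i]) for s, i in _INDEX.items()}
    out.T = float(dy[4])
    return out


def jacobian(y: np.ndarray, params: ModelParams) -> np.ndarray:
    """Analytic 5x5 Jacobian of :func:`rhs` at ``y`` (densities clipped at 0)."""
    x = np.clip(y[:4], 0.0, None)
    T = max(float(y[4]), 0.0)
    total = float(np.sum(x))
    J = np.zeros((5, 5))
    for s, i in _INDEX.items():
        r_i = intrinsic_growth_rate(s, params)
        g = r_i * (1.0 - total) - death_rate(T, s, params) - params.alpha
        for j in range(4):
            J[i, j] = -x[i] * r_i + (g if i == j else 0.0)
        J[i, 4] = -x[i] * death_rate_derivative(T, s, params)
    x_Co = max(float(x[0] + x[1]), 0.0)
    fprime = degradation_rate_derivative(x_Co, params)
    J[4, 0] = J[4, 1] = -fprime * T
    J[4, 4] = -degradation_rate(x_Co, params) - params.alpha
    return J


def detox_efficiency(alpha: float, T_in: float, T: float) -> float:
    """Detoxification efficiency ``phi = alpha (T_in - T)``.

    The rate at which toxin is removed by the whole system: outflow volume
    per time (``alpha``) times the concentration drop across the vessel.
    ``T`` above ``T_in`` signals an inconsistent state and is rejected.
    """
    if not 0.0 <= T <= T_in + 1e-12:
        raise ValueError(f"need 0 <= T <= T_in, got T={T!r}, T_in={T_in!r}")
    return alpha * (T_in - min(T, T_in))
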