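"""Discrete-time Markov chain over population states and inoculation control.

Mutation destroys cooperation faster than it recreates it, so left alone the
chemostat ends up cheater-dominated with zero detoxification.  The remedy is
to periodically inoculate cooperators.  The population's genotypic state is
tracked as a discrete-time Markov chain whose transitions are mutations
(probabilities ``mu1`` for the cooperation trait, ``mu2`` for resistance,
``mu1*mu2`` for both) or cooperator inoculations (``m1`` for sCo, ``m2`` for
rCo), each resolved by the short-term invasion rules; arrivals establish
with probability ``epsilon``.  Each state carries a detoxification
efficiency ``phi_i``, and the objectives are the expected efficiency at the
stationary distribution, ``sum_i phi_i pi*_i``, and the cumulative expected
efficiency over a finite horizon, optimized over time-dependent inoculation
probabilities by backward-induction dynamic programming.

State space (the 14 states of the baseline assumption set)
----------------------------------------------------------
Assumptions: mutation and inoculation events fire only in mono-cultures; at
the chosen culture conditions sCo and rCo mutually exclude one another, and
each cooperator excludes the cheater of the *opposite* resistance level.
Under these rules the invader wins exactly when it is a same-resistance
cheater facing a cooperator, or a cooperator facing an opposite-resistance
resident.  Enumerating all strategy pairs gives

* 4 mono-cultures: sCo, rCo, sCh, rCh;
* 6 one-step transient states, one per successful invasion in progress
  (resident <- invader): sCo<-sCh, rCo<-rCh, sCh<-rCo, rCh<-sCo,
  sCo<-rCo, rCo<-sCo, each resolving to the invader's mono-culture in the
  next step;
* 4 unfavorable-inoculation states (a cooperator poured into its own
  mono-culture or into a cheater population it cannot invade): sCo+sCo,
  rCo+rCo, sCh+sCo, rCh+rCo, each returning to the resident mono-culture in
  the next step.

Resistance-flip mutants arising inside a cheater mono-culture (sCh <-> rCh)
have no transient state in this space and no covering assumption; they are
modeled as failing to establish.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import networkx as nx
import numpy as np
import pandas as pd

from .core_model import Strategy

__all__ = [
    "FIG5_PHI",
    "MarkovState",
    "MarkovSpec",
    "TransitionMatrix",
    "Policy",
    "build_state_space",
    "default_phi_vector",
    "transition_matrix",
    "is_ergodic",
    "stationary_distribution",
    "expected_stationary_efficiency",
    "cumulative_efficiency",
    "long_run_average_efficiency",
    "optimize_stationary",
    "dp_optimal_policy",
    "sample_trajectory",
]

_MONO_ORDER = (Strategy.SCO, Strategy.RCO, Strategy.SCH, Strategy.RCH)

#: Illustrative 14-component per-state efficiency vector (see
#: :func:`default_phi_vector` for the mapping onto the canonical ordering).
FIG5_PHI = (0.4, 0.2, 0.0, 0.15, 0.3, 0.15, 0.0, 0.2, 0.35, 0.35, 0.3, 0.0, 0.2, 0.0)


def _invader_wins(resident: Strategy, invader: Strategy) -> bool:
    """Baseline invasion rule: who excludes whom at the chosen conditions."""
    if resident.resistant == invader.resistant:
        return resident.cooperator and not invader.cooperator
    return invader.cooperator


@dataclass(frozen=True)
class MarkovState:
    """One population state: a mono-culture, a transient invasion, or an
    unfavorable inoculation."""

    kind: str                      # "mono" | "transient" | "unfavorable"
    resident: Strategy
    arrival: Strategy | None = None

    @property
    def label(self) -> str:
        if self.kind == "mono":
            return f"mono:{self.resident.label}"
        if self.kind == "transient":
            return f"trans:{self.resident.label}<-{self.arrival.label}"
        return f"unfav:{self.resident.label}+{self.arrival.label}"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def build_state_space(
    include_transients: bool = True,
    include_unfavorable: bool = True,
) -> list[MarkovState]:
    """Enumerate the population-state space from the baseline invasion rule.

    With both flags on this yields exactly 14 states (4 mono-cultures +
    6 transients + 4 unfavorable inoculations); ``include_transients=False``
    resolves invasions instantaneously and ``include_unfavorable=False``
    drops the wasted-inoculation bookkeeping, giving the degenerate
    4-state variant.
    """
    states = [MarkovState("mono", s) for s in _MONO_ORDER]
    if include_transients:
        for res, inv in product(_MONO_ORDER, _MONO_ORDER):
            if res is not inv and _invader_wins(res, inv):
                states.append(MarkovState("transient", res, inv))
    if include_unfavorable:
        for res in _MONO_ORDER:
            for inoc in (Strategy.SCO, Strategy.RCO):
                if inoc is res or not _invader_wins(res, inoc):
                    states.append(MarkovState("unfavorable", res, inoc))
    return states


def default_phi_vector(states: list[MarkovState]) -> np.ndarray:
    """Map the illustrative 14-value efficiency vector onto ``states``.

    The published vector comes without a state ordering, so the assignment
    below is an explicit, documented fixture (overridable via the ``phi``
    argument of :class:`MarkovSpec`): the zeros land on the two cheater
    mono-cultures (forced: ``T = T_in`` with no degraders) and on the two
    unfavorable states of cheater residents; transients toward cooperators
    get the larger values; unfavorable states are reduced relative to their
    resident mono-culture.
    """
    table = {
        "mono:sCo": 0.4,
        "mono:rCo": 0.2,
        "mono:sCh": 0.0,
        "mono:rCh": 0.0,
        "trans:sCo<-sCh": 0.15,
        "trans:rCo<-rCh": 0.15,
        "trans:sCh<-rCo": 0.2,
        "trans:rCh<-sCo": 0.3,
        "trans:sCo<-rCo": 0.35,
        "trans:rCo<-sCo": 0.35,
        "unfav:sCo+sCo": 0.3,
        "unfav:rCo+rCo": 0.2,
        "unfav:sCh+sCo": 0.0,
        "unfav:rCh+rCo": 0.0,
    }
    try:
        return np.array([table[s.label] for s in states])
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"no default phi for state {exc}") from None


@dataclass
class MarkovSpec:
    """State space, per-state efficiencies and event probabilities.

    ``phi`` may carry the time-scale constant ``C`` already folded in; all
    entries must be nonnegative and cheater mono-cultures must be zero.
    ``mu = (mu1, mu2)`` are the per-step mutation probabilities of the
    cooperation and resistance traits; ``epsilon`` is the establishment
    probability of an arriving strategy.
    """

    states: list[MarkovState] = field(default_factory=build_state_space)
    phi: np.ndarray | None = None
    mu: tuple[float, float] = (0.01, 0.0)
    epsilon: float = 1.0

    def __post_init__(self):
        labels = [s.label for s in self.states]
        if len(set(labels)) != len(labels):
            raise ValueError("state labels must be unique")
        if self.phi is None:
            self.phi = default_phi_vector(self.states)
        self.phi = np.asarray(self.phi, dtype=float)
        if self.phi.shape != (len(self.states),):
            raise ValueError(
                f"phi has {self.phi.size} entries for {len(self.states)} states"
            )
        if np.any(self.phi < 0):
            raise ValueError("phi entries must be nonnegative")
        for s, p in zip(self.states, self.phi):
            if s.kind == "mono" and not s.resident.cooperator and p != 0.0:
                raise ValueError(
                    f"cheater mono-culture {s.label} must have phi = 0 "
                    "(T = T_in when only cheaters are present)"
                )
        mu1, mu2 = self.mu
        if not (0.0 <= mu1 <= 1.0 and 0.0 <= mu2 <= 1.0):
            raise ValueError("mutation probabilities must lie in [0, 1]")
        if not 0.0 < self.epsilon <= 1.0:
            raise ValueError("establishment probability must lie in (0, 1]")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def index(self, label: str) -> int:
        for i, s in enumerate(self.states):
            if s.label == label:
                return i
        raise KeyError(label)

    def event_budget(self) -> float:
        """Total per-step event probability excluding inoculations."""
        mu1, mu2 = self.mu
        return mu1 * (1 - mu2) + (1 - mu1) * mu2 + mu1 * mu2

    def max_inoculation(self) -> float:
        """Largest admissible m1 + m2 given the mutation budget."""
        return 1.0 - self.event_budget()


@dataclass
class TransitionMatrix:
    """Row-stochastic transition matrix for one inoculation pair ``m``."""

    P: np.ndarray
    states: list[MarkovState]
    m: tuple[float, float]

    def to_dataframe(self) -> pd.DataFrame:
        labels = [s.label for s in self.states]
        return pd.DataFrame(self.P, index=labels, columns=labels)


def transition_matrix(spec: MarkovSpec, m: tuple[float, float]) -> TransitionMatrix:
    """Build ``P(m; mu, epsilon)`` over ``spec.states``.

    From each mono-culture the five events (three mutation classes, two
    inoculations) are mutually exclusive alternatives with an explicit
    no-event complement; configurations whose probabilities sum above one
    are rejected.  A winning arrival establishes with probability
    ``epsilon`` (moving to its transient state, or straight to its
    mono-culture when transients are not modeled) and otherwise the
    population stays put.  Failed mutant invasions leave the state
    unchanged; failed or pointless cooperator inoculations occupy the
    corresponding unfavorable state for one step when modeled.  Transient
    and unfavorable states resolve deterministically in one step.
    """
    m1, m2 = m
    if not (0.0 <= m1 <= 1.0 and 0.0 <= m2 <= 1.0):
        raise ValueError("inoculation probabilities must lie in [0, 1]")
    mu1, mu2 = spec.mu
    total = spec.event_budget() + m1 + m2
    if total > 1.0 + 1e-12:
        raise ValueError(
            f"event probabilities sum to {total:.4f} > 1; mutation and "
            "inoculation events are mutually exclusive alternatives"
        )
    idx = {s.label: i for i, s in enumerate(spec.states)}
    has_transients = any(s.kind == "transient" for s in spec.states)
    has_unfav = any(s.kind == "unfavorable" for s in spec.states)
    n = spec.n_states
    P = np.zeros((n, n))
    for i, state in enumerate(spec.states):
        if state.kind == "transient":
            P[i, idx[f"mono:{state.arrival.label}"]] = 1.0
            continue
        if state.kind == "unfavorable":
            P[i, idx[f"mono:{state.resident.label}"]] = 1.0
            continue
        res = state.resident
        events: list[tuple[Strategy, float, bool]] = [
            (Strategy.from_traits(not res.cooperator, res.resistant), mu1 * (1 - mu2), False),
            (Strategy.from_traits(res.cooperator, not res.resistant), (1 - mu1) * mu2, False),
            (Strategy.from_traits(not res.cooperator, not res.resistant), mu1 * mu2, False),
            (Strategy.SCO, m1, True),
            (Strategy.RCO, m2, True),
        ]
        stay = 1.0
        for arrival, p, inoculated in events:
            if p == 0.0:
                continue
            stay -= p
            if arrival is not res and _invader_wins(res, arrival):
                dest = (
                    idx[f"trans:{res.label}<-{arrival.label}"]
                    if has_transients
                    else idx[f"mono:{arrival.label}"]
                )
                P[i, dest] += p * spec.epsilon
                P[i, i] += p * (1.0 - spec.epsilon)
            elif inoculated and has_unfav:
                P[i, idx[f"unfav:{res.label}+{arrival.label}"]] += p
            else:
                # failed mutant (or unfavorable inoculation when not modeled)
                P[i, i] += p
        P[i, i] += stay
    assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
    return TransitionMatrix(P=P, states=list(spec.states), m=(float(m1), float(m2)))


def is_ergodic(P: TransitionMatrix | np.ndarray) -> bool:
    """Irreducible and aperiodic on the positive-entry digraph."""
    A = P.P if isinstance(P, TransitionMatrix) else np.asarray(P)
    g = nx.from_numpy_array(A > 0, create_using=nx.DiGraph)
    return nx.is_strongly_connected(g) and nx.is_aperiodic(g)


def stationary_distribution(P: TransitionMatrix | np.ndarray) -> np.ndarray:
    """Unique ``pi* = pi* P`` of an ergodic chain, by linear solve.

    Non-ergodic chains are rejected (use
    :func:`long_run_average_efficiency`, which takes the Cesaro limit from
    an initial distribution, for reducible or periodic cases).
    """
    A = P.P if isinstance(P, TransitionMatrix) else np.asarray(P)
    if not is_ergodic(A):
        raise ValueError(
            "chain is not ergodic: no unique stationary distribution; "
            "evaluate the long-run average from an initial distribution instead"
        )
    n = A.shape[0]
    M = np.vstack([A.T - np.eye(n), np.ones((1, n))])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(M, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def expected_stationary_efficiency(pi: np.ndarray, spec: MarkovSpec) -> float:
    """``sum_i phi_i pi_i`` — expected efficiency at distribution ``pi``."""
    pi = np.asarray(pi, dtype=float)
    if pi.shape != spec.phi.shape:
        raise ValueError("distribution length does not match the state space")
    if not np.isclose(pi.sum(), 1.0, atol=1e-8):
        raise ValueError("distribution must sum to one")
    return float(spec.phi @ pi)


def cumulative_efficiency(
    spec: MarkovSpec,
    m: tuple[float, float],
    pi0: np.ndarray,
    S: int,
) -> float:
    """Cumulative expected efficiency ``sum_{s=0}^{S} phi . pi(s)``.

    ``pi(s) = pi(0) P^s`` under the constant inoculation pair ``m``.
    """
    if S < 0:
        raise ValueError("S must be nonnegative")
    P = transition_matrix(spec, m).P
    pi = np.asarray(pi0, dtype=float).copy()
    total = float(spec.phi @ pi)
    for _ in range(S):
        pi = pi @ P
        total += float(spec.phi @ pi)
    return total


def _recurrent_classes(A: np.ndarray) -> list[list[int]]:
    g = nx.from_numpy_array(A > 0, create_using=nx.DiGraph)
    classes = []
    for comp in nx.strongly_connected_components(g):
        if all(v in comp for u in comp for v in g.successors(u)):
            classes.append(sorted(comp))
    return classes


def long_run_average_efficiency(
    spec: MarkovSpec, m: tuple[float, float], pi0: np.ndarray
) -> float:
    """Cesaro limit of the per-step expected efficiency from ``pi0``.

    Exists for every finite chain: mass is eventually absorbed into the
    recurrent classes, and within each class the time-average distribution
    is the class's unique stationary vector (Cesaro handles periodicity).
    The value is the absorption-probability-weighted mean of the per-class
    stationary efficiencies, computed by linear solves rather than long
    simulation.
    """
    A = transition_matrix(spec, m).P
    pi0 = np.asarray(pi0, dtype=float)
    n = A.shape[0]
    classes = _recurrent_classes(A)
    recurrent = sorted(i for cls in classes for i in cls)
    transient = [i for i in range(n) if i not in recurrent]
    # absorption probabilities from transient states into each class
    value = 0.0
    # per-class stationary efficiency
    class_eff = []
    for cls in classes:
        sub = A[np.ix_(cls, cls)]
        k = len(cls)
        M = np.vstack([sub.T - np.eye(k), np.ones((1, k))])
        b = np.zeros(k + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(M, b, rcond=None)
        pi = np.clip(pi, 0.0, None)
        pi /= pi.sum()
        class_eff.append(float(spec.phi[cls] @ pi))
    if transient:
        Q = A[np.ix_(transient, transient)]
        absorb = np.zeros((len(transient), len(classes)))
        for c, cls in enumerate(classes):
            r = A[np.ix_(transient, cls)].sum(axis=1)
            absorb[:, c] = np.linalg.solve(np.eye(len(transient)) - Q, r)
    for c, cls in enumerate(classes):
        prob = float(pi0[cls].sum())
        if transient:
            prob += float(pi0[transient] @ absorb[:, c])
        value += prob * class_eff[c]
    return value


def _default_action_grid(step: float = 0.05) -> list[tuple[float, float]]:
    vals = np.round(np.arange(0.0, 1.0 + step / 2, step), 10)
    return [(float(a), float(b)) for a in vals for b in vals]


def optimize_stationary(
    spec: MarkovSpec,
    action_grid: list[tuple[float, float]] | None = None,
    pi0: np.ndarray | None = None,
) -> tuple[tuple[float, float], float]:
    """Constant inoculation pair maximizing the long-run expected efficiency.

    Grid search over admissible actions (those whose event probabilities
    sum to at most one).  Ergodic actions are scored by the stationary
    expectation; non-ergodic ones by the Cesaro long-run average from
    ``pi0`` (uniform when omitted).  Ties break toward smaller
    ``(m1, m2)`` lexicographically — fewer interventions.
    """
    if action_grid is None:
        action_grid = _default_action_grid()
    if pi0 is None:
        pi0 = np.full(spec.n_states, 1.0 / spec.n_states)
    budget = spec.max_inoculation()
    best_m, best_v = None, -np.inf
    for m in sorted(action_grid):
        if m[0] + m[1] > budget + 1e-12:
            continue
        P = transition_matrix(spec, m)
        if is_ergodic(P):
            v = expected_stationary_efficiency(stationary_distribution(P), spec)
        else:
            v = long_run_average_efficiency(spec, m, pi0)
        if v > best_v + 1e-12:
            best_m, best_v = m, v
    if best_m is None:
        raise ValueError("no admissible action in the grid")
    return best_m, best_v


@dataclass
class Policy:
    """Time-indexed open-loop inoculation policy from dynamic programming.

    ``actions[s]`` is the inoculation pair reported for step ``s`` —
    the maximizer of expected remaining cumulative efficiency marginalized
    over the state distribution ``pi(s)`` (the operator cannot observe the
    population state).  ``values[s]`` is that expected remaining cumulative
    efficiency; ``per_state_actions`` holds the state-conditional
    maximizers for diagnostics.
    """

    horizon: int
    actions: list[tuple[float, float]]
    values: list[float]
    per_state_actions: np.ndarray | None = None   # (S, n_states, 2)
    state_distributions: np.ndarray | None = None  # (S+1, n_states)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": np.arange(len(self.actions)),
                "m1": [a[0] for a in self.actions],
                "m2": [a[1] for a in self.actions],
                "value": self.values,
            }
        )


def _open_loop_rollout(
    Ps: np.ndarray, phi: np.ndarray, pi0: np.ndarray, seq: np.ndarray
) -> float:
    """Total cumulative efficiency sum_{s=0}^{S} phi . pi(s) of an action sequence."""
    pi = pi0.copy()
    total = float(phi @ pi)
    for a in seq:
        pi = pi @ Ps[a]
        total += float(phi @ pi)
    return total


def _closed_loop_pass(
    Ps: np.ndarray, phi: np.ndarray, pi0: np.ndarray, horizon: int
) -> tuple[np.ndarray, np.ndarray]:
    """Backward induction V(s,i) = phi_i + max_a [P(a) V(s+1)]_i, then a
    forward pass picking the marginalized action per step.

    Returns the chosen action-index sequence and the per-state argmax table
    (diagnostics: what an operator who *could* observe the state would do).
    """
    n = phi.size
    V = np.empty((horizon + 1, n))
    V[horizon] = phi
    argmax_states = np.empty((horizon, n), dtype=int)
    for s in range(horizon - 1, -1, -1):
        cont = Ps @ V[s + 1]              # (A, n)
        best = np.argmax(cont, axis=0)    # first max = lexicographically smallest
        argmax_states[s] = best
        V[s] = phi + cont[best, np.arange(n)]
    pi = pi0.copy()
    seq = np.empty(horizon, dtype=int)
    for s in range(horizon):
        scores = (Ps @ V[s + 1]) @ pi
        seq[s] = int(np.argmax(scores))
        pi = pi @ Ps[seq[s]]
    return seq, argmax_states


def _coordinate_sweeps(
    Ps: np.ndarray,
    phi: np.ndarray,
    pi0: np.ndarray,
    seq: np.ndarray,
    max_sweeps: int = 60,
) -> np.ndarray:
    """Iterate forward-backward sweeps to a self-consistent open-loop policy.

    Costates under the current sequence, lambda(s) = phi + P(a_s)
    lambda(s+1), are the exact sensitivities of the remaining objective; a
    forward sweep then re-picks each action to maximize
    ``pi(s) P(a) lambda(s+1)``.  The objective is multilinear in the action
    sequence, so each accepted sweep cannot decrease it; iteration stops at
    a fixed point (or when a heuristic sweep fails to improve).
    """
    horizon = seq.size
    n = phi.size
    best_val = _open_loop_rollout(Ps, phi, pi0, seq)
    for _ in range(max_sweeps):
        lam = np.empty((horizon + 1, n))
        lam[horizon] = phi
        for s in range(horizon - 1, -1, -1):
            lam[s] = phi + Ps[seq[s]] @ lam[s + 1]
        new_seq = seq.copy()
        pi = pi0.copy()
        for s in range(horizon):
            scores = (Ps @ lam[s + 1]) @ pi
            new_seq[s] = int(np.argmax(scores))
            pi = pi @ Ps[new_seq[s]]
        if np.array_equal(new_seq, seq):
            break
        val = _open_loop_rollout(Ps, phi, pi0, new_seq)
        if val <= best_val + 1e-12:
            break
        seq, best_val = new_seq, val
    return seq


def dp_optimal_policy(
    spec: MarkovSpec,
    pi0: np.ndarray,
    horizon: int,
    action_grid: list[tuple[float, float]] | None = None,
) -> Policy:
    """Open-loop inoculation schedule maximizing cumulative efficiency.

    The operator cannot observe the population state, so the policy is a
    time-indexed action sequence judged against the evolving state
    *distribution*.  Backward induction of the value function
    ``V(s, i) = phi_i + max_a [P(a) V(s+1)]_i`` followed by a forward pass
    that picks the marginalized maximizer of
    ``pi(s) . [phi + P(a) V(s+1)]`` seeds the schedule; forward-backward
    coordinate-ascent sweeps (exact costate sensitivities of the open-loop
    objective) then refine it to self-consistency.  A second seed — the
    best constant action, including non-ergodic ones scored by their Cesaro
    average — guards against poor local optima; the better refined schedule
    is returned.  Ties break toward the lexicographically smallest action
    (fewer interventions).
    """
    if horizon < 1:
        raise ValueError("horizon must be at least 1")
    if action_grid is None:
        action_grid = _default_action_grid()
    budget = spec.max_inoculation()
    actions = sorted(a for a in action_grid if a[0] + a[1] <= budget + 1e-12)
    if not actions:
        raise ValueError("no admissible action in the grid")
    Ps = np.stack([transition_matrix(spec, a).P for a in actions])  # (A, n, n)
    n = spec.n_states
    phi = spec.phi
    pi0 = np.asarray(pi0, dtype=float)

    seed_cl, argmax_states = _closed_loop_pass(Ps, phi, pi0, horizon)
    # second seed: best constant action by its own finite-horizon rollout
    const_vals = [
        _open_loop_rollout(Ps, phi, pi0, np.full(horizon, a)) for a in range(len(actions))
    ]
    seed_const = np.full(horizon, int(np.argmax(const_vals)))
    candidates = [
        _coordinate_sweeps(Ps, phi, pi0, seed)
        for seed in (seed_cl, seed_const)
    ]
    seq = max(candidates, key=lambda s: _open_loop_rollout(Ps, phi, pi0, s))

    # final costates/distributions under the returned schedule
    lam = np.empty((horizon + 1, n))
    lam[horizon] = phi
    for s in range(horizon - 1, -1, -1):
        lam[s] = phi + Ps[seq[s]] @ lam[s + 1]
    dists = np.empty((horizon + 1, n))
    dists[0] = pi0
    for s in range(horizon):
        dists[s + 1] = dists[s] @ Ps[seq[s]]
    values = [float(dists[s] @ lam[s]) for s in range(horizon)]
    per_state = np.array(
        [[actions[argmax_states[s, i]] for i in range(n)] for s in range(horizon)]
    )
    return Policy(
        horizon=horizon,
        actions=[actions[a] for a in seq],
        values=values,
        per_state_actions=per_state,
        state_distributions=dists,
    )


def sample_trajectory(
    spec: MarkovSpec,
    policy: Policy | None = None,
    m: tuple[float, float] | None = None,
    steps: int | None = None,
    seed: int = 0,
    pi0: np.ndarray | None = None,
) -> list[int]:
    """Reproducible stochastic realization of the chain.

    Either follow a DP ``policy`` for its horizon or a constant inoculation
    pair ``m`` for ``steps`` steps.  The same seed always yields the same
    state sequence.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_states
    if pi0 is None:
        pi0 = np.zeros(n)
        pi0[0] = 1.0
    if policy is not None:
        plans = policy.actions
    elif m is not None and steps is not None:
        plans = [m] * steps
    else:
        raise ValueError("provide a policy, or a constant m with steps")
    cache: dict[tuple[float, float], np.ndarray] = {}
    state = int(rng.choice(n, p=np.asarray(pi0) / np.sum(pi0)))
    seq = [state]
    for a in plans:
        if a not in cache:
            cache[a] = transition_matrix(spec, a).P
        state = int(rng.choice(n, p=cache[a][state]))
        seq.append(state)
    return seq
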