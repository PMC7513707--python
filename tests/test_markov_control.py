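"""State-transition Markov chain, stationary analysis, and DP control."""

from itertools import product

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from detoxevo import (
    FIG5_PHI,
    MarkovSpec,
    Strategy,
    build_state_space,
    cumulative_efficiency,
    default_phi_vector,
    dp_optimal_policy,
    expected_stationary_efficiency,
    is_ergodic,
    long_run_average_efficiency,
    optimize_stationary,
    sample_trajectory,
    stationary_distribution,
    transition_matrix,
)


def _spec(mu=(0.01, 0.0), epsilon=1.0, phi=None, **kw):
    return MarkovSpec(states=build_state_space(**kw), mu=mu, epsilon=epsilon, phi=phi)


def _point_mass(spec, label):
    pi0 = np.zeros(spec.n_states)
    pi0[spec.index(label)] = 1.0
    return pi0


class TestStateSpace:
    def test_baseline_space_has_fourteen_states(self):
        states = build_state_space()
        assert len(states) == 14
        kinds = [s.kind for s in states]
        assert kinds.count("mono") == 4
        assert kinds.count("transient") == 6
        assert kinds.count("unfavorable") == 4

    def test_monoculture_only_variant(self):
        assert len(build_state_space(False, False)) == 4

    def test_count_decomposes_by_assumption_flags(self):
        # structural identity: 4 + #transients + #unfavorable
        n_trans = sum(
            1 for s in build_state_space(True, False) if s.kind == "transient"
        )
        n_unfav = sum(
            1 for s in build_state_space(False, True) if s.kind == "unfavorable"
        )
        assert len(build_state_space()) == 4 + n_trans + n_unfav

    def test_labels_unique(self):
        labels = [s.label for s in build_state_space()]
        assert len(set(labels)) == len(labels)

    def test_phi_fixture_zeros_cheater_monocultures(self):
        states = build_state_space()
        phi = default_phi_vector(states)
        assert sorted(phi) == sorted(FIG5_PHI)
        for s, p in zip(states, phi):
            if s.kind == "mono" and not s.resident.cooperator:
                assert p == 0.0

    def test_spec_rejects_nonzero_phi_on_cheater_monoculture(self):
        states = build_state_space()
        phi = default_phi_vector(states)
        phi[[s.label for s in states].index("mono:sCh")] = 0.1
        with pytest.raises(ValueError):
            MarkovSpec(states=states, phi=phi)


class TestTransitionMatrix:
    def test_no_events_freezes_every_monoculture(self):
        spec = _spec(mu=(0.0, 0.0))
        P = transition_matrix(spec, (0.0, 0.0)).P
        for s in spec.states:
            if s.kind == "mono":
                i = spec.index(s.label)
                assert P[i, i] == 1.0
        # the degenerate mono-culture-only chain is exactly the identity
        spec4 = _spec(mu=(0.0, 0.0), include_transients=False, include_unfavorable=False)
        assert np.array_equal(transition_matrix(spec4, (0.0, 0.0)).P, np.eye(4))

    @settings(derandomize=True, max_examples=60)
    @given(
        mu1=st.floats(0.0, 0.2),
        mu2=st.floats(0.0, 0.2),
        m1=st.floats(0.0, 0.3),
        m2=st.floats(0.0, 0.3),
        eps=st.floats(0.1, 1.0),
    )
    def test_rows_always_stochastic(self, mu1, mu2, m1, m2, eps):
        spec = _spec(mu=(mu1, mu2), epsilon=eps)
        assume(m1 + m2 <= spec.max_inoculation())
        P = transition_matrix(spec, (m1, m2)).P
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(P >= 0.0) and np.all(P <= 1.0)

    def test_overcommitted_probabilities_rejected(self):
        spec = _spec(mu=(0.5, 0.0))
        with pytest.raises(ValueError):
            transition_matrix(spec, (0.4, 0.2))

    def test_cheater_state_absorbing_without_inoculation(self):
        # mu2 = 0: once sCh dominates, cooperation cannot reappear
        spec = _spec(mu=(0.01, 0.0))
        P = transition_matrix(spec, (0.0, 0.0)).P
        i = spec.index("mono:sCh")
        assert P[i, i] == 1.0

    def test_establishment_probability_splits_arrivals(self):
        full = transition_matrix(_spec(), (0.0, 0.0)).P
        half = transition_matrix(_spec(epsilon=0.5), (0.0, 0.0)).P
        i = _spec().index("mono:sCo")
        j = _spec().index("trans:sCo<-sCh")
        assert half[i, j] == pytest.approx(full[i, j] * 0.5)
        assert half[i, i] == pytest.approx(full[i, i] + full[i, j] * 0.5)

    def test_transients_resolve_to_invader_in_one_step(self):
        spec = _spec()
        P = transition_matrix(spec, (0.1, 0.1)).P
        assert P[spec.index("trans:sCh<-rCo"), spec.index("mono:rCo")] == 1.0
        assert P[spec.index("unfav:sCh+sCo"), spec.index("mono:sCh")] == 1.0


class TestErgodicity:
    def test_identity_not_ergodic(self):
        assert not is_ergodic(np.eye(3))

    def test_inoculated_chain_is_ergodic(self):
        spec = _spec(mu=(0.01, 0.0))
        assert is_ergodic(transition_matrix(spec, (0.05, 0.05)))

    def test_uninoculated_chain_is_not(self):
        spec = _spec(mu=(0.01, 0.0))
        assert not is_ergodic(transition_matrix(spec, (0.0, 0.0)))


class TestStationaryDistribution:
    def test_two_state_symmetric_chain(self):
        P = np.array([[0.9, 0.1], [0.1, 0.9]])
        assert np.allclose(stationary_distribution(P), [0.5, 0.5], atol=1e-12)

    def test_non_ergodic_rejected(self):
        with pytest.raises(ValueError):
            stationary_distribution(np.eye(4))

    def test_matches_power_iteration_on_random_chains(self, rng):
        for _ in range(5):
            P = rng.dirichlet(np.ones(14) * 0.5, size=14) + 1e-9
            P /= P.sum(axis=1, keepdims=True)
            pi = stationary_distribution(P)
            q = np.full(14, 1 / 14)
            for _ in range(20000):
                q_next = q @ P
                if np.max(np.abs(q_next - q)) < 1e-15:
                    q = q_next
                    break
                q = q_next
            assert np.max(np.abs(pi - q)) < 1e-10
            assert np.max(np.abs(pi @ P - pi)) < 1e-12

    def test_invariant_under_squaring(self):
        spec = _spec()
        P = transition_matrix(spec, (0.1, 0.2)).P
        pi = stationary_distribution(P)
        pi2 = stationary_distribution(P @ P)
        assert np.allclose(pi, pi2, atol=1e-10)


class TestEfficiencyObjectives:
    def test_point_mass_on_zero_state(self):
        spec = _spec()
        pi = _point_mass(spec, "mono:sCh")
        assert expected_stationary_efficiency(pi, spec) == 0.0

    def test_simple_average(self):
        spec = _spec()
        pi = np.zeros(14)
        pi[spec.index("mono:sCo")] = 0.5
        pi[spec.index("mono:sCh")] = 0.5
        assert expected_stationary_efficiency(pi, spec) == pytest.approx(
            0.5 * spec.phi[spec.index("mono:sCo")]
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            expected_stationary_efficiency(np.array([1.0]), _spec())

    def test_cumulative_at_zero_steps(self):
        spec = _spec()
        pi0 = _point_mass(spec, "mono:sCo")
        assert cumulative_efficiency(spec, (0.1, 0.1), pi0, 0) == pytest.approx(
            spec.phi[spec.index("mono:sCo")]
        )

    def test_cumulative_vanishes_with_zero_phi(self):
        spec = _spec(phi=np.zeros(14))
        pi0 = _point_mass(spec, "mono:sCo")
        assert cumulative_efficiency(spec, (0.2, 0.1), pi0, 50) == 0.0

    def test_cumulative_rate_approaches_stationary_expectation(self):
        spec = _spec()
        m = (0.1, 0.1)
        phat = expected_stationary_efficiency(
            stationary_distribution(transition_matrix(spec, m)), spec
        )
        S = 100_000
        pi0 = _point_mass(spec, "mono:sCo")
        rate = cumulative_efficiency(spec, m, pi0, S) / (S + 1)
        assert rate == pytest.approx(phat, rel=1e-3)

    def test_collapse_without_inoculation(self):
        # mu1 > 0, mu2 = 0, no inoculation: cheaters take over for good
        spec = _spec(mu=(0.01, 0.0))
        pi0 = _point_mass(spec, "mono:sCo")
        assert long_run_average_efficiency(spec, (0.0, 0.0), pi0) == pytest.approx(0.0)


class TestOptimizeStationary:
    def test_flat_objective_breaks_ties_toward_no_intervention(self):
        spec = _spec(phi=np.zeros(14))
        m, v = optimize_stationary(spec, action_grid=[(0.2, 0.1), (0.0, 0.0), (0.1, 0.0)])
        assert m == (0.0, 0.0)
        assert v == 0.0

    def test_optimum_requires_inoculation_when_mutation_destroys_cooperation(self):
        spec = _spec(mu=(0.01, 0.0))
        pi0 = _point_mass(spec, "mono:sCo")
        m, v = optimize_stationary(spec, pi0=pi0)
        assert max(m) > 0.0
        assert v > 0.0


class TestDynamicProgramming:
    def test_flat_rewards_give_no_intervention(self):
        spec = _spec(phi=np.zeros(14))
        pi0 = _point_mass(spec, "mono:sCo")
        pol = dp_optimal_policy(spec, pi0, horizon=1)
        assert pol.actions == [(0.0, 0.0)]

    def test_first_step_from_cooperator_monoculture_is_hands_off(self):
        spec = _spec(mu=(0.01, 0.0), phi=np.asarray(
            default_phi_vector(build_state_space())))
        pi0 = _point_mass(spec, "mono:sCo")
        pol = dp_optimal_policy(spec, pi0, horizon=300)
        assert pol.actions[0] == (0.0, 0.0)

    def test_values_shrink_with_remaining_horizon(self):
        spec = _spec(mu=(0.01, 0.0))
        pi0 = _point_mass(spec, "mono:sCo")
        pol = dp_optimal_policy(spec, pi0, horizon=200)
        assert np.all(np.diff(pol.values) <= 1e-9)

    def test_beats_every_constant_schedule(self):
        spec = _spec(mu=(0.01, 0.0))
        pi0 = _point_mass(spec, "mono:sCo")
        grid = [(a, b) for a in (0.0, 0.25, 0.5) for b in (0.0, 0.25, 0.5)]
        horizon = 400
        pol = dp_optimal_policy(spec, pi0, horizon, action_grid=grid)
        for m in grid:
            if sum(m) > spec.max_inoculation():
                continue
            assert pol.values[0] >= cumulative_efficiency(spec, m, pi0, horizon) - 1e-9

    def test_matches_exhaustive_enumeration_on_small_chain(self):
        # 4-state mono-culture-only chain, 4 actions, short horizon: the DP
        # schedule must attain the brute-force open-loop optimum
        spec = _spec(mu=(0.1, 0.05), phi=np.array([0.4, 0.2, 0.0, 0.0]),
                     include_transients=False, include_unfavorable=False)
        pi0 = np.array([1.0, 0.0, 0.0, 0.0])
        grid = [(0.0, 0.0), (0.0, 0.4), (0.4, 0.0), (0.4, 0.4)]
        horizon = 5
        pol = dp_optimal_policy(spec, pi0, horizon, action_grid=grid)
        Ps = {m: transition_matrix(spec, m).P for m in grid}
        best = -np.inf
        for seq in product(grid, repeat=horizon):
            pi = pi0.copy()
            total = float(spec.phi @ pi)
            for m in seq:
                pi = pi @ Ps[m]
                total += float(spec.phi @ pi)
            best = max(best, total)
        assert pol.values[0] == pytest.approx(best, abs=1e-10)


class TestSampleTrajectory:
    def test_identity_chain_never_moves(self):
        spec = _spec(mu=(0.0, 0.0))
        seq = sample_trajectory(spec, m=(0.0, 0.0), steps=50, seed=7)
        assert len(set(seq)) == 1

    def test_same_seed_same_realization(self):
        spec = _spec(mu=(0.01, 0.0))
        a = sample_trajectory(spec, m=(0.1, 0.1), steps=500, seed=123)
        b = sample_trajectory(spec, m=(0.1, 0.1), steps=500, seed=123)
        assert a == b

    def test_empirical_frequencies_match_stationary_law(self):
        spec = _spec(mu=(0.05, 0.02))
        m = (0.3, 0.25)
        P = transition_matrix(spec, m)
        pi = stationary_distribution(P)
        n = 100_000
        seq = sample_trajectory(spec, m=m, steps=n, seed=2024)
        counts = np.bincount(seq[1000:], minlength=spec.n_states)
        freq = counts / counts.sum()
        sigma = np.sqrt(pi * (1 - pi) / counts.sum())
        assert np.all(np.abs(freq - pi) <= 3 * sigma + 1e-4)
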