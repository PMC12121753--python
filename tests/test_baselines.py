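"""Activity-driven sampling and group-change dynamics."""

import numpy as np
import pytest
from scipy.stats import spearmanr

import helpers
from hypercast.core import TemporalHypergraph, aggregate
from hypercast.baselines import (
    GroupChangeParams,
    activity_potentials,
    change_probability,
    fit_group_change,
    group_state_from_history,
    sample_activity_driven,
    simulate_group_change,
    step_group_change,
)


class TestActivityPotentials:
    def test_fraction_of_events(self):
        events_at = {t: {(1, 2)} for t in range(1, 4)}
        events_at.update({t: {(3, 4)} for t in range(4, 11)})
        H = TemporalHypergraph(node_set=frozenset(range(1, 5)), horizon=10,
                               events_at=events_at)
        pots = activity_potentials(H, orders=(2,))
        assert pots.for_order(2)[1] == pytest.approx(0.3)
        assert pots.for_order(2)[3] == pytest.approx(0.7)

    def test_sums_to_order(self, markov_net):
        pots = activity_potentials(markov_net)
        for d in (2, 3, 4):
            assert sum(pots.for_order(d).values()) == pytest.approx(d)

    def test_inactive_node_gets_zero(self, markov_net):
        H = TemporalHypergraph(
            node_set=markov_net.node_set | {999}, horizon=markov_net.horizon,
            events_at=markov_net.events_at,
        )
        pots = activity_potentials(H)
        assert pots.for_order(2)[999] == 0.0


class TestActivityDrivenSampling:
    def test_single_candidate_is_certain(self, markov_agg, rng):
        H = TemporalHypergraph(node_set=frozenset({1, 2, 3}), horizon=2,
                               events_at={1: {(1, 2, 3)}, 2: {(1, 2, 3)}})
        agg = aggregate(H)
        pots = activity_potentials(H, orders=(3,))
        out = sample_activity_driven(agg, pots, {3: 1}, rng)
        assert out[3] == {(1, 2, 3)}

    def test_concentrated_potential(self, rng):
        H = TemporalHypergraph(node_set=frozenset(range(1, 5)), horizon=4,
                               events_at={1: {(1, 2)}, 2: {(1, 2)}, 3: {(1, 2)},
                                          4: {(3, 4)}})
        agg = aggregate(H)
        pots = activity_potentials(H, orders=(2,))
        # overwhelm node 1's weight: pick from events containing node 1 only
        pots.potentials[2] = {1: 1.0, 2: 0.0, 3: 0.0, 4: 0.0}
        for _ in range(50):
            assert sample_activity_driven(agg, pots, {2: 1}, rng)[2] == {(1, 2)}

    def test_uniform_two_candidates_split_evenly(self, rng):
        H = TemporalHypergraph(node_set=frozenset(range(1, 5)), horizon=2,
                               events_at={1: {(1, 2)}, 2: {(3, 4)}})
        agg = aggregate(H)
        pots = activity_potentials(H, orders=(2,))
        n_draws = 10_000
        first = sum(
            sample_activity_driven(agg, pots, {2: 1}, rng)[2] == {(1, 2)}
            for _ in range(n_draws)
        )
        se = np.sqrt(0.25 / n_draws)
        assert abs(first / n_draws - 0.5) < 3 * se

    def test_inclusion_frequency_tracks_potential(self, markov_net, markov_agg):
        rng = np.random.default_rng(99)
        pots = activity_potentials(markov_net)
        freq = {u: 0 for u in markov_net.node_set}
        n_draws = 2000
        for _ in range(n_draws):
            out = sample_activity_driven(markov_agg, pots, {2: 3}, rng)
            for h in out[2]:
                for u in h:
                    freq[u] += 1
        nodes = sorted(markov_net.node_set)
        rho, _ = spearmanr([pots.for_order(2)[u] for u in nodes],
                           [freq[u] for u in nodes])
        assert rho > 0


class TestChangeProbability:
    def _params(self, **kw):
        base = dict(beta=-0.8, b_d={1: 1.0, 2: 2.0, 3: 2.5, 4: 2.8},
                    d0=4.0, alpha_logistic=1.0)
        base.update(kw)
        return GroupChangeParams(**base)

    def test_zero_amplitude_freezes(self):
        p = self._params(b_d={d: 0.0 for d in range(1, 5)})
        assert change_probability(p, 2, 5, 50) == 0.0

    def test_decreasing_in_residence_with_negative_beta(self):
        p = self._params()
        vals = [change_probability(p, 2, tau, 50) for tau in range(1, 200)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))
        # tends to b_d / N from above
        assert vals[-1] == pytest.approx(2.0 / 50, rel=0.05)

    def test_clipped_to_unit_interval(self):
        p = self._params(b_d={2: 500.0})
        assert change_probability(p, 2, 1, 10) == 1.0

    def test_logistic_limits(self):
        # saturating steepness: b_d -> d0 for d >= 2; b_1 = d0/2 always
        logistic = lambda d, d0, a: d0 / (1.0 + np.exp(-a * (d - 1.0)))
        assert logistic(1, 4.0, 1e6) == pytest.approx(2.0)
        for d in (2, 3, 4):
            assert logistic(d, 4.0, 1e3) == pytest.approx(4.0)


class TestStepGroupChange:
    def _frozen_params(self, **kw):
        base = dict(beta=-0.8, b_d={d: 0.0 for d in range(1, 5)},
                    d0=0.0, alpha_logistic=1.0, epsilon=100, L=10)
        base.update(kw)
        return GroupChangeParams(**base)

    def test_zero_change_probability_freezes_state(self, markov_net, rng):
        state = group_state_from_history(markov_net, 50)
        new = step_group_change(state, markov_net, self._frozen_params(), 50, rng)
        assert new.groups == state.groups
        assert all(new.residence[u] == state.residence[u] + 1
                   for u in markov_net.node_set)

    def test_huge_epsilon_isolates_all_changers(self, markov_net, rng):
        params = self._frozen_params(
            b_d={d: 1e9 for d in range(1, 5)}, epsilon=10**9)
        state = group_state_from_history(markov_net, 50)
        new = step_group_change(state, markov_net, params, 50, rng)
        assert all(len(g) == 1 for g in new.groups.values())

    def test_changer_joins_fully_encountered_group(self, rng):
        # node 3 has met {1, 2} in the window but never {4, 5}
        events = {t: {(1, 2, 3)} for t in range(1, 10)}
        events[10] = {(1, 2), (4, 5)}
        H = TemporalHypergraph(node_set=frozenset(range(1, 6)), horizon=11,
                               events_at=events)
        params = GroupChangeParams(beta=-0.8,
                                   b_d={1: 1e9, 2: 0.0, 3: 0.0, 4: 0.0},
                                   d0=0.0, alpha_logistic=1.0, epsilon=0, L=10)
        state = group_state_from_history(H, 10)
        assert state.membership[3] != state.membership[1]
        new = step_group_change(state, H, params, 10, rng)
        assert new.membership[3] == new.membership[1]

    def test_partition_maintained_over_many_steps(self, markov_net):
        rng = np.random.default_rng(4)
        params = GroupChangeParams(beta=-0.8,
                                   b_d={1: 2.0, 2: 3.0, 3: 3.5, 4: 3.8},
                                   d0=4.0, alpha_logistic=1.0, epsilon=5, L=10)
        state = group_state_from_history(markov_net, 30)
        for t in range(30, 60):
            state = step_group_change(state, markov_net, params, t, rng)
            state.check_partition(markov_net.node_set)


class TestFitGroupChange:
    def test_recovers_exponent_and_amplitude_ordering(self):
        # observable hazard equals the model curve by construction
        b_true = {2: 3.5, 3: 4.2, 4: 4.6}
        rels = []
        for seed in (1, 2, 3):
            H = helpers.paired_reshuffle_network(-0.8, b_true, 6000, seed)
            fit = fit_group_change(H, L=30)
            rels.append(abs(fit.beta + 0.8) / 0.8)
            b_raw = fit.diagnostics["b_raw"]
            assert b_raw[2] < b_raw[3] < b_raw[4]
        assert np.median(rels) <= 0.10

    def test_insufficient_spread_raises(self):
        H = helpers.static_hypergraph({(1, 2), (3, 4)}, horizon=30)
        with pytest.raises(ValueError):
            fit_group_change(H, L=10)

    def test_simulated_dynamics_stay_partitioned(self):
        params = GroupChangeParams(beta=-0.8,
                                   b_d={1: 1.0, 2: 1.5, 3: 1.8, 4: 1.9},
                                   d0=2.0, alpha_logistic=1.0, epsilon=2, L=20)
        rng = np.random.default_rng(0)
        H = simulate_group_change(30, params, 200, rng,
                                  init_group_sizes=(2, 2, 3, 3, 4))
        assert H.event_counts_by_order().get(2, 0) > 0
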