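"""Decay features, tendency models, Lasso fitting and top-n selection."""

import math

import numpy as np
import pytest

import helpers
from hypercast.core import (
    NeighborType,
    TemporalHypergraph,
    aggregate,
    aggregate_pairwise,
    decompose_pairwise,
    enumerate_phi_types,
)
from hypercast.models import (
    DecayParams,
    InsufficientHistoryError,
    ModelCoefficients,
    SelfDrivenModel,
    TendencyModel,
    decay_feature,
    default_alpha_grid,
    fit_lasso,
    predict_topn,
    refined_phi_set,
    tendency_general,
    tendency_self_driven,
)


class TestDecayFeature:
    def test_zero_tau_counts_window_activations(self, markov_agg):
        params = DecayParams(L=10, tau=0.0)
        target = markov_agg.by_order[3][0]
        phi = NeighborType(3, 3, 3)
        y = decay_feature(markov_agg, target, phi, 20, params)
        x = markov_agg.activity[target]
        assert y == pytest.approx(float(x[10:20].sum()))

    def test_single_recent_activation_weighs_one(self):
        H = TemporalHypergraph(node_set=frozenset({1, 2}), horizon=6,
                               events_at={6: {(1, 2)}})
        agg = aggregate(H)
        y = decay_feature(agg, (1, 2), NeighborType(2, 2, 2), 6,
                          DecayParams(L=4, tau=3.7))
        assert y == pytest.approx(1.0)

    def test_halving_decay(self):
        H = TemporalHypergraph(node_set=frozenset({1, 2}), horizon=5,
                               events_at={4: {(1, 2)}, 5: {(1, 2)}})
        agg = aggregate(H)
        y = decay_feature(agg, (1, 2), NeighborType(2, 2, 2), 5,
                          DecayParams(L=4, tau=math.log(2)))
        assert y == pytest.approx(1.5)

    def test_insufficient_history_raises(self, markov_agg):
        with pytest.raises(InsufficientHistoryError):
            decay_feature(markov_agg, markov_agg.by_order[2][0],
                          NeighborType(2, 2, 2), 10, DecayParams(L=30, tau=1))

    def test_matches_double_loop_oracle(self, markov_agg):
        rng = np.random.default_rng(5)
        params = DecayParams(L=12, tau=0.8)
        for _ in range(20):
            d = int(rng.choice([2, 3, 4]))
            target = markov_agg.by_order[d][int(rng.integers(len(markov_agg.by_order[d])))]
            phis = enumerate_phi_types(d, 4)
            phi = phis[int(rng.integers(len(phis)))]
            t = int(rng.integers(params.L, markov_agg.horizon + 1))
            rows = [markov_agg.activity[h]
                    for h in markov_agg.neighbors_of(target, phi)]
            expect = helpers.brute_force_decay(rows, t, params.L, params.tau)
            got = decay_feature(markov_agg, target, phi, t, params)
            assert got == pytest.approx(expect, rel=1e-12, abs=1e-12)

    def test_monotone_in_added_activation(self):
        base = {4: {(1, 2)}}
        H1 = TemporalHypergraph(node_set=frozenset({1, 2}), horizon=6, events_at=dict(base))
        H2 = TemporalHypergraph(node_set=frozenset({1, 2}), horizon=6,
                                events_at={**base, 5: {(1, 2)}})
        params = DecayParams(L=5, tau=0.3)
        y1 = decay_feature(aggregate(H1), (1, 2), NeighborType(2, 2, 2), 6, params)
        y2 = decay_feature(aggregate(H2), (1, 2), NeighborType(2, 2, 2), 6, params)
        assert y2 > y1


class TestSelfDrivenTendency:
    def test_always_active_with_zero_tau_equals_window(self):
        H = helpers.static_hypergraph({(1, 2)}, horizon=20)
        aggp = aggregate_pairwise(decompose_pairwise(H))
        w = tendency_self_driven(aggp, (1, 2), 10, DecayParams(L=7, tau=0.0))
        assert w == pytest.approx(7.0)

    def test_single_oldest_activation(self):
        H = TemporalHypergraph(node_set=frozenset({1, 2}), horizon=10,
                               events_at={7: {(1, 2)}})
        aggp = aggregate_pairwise(decompose_pairwise(H))
        w = tendency_self_driven(aggp, (1, 2), 10, DecayParams(L=4, tau=math.log(2)))
        assert w == pytest.approx(0.125)

    def test_never_active_scores_zero(self):
        H = TemporalHypergraph(node_set=frozenset({1, 2, 3}), horizon=10,
                               events_at={1: {(1, 2)}, 9: {(1, 2)}, 5: {(2, 3)}})
        aggp = aggregate_pairwise(decompose_pairwise(H))
        w = tendency_self_driven(aggp, (2, 3), 9, DecayParams(L=3, tau=1.0))
        assert w == 0.0


class TestTendencyGeneral:
    def test_zero_coefficients_give_intercept(self, markov_agg):
        params = DecayParams(L=10, tau=1.0)
        phi_set = enumerate_phi_types(2, 4)
        coeffs = ModelCoefficients(2, 0.7, {p.label: 0.0 for p in phi_set},
                                   phi_set, params, alpha=0.0)
        for h in markov_agg.by_order[2][:5]:
            assert tendency_general(markov_agg, h, 15, params, coeffs) == 0.7

    def test_linear_combination_of_features(self, markov_agg):
        params = DecayParams(L=10, tau=1.0)
        phi_set = refined_phi_set(3, 4)
        cmap = {"322": 0.3, "333": 1.0, "343": 0.9}
        coeffs = ModelCoefficients(3, 0.1, cmap, phi_set, params, alpha=0.0)
        target = markov_agg.by_order[3][0]
        expect = 0.1 + sum(
            cmap[p.label] * decay_feature(markov_agg, target, p, 20, params)
            for p in phi_set
        )
        assert tendency_general(markov_agg, target, 20, params, coeffs) == \
            pytest.approx(expect)

    def test_target_only_reduces_to_self_driven_form(self, markov_agg):
        params = DecayParams(L=10, tau=0.5)
        phi = NeighborType(3, 3, 3)
        coeffs = ModelCoefficients(3, 0.0, {phi.label: 1.0}, [phi], params, alpha=0.0)
        for target in markov_agg.by_order[3][:5]:
            w = tendency_general(markov_agg, target, 20, params, coeffs)
            rows = [markov_agg.activity[target]]
            assert w == pytest.approx(
                helpers.brute_force_decay(rows, 20, params.L, params.tau))


class TestFitLasso:
    def test_default_grid_endpoints(self):
        grid = default_alpha_grid()
        assert len(grid) == 200
        assert grid[0] == pytest.approx(1e-19)
        assert grid[-1] == pytest.approx(10.0)

    def test_full_shrinkage_at_large_alpha(self, markov_net, markov_agg):
        c = fit_lasso(markov_net, markov_agg, 3, DecayParams(L=30, tau=5.0),
                      alpha_grid=[10.0], standardize=True)
        assert all(v == 0.0 for v in c.coeffs.values())

    def test_degenerate_labels_give_intercept_only(self):
        H = helpers.static_hypergraph({(1, 2), (3, 4)}, horizon=40)
        agg = aggregate(H)
        with pytest.warns(UserWarning, match="degenerate"):
            c = fit_lasso(H, agg, 2, DecayParams(L=10, tau=1.0))
        assert c.intercept == 1.0
        assert all(v == 0.0 for v in c.coeffs.values())

    def test_requires_training_steps(self, markov_agg):
        with pytest.raises(ValueError, match="T >= L"):
            fit_lasso(None, markov_agg, 2, DecayParams(L=119, tau=1.0))


class TestPredictTopN:
    def test_clear_winner(self, rng):
        assert predict_topn({"a": 0.9, "b": 0.5, "c": 0.1}, 1, rng) == {"a"}

    def test_all_candidates(self, rng):
        scores = {"a": 0.9, "b": 0.5, "c": 0.5}
        assert predict_topn(scores, 3, rng) == set(scores)

    def test_negative_n_rejected(self, rng):
        with pytest.raises(ValueError):
            predict_topn({"a": 1.0}, -1, rng)

    def test_boundary_ties_sampled_uniformly(self, rng):
        scores = {"a": 0.9, "b": 0.5, "c": 0.5}
        n_draws = 10_000
        picked_b = 0
        for _ in range(n_draws):
            sel = predict_topn(scores, 2, rng)
            assert "a" in sel and len(sel) == 2
            picked_b += "b" in sel
        se = math.sqrt(0.25 / n_draws)
        assert abs(picked_b / n_draws - 0.5) < 3 * se

    def test_zero_tau_target_ranking_matches_window_counts(self, markov_agg, rng):
        params = DecayParams(L=20, tau=0.0)
        phi = NeighborType(2, 2, 2)
        t = 40
        scores = {
            h: decay_feature(markov_agg, h, phi, t, params)
            for h in markov_agg.by_order[2]
        }
        counts = {h: float(markov_agg.activity[h][t - 20:t].sum())
                  for h in markov_agg.by_order[2]}
        assert scores == pytest.approx(counts)


class TestSelfDrivenModel:
    def test_static_network_reproduced_exactly(self, rng):
        H = helpers.static_hypergraph({(1, 2, 3), (4, 5)}, horizon=50)
        model = SelfDrivenModel(H, DecayParams(L=30, tau=5.0))
        pred = model.predict(40, rng)
        assert pred == {3: {(1, 2, 3)}, 2: {(4, 5)}}

    def test_no_edges_predicts_no_events(self, rng):
        H = TemporalHypergraph(node_set=frozenset({1, 2}), horizon=50,
                               events_at={1: {(1, 2)}, 45: {(1, 2)}})
        model = SelfDrivenModel(H, DecayParams(L=10, tau=1.0))
        assert model.predict(30, rng) == {}  # true count at 31 is zero

    def test_predicted_triangle_promotes_to_one_event(self, rng):
        events = {t: {(1, 2), (1, 3), (2, 3)} for t in range(1, 41)}
        events[41] = {(1, 2, 3)}
        H = TemporalHypergraph(node_set=frozenset({1, 2, 3}), horizon=41,
                               events_at=events)
        model = SelfDrivenModel(H, DecayParams(L=10, tau=1.0))
        pred = model.predict(40, rng)
        assert pred == {3: {(1, 2, 3)}}


class TestTendencyModel:
    def test_refined_equals_general_when_other_coefficients_zero(self, markov_net):
        params = DecayParams(L=30, tau=5.0)
        gen = TendencyModel(markov_net, params, mode="general")
        ref = TendencyModel(markov_net, params, mode="refined")
        phi_gen = enumerate_phi_types(3, 4)
        cmap_gen = {p.label: (0.5 if p.kind != "other" else 0.0) for p in phi_gen}
        gen.set_coefficients({3: ModelCoefficients(3, 0.2, cmap_gen, phi_gen,
                                                   params, alpha=0.0)})
        phi_ref = refined_phi_set(3, 4)
        ref.set_coefficients({3: ModelCoefficients(3, 0.2,
                                                   {p.label: 0.5 for p in phi_ref},
                                                   phi_ref, params, alpha=0.0)})
        wg = gen.tendencies(3, 60)
        wr = ref.tendencies(3, 60)
        for h in wg:
            assert wg[h] == pytest.approx(wr[h])

    def test_nonzero_support_shrinks_along_alpha_grid(self, markov_agg):
        from hypercast.models import coefficient_path, training_matrix
        X, y = training_matrix(markov_agg, 3, DecayParams(L=30, tau=5.0))
        grid = default_alpha_grid(1e-4, 10.0, 30)
        path = coefficient_path(X, y, grid, standardize=True)
        nnz = (np.abs(path) > 1e-12).sum(axis=1)
        assert np.all(np.diff(nnz) <= 0)
        assert nnz[-1] == 0
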