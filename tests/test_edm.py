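import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from attractortest.edm import (
    CrossMapForecaster,
    SimplexForecaster,
    cross_map_forecast,
    embed,
    embed_array,
    neighbor_weights,
    select_embedding_dimension,
    simplex_forecast,
)
from attractortest.exceptions import InsufficientDataError
from attractortest.series import standardize

import reference as ref
from conftest import make_series


class TestEmbed:
    def test_basic_vectors(self):
        s = make_series([1.0, 2.0, 3.0, 4.0], times=np.array([1.0, 2.0, 3.0, 4.0]))
        vs = embed(s, 2)
        assert [(v.anchor_time, v.components) for v in vs] == [
            (2.0, (2.0, 1.0)),
            (3.0, (3.0, 2.0)),
            (4.0, (4.0, 3.0)),
        ]

    def test_E1_is_identity(self):
        s = make_series([5.0, 6.0, 7.0])
        vs = embed(s, 1)
        assert len(vs) == 3
        assert all(v.components == (x,) for v, x in zip(vs, [5.0, 6.0, 7.0]))

    def test_vector_count(self):
        x = np.sin(np.arange(17.0))
        for E in (1, 2, 5):
            vectors, anchors = embed_array(x, E)
            assert vectors.shape == (17 - E + 1, E)
            assert anchors[0] == E - 1

    def test_too_short_raises(self):
        with pytest.raises(InsufficientDataError):
            embed(make_series([1.0, 2.0, 3.0, 4.0]), 5)


class TestNeighborWeights:
    def test_equal_distances_give_uniform_weights(self):
        w = neighbor_weights([2.0, 2.0, 2.0, 2.0])
        np.testing.assert_allclose(w, 0.25, atol=1e-15)

    def test_hand_computed_values(self):
        # u = exp(-1), exp(-2), exp(-3) normalized.
        w = neighbor_weights([1.0, 2.0, 3.0])
        np.testing.assert_allclose(w, [0.66524096, 0.24472847, 0.09003057], atol=1e-7)

    def test_zero_distance_convention(self):
        np.testing.assert_allclose(neighbor_weights([0.0, 0.0, 5.0]), [0.5, 0.5, 0.0])

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            neighbor_weights([2.0, 1.0])

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=100.0), min_size=2, max_size=12)
    )
    def test_weights_sum_to_one_and_decrease(self, distances):
        d = np.sort(np.asarray(distances))
        w = neighbor_weights(d)
        assert abs(w.sum() - 1.0) < 1e-12
        assert np.all(np.diff(w) <= 1e-15)  # non-increasing in distance


class TestEmbeddingSelection:
    def test_period2_is_perfectly_predictable_at_smallest_E(self):
        s = standardize(make_series([1.0, -1.0] * 8))
        att = select_embedding_dimension(s, E_max=5)
        assert att.cv_skill > 1 - 1e-9
        # exhaustive oracle: the smallest E with perfect skill must win
        smallest_perfect = min(
            E for E in range(1, 6)
            if (ref.ref_pearson(
                [o for _, o, _ in ref.ref_simplex_forecast(list(s.values), list(s.values), E, True)],
                [p for _, _, p in ref.ref_simplex_forecast(list(s.values), list(s.values), E, True)],
            ) or -2) > 1 - 1e-9
        )
        assert att.E == smallest_perfect

    def test_white_noise_has_no_skill(self):
        # Monte Carlo: the cross-validated skill of i.i.d. noise is
        # statistically indistinguishable from zero.
        rng = np.random.default_rng(7)
        ok = 0
        n_trials = 200
        for _ in range(n_trials):
            s = standardize(make_series(rng.standard_normal(60)))
            att = select_embedding_dimension(s)
            ok += abs(att.cv_skill) < 0.45
        assert ok / n_trials >= 0.95

    def test_series_too_short(self):
        with pytest.raises(InsufficientDataError):
            select_embedding_dimension(make_series(np.sin(np.arange(6.0))), E_max=5)

    def test_library_size_matches_selected_E(self):
        s = standardize(make_series(np.sin(0.7 * np.arange(40.0))))
        att = select_embedding_dimension(s)
        assert att.vectors.shape == (len(s) - att.E + 1, att.E)


class TestSimplexForecast:
    def test_noise_free_cycle_forecasts_itself_exactly(self):
        s = standardize(make_series([1.0, -1.0] * 10, label="cycle"))
        att = select_embedding_dimension(s, E_max=3)
        res = simplex_forecast(s, att, self_exclusion=True)
        np.testing.assert_allclose(res.predicted, res.observed, atol=1e-9)

    def test_without_exclusion_self_match_absorbs_weight(self):
        s = standardize(make_series(np.sin(0.9 * np.arange(25.0)), label="c"))
        att = select_embedding_dimension(s, E_max=4)
        res = simplex_forecast(s, att, self_exclusion=False)
        np.testing.assert_allclose(res.predicted, res.observed, atol=1e-12)

    def test_wrong_cycle_library_gives_large_errors(self):
        two = standardize(make_series([1.0, -1.0] * 12, label="two"))
        four = standardize(make_series([1.0, 0.2, -1.0, -0.2] * 6, label="four"))
        att4 = select_embedding_dimension(four, E_max=4)
        res = simplex_forecast(two, att4, self_exclusion=False)
        assert np.max(np.abs(res.predicted - res.observed)) > 0.1

    def test_forecast_is_convex_combination_of_successors(self):
        rng = np.random.default_rng(3)
        lib = standardize(make_series(rng.standard_normal(30), label="lib"))
        tgt = standardize(make_series(rng.standard_normal(20), label="tgt"))
        att = select_embedding_dimension(lib)
        res = simplex_forecast(tgt, att, self_exclusion=False)
        succ = lib.values[att.anchor_idx[att.anchor_idx < len(lib) - 1] + 1]
        assert np.all(res.predicted >= succ.min() - 1e-12)
        assert np.all(res.predicted <= succ.max() + 1e-12)

    def test_standardized_scale_invariance(self):
        rng = np.random.default_rng(5)
        raw_lib = rng.standard_normal(30)
        raw_tgt = rng.standard_normal(25)
        errors = []
        for a, b in ((1.0, 0.0), (37.5, -4.0)):
            lib = standardize(make_series(a * raw_lib + b, label="lib"))
            tgt = standardize(make_series(a * raw_tgt + b, label="tgt"))
            att = select_embedding_dimension(lib, E_max=4)
            res = simplex_forecast(tgt, att, self_exclusion=False)
            errors.append(res.predicted - res.observed)
        np.testing.assert_allclose(errors[0], errors[1], atol=1e-9)


class TestCrossMap:
    def test_self_cross_map_of_cycle_is_exact(self):
        s = standardize(make_series([1.0, 0.0, -1.0, 0.0] * 6, label="c"))
        att = select_embedding_dimension(s, E_max=4)
        res = cross_map_forecast(s, s, att, s, self_exclusion=True)
        np.testing.assert_allclose(res.predicted, res.observed, atol=1e-9)

    def test_coupled_food_chain_variables_cross_map_well(self, ensemble, rng):
        bundle = ensemble.draw("B", 100, 0.01, rng)
        P = standardize(bundle["P"])
        C = standardize(bundle["C"])
        att = select_embedding_dimension(P)
        res = cross_map_forecast(P, C, att, C, self_exclusion=True)
        assert res.pearson() > 0.9

    def test_independent_noise_does_not_cross_map(self):
        rng = np.random.default_rng(11)
        ok = 0
        n_trials = 200
        for _ in range(n_trials):
            x = standardize(make_series(rng.standard_normal(100), label="a"))
            y = standardize(make_series(rng.standard_normal(100), label="a"))
            att = select_embedding_dimension(x)
            res = cross_map_forecast(x, y, att, y, self_exclusion=True)
            ok += abs(res.pearson()) < 0.4
        assert ok / n_trials >= 0.95


class TestOracleEquivalence:
    """Exhaustive-search reference agreement on short series."""

    @pytest.mark.parametrize("seed,n,E", [(0, 12, 1), (1, 20, 2), (2, 30, 3), (3, 25, 4)])
    def test_simplex_forecast_matches_reference(self, seed, n, E):
        rng = np.random.default_rng(seed)
        lib = list(rng.standard_normal(n))
        tgt = list(rng.standard_normal(n - 3))
        f = SimplexForecaster(embedding_dim=E).fit(np.array(lib))
        res = f.forecast(np.array(tgt))
        expected = ref.ref_simplex_forecast(tgt, lib, E, exclude_self=False)
        assert len(res) == len(expected)
        for (t, obs, pred), o, p in zip(expected, res.observed, res.predicted):
            assert o == obs
            assert p == pytest.approx(pred, abs=1e-12)

    @pytest.mark.parametrize("seed,n,E", [(4, 18, 2), (5, 26, 3)])
    def test_self_excluded_forecast_matches_reference(self, seed, n, E):
        rng = np.random.default_rng(seed)
        x = list(rng.standard_normal(n))
        f = SimplexForecaster(embedding_dim=E).fit(np.array(x))
        res = f.forecast(np.array(x), exclude_self=True)
        expected = ref.ref_simplex_forecast(x, x, E, exclude_self=True)
        for (t, obs, pred), p in zip(expected, res.predicted):
            assert p == pytest.approx(pred, abs=1e-12)

    @pytest.mark.parametrize("seed,n,E", [(6, 20, 2), (7, 30, 4)])
    def test_cross_map_matches_reference(self, seed, n, E):
        rng = np.random.default_rng(seed)
        lx, ly = list(rng.standard_normal(n)), list(rng.standard_normal(n))
        tx, ty = list(rng.standard_normal(n - 2)), list(rng.standard_normal(n - 2))
        f = CrossMapForecaster(embedding_dim=E).fit(np.array(lx), np.array(ly))
        res = f.forecast(np.array(tx), np.array(ty))
        expected = ref.ref_cross_map_forecast(tx, ty, lx, ly, E, exclude_self=False)
        for (t, obs, pred), o, p in zip(expected, res.observed, res.predicted):
            assert o == obs
            assert p == pytest.approx(pred, abs=1e-12)

    def test_tied_distances_break_to_smaller_anchor(self):
        # A periodic library has exactly duplicated vectors, so the
        # (E+1)-th neighbor is frequently tied; the deterministic
        # tie-breaking must match the reference everywhere.
        x = [1.0, -1.0, 0.5, 1.0, -1.0, 0.5] * 4
        f = SimplexForecaster(embedding_dim=2).fit(np.array(x))
        res = f.forecast(np.array(x), exclude_self=True)
        expected = ref.ref_simplex_forecast(x, x, 2, exclude_self=True)
        for (t, obs, pred), p in zip(expected, res.predicted):
            assert p == pytest.approx(pred, abs=1e-12)

    def test_embedding_selection_matches_reference(self):
        rng = np.random.default_rng(9)
        x = np.sin(0.8 * np.arange(24.0)) + 0.1 * rng.standard_normal(24)
        s = standardize(make_series(x))
        att = select_embedding_dimension(s, E_max=5)
        best_E, best_r = ref.ref_loo_best_E(list(s.values), 5)
        assert att.E == best_E
        assert att.cv_skill == pytest.approx(best_r, abs=1e-10)


class TestEstimatorInterface:
    def test_get_set_params_roundtrip(self):
        f = SimplexForecaster(embedding_dim=3, theiler=1)
        params = f.get_params()
        assert params["embedding_dim"] == 3
        clone = SimplexForecaster().set_params(**params)
        assert clone.embedding_dim == 3 and clone.theiler == 1

    def test_unfitted_predict_raises(self):
        with pytest.raises(RuntimeError, match="not fitted"):
            SimplexForecaster().predict(np.arange(10.0))

    def test_fitted_attributes(self):
        s = standardize(make_series(np.sin(0.7 * np.arange(40.0))))
        f = SimplexForecaster().fit(s)
        assert hasattr(f, "attractor_")
        assert f.embedding_dim_ == f.attractor_.E
        assert np.isfinite(f.cv_skill_)
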