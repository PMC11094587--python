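import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edmcast import (
    ExclusionPolicy,
    TimeSeries,
    build_lag_matrix,
    construct_library,
    euclidean_distance,
    first_difference,
    forecast_next,
    make_diff,
    predict_point,
    rank_neighbours,
    simplex_weights,
    valid_focal_times,
)

from .oracles import brute_force_simplex


class TestEuclideanDistance:
    def test_three_four_five(self):
        assert euclidean_distance((0, 0), (3, 4)) == 5.0

    def test_identity(self):
        v = np.array([1.5, -2.0, 7.0])
        assert euclidean_distance(v, v) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            euclidean_distance([1, 2], [1, 2, 3])

    @given(st.integers(min_value=1, max_value=8), st.integers(min_value=0, max_value=10**6))
    @settings(max_examples=50, deadline=None)
    def test_against_sum_of_squares_oracle(self, E, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=E), rng.normal(size=E)
        oracle = math.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))
        assert euclidean_distance(a, b) == pytest.approx(oracle, rel=1e-14)


class TestSimplexWeights:
    def test_nearest_weight_is_exp_minus_one(self):
        w = simplex_weights(np.array([0.3, 0.7, 2.1]))
        assert w[0] == pytest.approx(math.exp(-1))

    def test_equal_distances_all_exp_minus_one(self):
        w = simplex_weights(np.array([0.5, 0.5, 0.5]))
        np.testing.assert_allclose(w, math.exp(-1))

    def test_direct_substitution(self):
        w = simplex_weights(np.array([1.0, 2.0, 4.0]))
        np.testing.assert_allclose(w, [math.exp(-1), math.exp(-2), math.exp(-4)])

    def test_zero_nearest_distance(self):
        w = simplex_weights(np.array([0.0, 0.0, 1.0, 2.0]))
        np.testing.assert_allclose(w, [1.0, 1.0, math.exp(-1), math.exp(-2)])

    def test_all_zero_distances_equal_weights(self):
        np.testing.assert_array_equal(simplex_weights(np.zeros(3)), np.ones(3))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            simplex_weights(np.array([]))

    def test_unsorted_raises(self):
        with pytest.raises(ValueError, match="ascending"):
            simplex_weights(np.array([2.0, 1.0]))

    @given(
        st.lists(st.floats(min_value=1e-6, max_value=1e3), min_size=1, max_size=10),
    )
    def test_weight_bounds_property(self, raw):
        from hypothesis import assume

        d = np.sort(np.array(raw))
        assume(d[-1] / d[0] < 700)  # exp(-x) underflows to 0 beyond ~745
        w = simplex_weights(d)
        assert np.all(w > 0) and np.all(w <= w[0]) and w[0] <= 1.0
        assert np.all(np.diff(w) <= 0)


class TestRankNeighbours:
    def test_matches_brute_force_sort(self, random_series):
        diff = first_difference(random_series)
        lag = build_lag_matrix(diff, 3)
        t_star = 40
        lib = construct_library(lag, t_star)
        nbrs = rank_neighbours(lag, lib, t_star, k=6)
        focal = lag.row(t_star)
        oracle = sorted(
            lib.member_times,
            key=lambda t: (float(np.linalg.norm(lag.row(t) - focal)), t),
        )[:6]
        assert list(nbrs.times) == oracle
        assert np.all(np.diff(nbrs.distances) >= 0)

    def test_duplicate_focal_ranks_first_with_zero_distance(self):
        # duplicate the focal state elsewhere in the series
        vals = np.array([0.0, 1.0, 3.0, 2.0, 5.0, 1.0, 3.0, 2.0, 4.0, 0.0, 2.0, 4.0, 1.0])
        ts = TimeSeries(np.cumsum(vals))  # diffs equal vals[1:]
        diff = first_difference(ts)
        lag = build_lag_matrix(diff, 2)
        # rows 3 and 7 share (Y_t, Y_{t-1}) by construction
        lib = construct_library(lag, 3, ExclusionPolicy.radius(0))
        nbrs = rank_neighbours(lag, lib, 3, k=3)
        assert nbrs.times[0] == 7
        assert nbrs.distances[0] == 0.0
        assert nbrs.weights[0] == 1.0

    def test_library_smaller_than_k(self):
        rng = np.random.default_rng(0)
        diff = first_difference(TimeSeries(rng.normal(size=12)))
        lag = build_lag_matrix(diff, 3)
        lib = construct_library(lag, 5)
        with pytest.raises(ValueError, match=rf"C={lib.size}"):
            rank_neighbours(lag, lib, 5, k=lib.size + 1)

    def test_default_k_is_E_plus_one(self, random_series):
        diff = first_difference(random_series)
        lag = build_lag_matrix(diff, 4)
        lib = construct_library(lag, 50)
        assert len(rank_neighbours(lag, lib, 50).times) == 5


class TestPredictPoint:
    def test_constant_targets_give_that_value(self):
        # neighbours all map to the same target value -> prediction equals it
        ts = TimeSeries(np.cumsum([0.0] + [1.0, 2.0] * 10))  # diffs alternate 1,2
        diff = first_difference(ts)
        lag = build_lag_matrix(diff, 2)
        # focal rows with x = (1,2) all map to Y_{t+1} = 2
        pred = predict_point(lag, 10)
        t1 = pred.focal_t + 1
        assert pred.y_hat == pytest.approx(diff.at(t1))

    def test_matches_brute_force_oracle(self, random_series):
        y = first_difference(random_series).values
        lag = build_lag_matrix(first_difference(random_series), 3)
        for t_star in (3, 17, 42, 77, 98):
            pred = predict_point(lag, t_star)
            oracle = brute_force_simplex(y, 3, t_star)
            assert pred.y_hat == pytest.approx(oracle, rel=1e-12)

    def test_radius_policy_matches_oracle(self, random_series):
        y = first_difference(random_series).values
        lag = build_lag_matrix(first_difference(random_series), 2)
        for t_star in (5, 30, 60, 95):
            pred = predict_point(lag, t_star, ExclusionPolicy.radius(0))
            oracle = brute_force_simplex(y, 2, t_star, radius_k=0)
            assert pred.y_hat == pytest.approx(oracle, rel=1e-12)

    def test_convexity_neighbour_targets(self, spiky_series):
        diff = first_difference(spiky_series)
        lag = build_lag_matrix(diff, 3)
        for t_star in valid_focal_times(spiky_series.T, 3):
            pred = predict_point(lag, t_star)
            targets = [diff.at(t + 1) for t in pred.neighbours.times]
            assert min(targets) - 1e-12 <= pred.y_hat <= max(targets) + 1e-12
            assert diff.values.min() - 1e-12 <= pred.y_hat <= diff.values.max() + 1e-12

    def test_determinism(self, spiky_series):
        lag = build_lag_matrix(first_difference(spiky_series), 4)
        a = predict_point(lag, 50)
        b = predict_point(lag, 50)
        assert a.y_hat == b.y_hat
        assert a.neighbours.times == b.neighbours.times
        np.testing.assert_array_equal(a.neighbours.weights, b.neighbours.weights)


class TestForecastNext:
    def test_forecast_uses_last_valid_focal_time(self, spiky_series):
        fc = forecast_next(spiky_series, 3)
        assert fc.focal_t == spiky_series.T - 1
        assert fc.n_hat == pytest.approx(fc.y_hat + spiky_series.at(spiky_series.T))

    def test_clamp_to_min_remedy(self):
        # engineer a negative raw-scale forecast: negative diffs dominate
        rng = np.random.default_rng(11)
        vals = np.abs(rng.normal(size=40)) * 0.01 + np.linspace(2.0, 0.02, 40)
        ts = TimeSeries(vals)
        fc_none = forecast_next(ts, 2, remedy="none")
        fc_clamp = forecast_next(ts, 2, remedy="clamp_to_min")
        if fc_none.n_hat < 0:
            assert fc_clamp.n_hat == pytest.approx(float(vals.min()))
        else:
            assert fc_clamp.n_hat == fc_none.n_hat

    def test_log_transform_requires_positive(self):
        ts = TimeSeries(np.concatenate([[-1.0], np.ones(30)]))
        with pytest.raises(ValueError, match="positive"):
            forecast_next(ts, 2, remedy="log_transform")

    def test_log_transform_back_transforms(self, spiky_series):
        fc = forecast_next(spiky_series, 3, remedy="log_transform")
        log_fc = forecast_next(TimeSeries(np.log(spiky_series.values)), 3, remedy="none")
        assert fc.n_hat == pytest.approx(math.exp(log_fc.n_hat))
        assert fc.n_hat > 0

    def test_periodic_series_forecast(self):
        # strictly periodic diffs: neighbours are exact matches, the forecast
        # equals the next periodic value
        period = [1.0, -2.0, 0.5, 0.5]
        vals = np.cumsum([0.0] + period * 12)
        ts = TimeSeries(vals)
        fc = forecast_next(ts, 4)
        L = ts.T - 1  # diffs Y_1..Y_48 cycle with period 4
        expected_next = period[L % 4]
        assert fc.y_hat == pytest.approx(expected_next)

    def test_unknown_remedy(self, spiky_series):
        with pytest.raises(ValueError, match="remedy"):
            forecast_next(spiky_series, 2, remedy="banana")


@given(st.integers(min_value=0, max_value=10**6))
@settings(max_examples=25, deadline=None)
def test_prediction_convexity_property(seed):
    rng = np.random.default_rng(seed)
    ts = TimeSeries(rng.normal(size=30))
    diff = first_difference(ts)
    lag = build_lag_matrix(diff, 2)
    for t_star in valid_focal_times(30, 2):
        pred = predict_point(lag, t_star)
        targets = [diff.at(t + 1) for t in pred.neighbours.times]
        assert min(targets) - 1e-12 <= pred.y_hat <= max(targets) + 1e-12
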