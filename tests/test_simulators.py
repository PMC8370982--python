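import numpy as np
import pytest

from attractortest.exceptions import BistabilityError, DegenerateSeriesError
from attractortest.simulators import (
    ASSParams,
    FoodChainParams,
    add_observation_noise,
    ass_drift,
    classify_food_chain_regime,
    estimate_cycle_period,
    find_fold_points,
    sample_series,
    simulate_ass,
    simulate_food_chain,
    skeleton_equilibria,
)

import reference as ref
from conftest import make_series


class TestFoodChain:
    def test_equilibrium_regime_settles(self, food_chain_trajectories):
        traj = food_chain_trajectories[0.78]
        for series in traj.values():
            tail = series.values[-100:]
            assert np.max(np.abs(np.diff(tail))) < 1e-4

    def test_regime_classification(self, food_chain_trajectories):
        expected = {0.78: "equilibrium", 0.85: "cycle_2", 0.92: "cycle_4", 0.997: "aperiodic"}
        for K, label in expected.items():
            assert classify_food_chain_regime(food_chain_trajectories[K]["C"]) == label

    def test_states_positive_and_bounded(self, food_chain_trajectories):
        for traj in food_chain_trajectories.values():
            for series in traj.values():
                assert np.all(series.values > 0)
                assert np.all(series.values < 5.0)

    def test_chaotic_sensitivity_to_initial_conditions(self):
        # Twin runs differing by 1e-8 diverge to attractor-scale separation.
        base = simulate_food_chain(
            FoodChainParams(K=0.997), total_time=11000, burn_in=10000
        )
        twin = simulate_food_chain(
            FoodChainParams(K=0.997), total_time=11000, burn_in=10000,
            initial_state=(0.8 + 1e-8, 0.2, 1.0),
        )
        sep = np.max(np.abs(base["C"].values - twin["C"].values))
        assert sep > 0.1 * np.ptp(base["C"].values)

    def test_tolerance_robustness_of_periodic_regime(self):
        a = simulate_food_chain(FoodChainParams(K=0.85), total_time=10300, burn_in=10000)
        b = simulate_food_chain(
            FoodChainParams(K=0.85), total_time=10300, burn_in=10000,
            rtol=5e-9, atol=5e-11,
        )
        assert np.max(np.abs(a["C"].values - b["C"].values)) < 1e-5

    def test_invalid_setup_raises(self):
        with pytest.raises(ValueError):
            simulate_food_chain(FoodChainParams(K=0.85), total_time=10.0, burn_in=20.0)
        with pytest.raises(ValueError):
            FoodChainParams(K=-1.0)


class TestSampling:
    def test_every_one_is_identity(self):
        s = make_series(np.sin(np.arange(10.0)))
        out = sample_series(s, every=1)
        np.testing.assert_array_equal(out.values, s.values)

    def test_every_five_counts(self):
        s = make_series(np.arange(10.0))
        assert len(sample_series(s, every=5)) == 2

    def test_two_point_cycle_sampled_at_ten_per_cycle(self, food_chain_trajectories):
        series = food_chain_trajectories[0.85]["C"]
        period = estimate_cycle_period(series)
        sampled = sample_series(series, every=5)
        samples_per_cycle = period / sampled.dt
        assert abs(samples_per_cycle - 10.0) <= 2.0


class TestObservationNoise:
    def test_rho_zero_is_identity(self):
        s = make_series(np.sin(np.arange(20.0)))
        out = add_observation_noise(s, 0.0, seed=1)
        np.testing.assert_array_equal(out.values, s.values)

    def test_noise_scale_matches_rho(self):
        rng = np.random.default_rng(0)
        s = make_series(np.sin(0.3 * np.arange(10000.0)))
        rho = 0.2
        noisy = add_observation_noise(s, rho, rng=rng)
        resid_sd = np.std(noisy.values - s.values, ddof=1)
        target = rho * np.std(s.values, ddof=1)
        assert abs(resid_sd - target) <= 0.03 * target

    def test_seed_determinism(self):
        s = make_series(np.sin(np.arange(50.0)))
        a = add_observation_noise(s, 0.1, seed=7)
        b = add_observation_noise(s, 0.1, seed=7)
        np.testing.assert_array_equal(a.values, b.values)

    def test_zero_variance_input_raises(self):
        with pytest.raises(DegenerateSeriesError):
            add_observation_noise(make_series(np.ones(10)), 0.1, seed=0)

    def test_noise_is_unbiased(self):
        s = make_series(np.sin(0.3 * np.arange(200.0)))
        rho = 0.1
        acc = np.zeros(len(s))
        n_rep = 1000
        for seed in range(n_rep):
            acc += add_observation_noise(s, rho, seed=seed).values
        sd = rho * np.std(s.values, ddof=1)
        assert np.max(np.abs(acc / n_rep - s.values)) < 3 * sd / np.sqrt(n_rep) * 4


class TestClassifier:
    def test_constant_series(self):
        assert classify_food_chain_regime(make_series(np.ones(50))) == "equilibrium"

    def test_simple_wave_is_two_point(self):
        t = np.arange(400.0)
        s = make_series(np.sin(2 * np.pi * t / 25.0))
        assert classify_food_chain_regime(s) == "cycle_2"

    def test_period_doubled_wave_is_four_point(self):
        t = np.arange(800.0)
        s = make_series(
            np.sin(2 * np.pi * t / 25.0) + 0.4 * np.sin(np.pi * t / 25.0)
        )
        assert classify_food_chain_regime(s) == "cycle_4"


class TestStochasticModel:
    def test_sigma_zero_stays_on_equilibrium(self):
        params = ASSParams(c=2.2, sigma=0.0, branch="lower", seed=0)
        s = simulate_ass(params, n_samples=200)
        eq = [x for x, st in skeleton_equilibria(2.2) if st == "stable"][0]
        assert np.max(np.abs(s.values - eq)) < 1e-4

    def test_seed_determinism(self):
        p = ASSParams(c=2.2, branch="upper", seed=42)
        a = simulate_ass(p, n_samples=100)
        b = simulate_ass(p, n_samples=100)
        np.testing.assert_array_equal(a.values, b.values)

    def test_lower_branch_stays_in_basin(self):
        s = simulate_ass(ASSParams(c=2.2, branch="lower", seed=3), n_samples=10000)
        eqs = skeleton_equilibria(2.2)
        lower = min(x for x, st in eqs if st == "stable" and x > 1e-9)
        middle = [x for x, st in eqs if st == "unstable" and x > 1e-9][0]
        assert abs(np.mean(s.values) - lower) <= 0.05 * lower
        assert np.max(s.values) < middle  # no stochastic flip

    def test_halving_dt_converges_for_sigma_zero(self):
        coarse = simulate_ass(ASSParams(c=2.0, sigma=0.0, dt=0.02, branch="upper"), 50)
        fine = simulate_ass(ASSParams(c=2.0, sigma=0.0, dt=0.01, branch="upper"), 50)
        assert np.max(np.abs(coarse.values - fine.values)) < 1e-3

    def test_branch_outside_window_raises(self):
        with pytest.raises(BistabilityError):
            simulate_ass(ASSParams(c=1.0, branch="lower", seed=0), 10)
        with pytest.raises(BistabilityError):
            simulate_ass(ASSParams(c=3.5, branch="upper", seed=0), 10)


class TestSkeleton:
    def test_logistic_limit_at_c_zero(self):
        eqs = skeleton_equilibria(0.0, K=11.0)
        assert eqs == [(0.0, "unstable"), (pytest.approx(11.0, abs=1e-9), "stable")]

    def test_three_equilibria_in_bistable_window(self):
        eqs = [x for x, _ in skeleton_equilibria(2.2) if x > 1e-9]
        assert len(eqs) == 3
        states = [s for x, s in skeleton_equilibria(2.2) if x > 1e-9]
        assert states == ["stable", "unstable", "stable"]

    def test_single_low_state_beyond_upper_fold(self):
        eqs = [(x, s) for x, s in skeleton_equilibria(3.5) if x > 1e-9]
        assert len(eqs) == 1
        assert eqs[0][1] == "stable"
        assert eqs[0][0] < 2.0

    def test_equilibria_are_drift_roots(self):
        for c in (0.5, 1.9, 2.2, 2.8, 3.5):
            for x, _ in skeleton_equilibria(c):
                assert abs(float(ass_drift(x, c))) < 1e-7

    def test_fold_points_match_scan_oracle(self):
        c_lower, c_upper = find_fold_points(11.0)
        transitions = ref.ref_fold_scan(ass_drift, c_lo=1.5, c_hi=3.2, c_step=1e-3)
        assert abs(c_lower - transitions[0]) < 2e-3
        assert abs(c_upper - transitions[-1]) < 2e-3

    def test_grid_harvest_rates_are_bistable(self):
        c_lower, c_upper = find_fold_points(11.0)
        for c in np.round(np.arange(1.83, 2.731, 0.05), 2):
            assert c_lower < c < c_upper
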