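"""Metabolic rate/cost model, moving-time normalisation, fitting, bootstrap."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from reachvigor.metabolics import (
    BlockSummary,
    GasSeries,
    MetabolicParams,
    bootstrap_optimal_durations,
    brockway_power,
    cost_per_movement,
    fit_rate_model,
    minimum_cost,
    movement_cost,
    moving_rate,
    optimal_duration,
    rate_model,
    steady_state_power,
)

REPORTED = MetabolicParams(a=98.25, b=0.86, i=0.83, j=5.83)


class TestBrockway:
    @pytest.mark.parametrize(
        "vo2,vco2,expected",
        [(0.0, 0.0, 0.0), (4.0, 3.2, 80.752), (1.0, 0.0, 16.58), (0.0, 1.0, 4.51)],
    )
    def test_hand_values(self, vo2, vco2, expected):
        assert brockway_power(vo2, vco2) == pytest.approx(expected)

    def test_negative_flow_rejected(self):
        with pytest.raises(ValueError):
            brockway_power(-0.1, 1.0)


class TestSteadyState:
    def test_constant_series(self):
        t = np.arange(0, 301, 5.0)
        g = GasSeries(t, np.full_like(t, 4.0), np.full_like(t, 3.2))
        assert steady_state_power(g) == pytest.approx(80.752)

    def test_windowing_ignores_early_segment(self):
        t = np.arange(0, 301, 1.0)
        vo2 = np.where(t < 120, 1.0, 5.0)  # step right at the window boundary
        g = GasSeries(t, vo2, np.zeros_like(t))
        assert steady_state_power(g, window=180.0) == pytest.approx(16.58 * 5.0)

    def test_too_short_series_rejected(self):
        t = np.arange(0, 100, 5.0)
        g = GasSeries(t, np.ones_like(t), np.ones_like(t))
        with pytest.raises(ValueError, match="shorter"):
            steady_state_power(g, window=180.0)

    def test_noisy_series_recovers_mean(self, rng):
        t = np.arange(0, 301, 1.0)
        mu_vo2 = 5.0
        vo2 = np.clip(rng.normal(mu_vo2, 0.3, len(t)), 0, None)
        g = GasSeries(t, vo2, np.zeros_like(t))
        mu = 16.58 * mu_vo2
        sem = 16.58 * 0.3 / np.sqrt(181)
        assert abs(steady_state_power(g) - mu) < 3 * sem

    def test_gas_series_validation(self):
        with pytest.raises(ValueError):
            GasSeries(np.array([0.0, 0.0]), np.ones(2), np.ones(2))
        with pytest.raises(ValueError):
            GasSeries(np.array([0.0, 1.0]), np.array([1.0, -1.0]), np.ones(2))


class TestMovingRate:
    def test_always_moving_returns_measured(self):
        b = BlockSummary(T_m=300, T_trial=300, n=100, e_parvo=120, e_rest=70)
        assert moving_rate(b) == pytest.approx(120.0)

    def test_no_surcharge_returns_rest(self):
        b = BlockSummary(T_m=100, T_trial=300, n=100, e_parvo=70, e_rest=70)
        assert moving_rate(b) == pytest.approx(70.0)

    def test_hand_calculation(self):
        b = BlockSummary(T_m=100, T_trial=300, n=200, e_parvo=100, e_rest=70)
        assert moving_rate(b) == pytest.approx(160.0)
        assert cost_per_movement(moving_rate(b), b.T_m, b.n) == pytest.approx(80.0)

    def test_generation_roundtrip(self):
        # composing e_parvo from a known moving rate and inverting is exact
        rate, rest, T_m, T_trial = 143.7, 71.2, 123.4, 310.0
        e_parvo = (rate * T_m + rest * (T_trial - T_m)) / T_trial
        b = BlockSummary(T_m=T_m, T_trial=T_trial, n=150, e_parvo=e_parvo, e_rest=rest)
        assert moving_rate(b) == pytest.approx(rate, abs=1e-9)

    def test_invalid_blocks_rejected(self):
        with pytest.raises(ValueError):
            BlockSummary(T_m=0, T_trial=300, n=10, e_parvo=100, e_rest=70)
        with pytest.raises(ValueError):
            BlockSummary(T_m=400, T_trial=300, n=10, e_parvo=100, e_rest=70)
        with pytest.raises(ValueError):
            cost_per_movement(100.0, 50.0, 0)


class TestRateAndCost:
    def test_b_zero_is_flat_offset(self):
        p = MetabolicParams(a=100, b=0.0, i=1, j=3)
        for t in (0.3, 0.7, 1.5):
            assert rate_model(p, 2.0, t) == pytest.approx(100.0)
        # and the cost grows linearly
        assert movement_cost(p, 2.0, 0.5) == pytest.approx(50.0)

    def test_reported_parameter_evaluation(self):
        assert rate_model(REPORTED, 2.44, 0.66) == pytest.approx(118.5778, abs=1e-3)
        assert movement_cost(REPORTED, 2.44, 0.66) == pytest.approx(78.2614, abs=1e-3)

    def test_power_law_halving(self):
        # the speed-dependent surcharge halves when t is scaled by 2^(1/j)
        t = 0.6
        surcharge = rate_model(REPORTED, 3.0, t) - REPORTED.a
        scaled = rate_model(REPORTED, 3.0, t * 2 ** (1 / REPORTED.j)) - REPORTED.a
        assert scaled == pytest.approx(surcharge / 2, rel=1e-12)

    def test_cost_equals_rate_times_duration(self):
        for t in (0.3, 0.66, 1.2):
            assert movement_cost(REPORTED, 4.9, t) == pytest.approx(
                rate_model(REPORTED, 4.9, t) * t, rel=1e-12
            )

    def test_alternative_model_mass_dependent_offset(self):
        p = MetabolicParams(a=100, b=0.5, i=1, j=3, k=0.5)
        assert rate_model(p, 4.0, 1.0) == pytest.approx(100 * 2.0 + 0.5 * 4.0)

    def test_invalid_duration_rejected(self):
        with pytest.raises(ValueError):
            rate_model(REPORTED, 2.44, 0.0)
        with pytest.raises(ValueError):
            movement_cost(REPORTED, 2.44, -1.0)


class TestOptimalDuration:
    @pytest.mark.parametrize(
        "mass,expected",
        [(2.44, 0.660), (4.834, 0.728), (7.127, 0.769), (11.691, 0.826)],
    )
    def test_reported_optima(self, mass, expected):
        assert optimal_duration(REPORTED, mass) == pytest.approx(expected, abs=2e-3)

    def test_stationarity_condition(self):
        t = optimal_duration(REPORTED, 2.44)
        lhs = REPORTED.a
        rhs = (REPORTED.j - 1) * REPORTED.b * 2.44**REPORTED.i * t**-REPORTED.j
        assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_matches_dense_grid_search(self, rng):
        for _ in range(5):
            p = MetabolicParams(
                a=rng.uniform(50, 150),
                b=rng.uniform(0.2, 3.0),
                i=rng.uniform(0.5, 1.2),
                j=rng.uniform(2.0, 8.0),
            )
            m = rng.uniform(2, 12)
            grid = np.arange(0.1, 3.0, 1e-5)
            oracle = grid[np.argmin(movement_cost(p, m, grid))]
            assert optimal_duration(p, m) == pytest.approx(oracle, abs=1e-5)

    def test_duration_ratio_law(self):
        m1, m2 = 2.506, 6.282
        ratio = optimal_duration(REPORTED, m2) / optimal_duration(REPORTED, m1)
        assert ratio == pytest.approx(
            (m2 / m1) ** (REPORTED.i / REPORTED.j), rel=1e-12
        )

    def test_minimum_cost_identity(self):
        t = optimal_duration(REPORTED, 2.44)
        expected = REPORTED.a * t * REPORTED.j / (REPORTED.j - 1)
        assert minimum_cost(REPORTED, 2.44) == pytest.approx(expected, abs=1e-9)

    def test_convexity_of_cost(self):
        grid = np.linspace(0.15, 2.5, 400)
        c = movement_cost(REPORTED, 5.0, grid)
        assert np.all(np.diff(c, 2) > 0)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        a=st.floats(40, 160),
        b=st.floats(0.2, 3.0),
        i=st.floats(0.4, 1.3),
        j=st.floats(1.5, 8.0),
        m=st.floats(1.5, 13.0),
        m2=st.floats(1.5, 13.0),
    )
    def test_optimum_properties_hold_generally(self, a, b, i, j, m, m2):
        """Stationarity, the mass-ratio law, and the minimum-cost identity
        hold across the parameter space, not just the fitted values."""
        p = MetabolicParams(a=a, b=b, i=i, j=j)
        t = optimal_duration(p, m, bounds=(1e-4, 1e4))
        assert a == pytest.approx((j - 1) * b * m**i * t**-j, rel=1e-9)
        t2 = optimal_duration(p, m2, bounds=(1e-4, 1e4))
        assert t2 / t == pytest.approx((m2 / m) ** (i / j), rel=1e-9)
        assert movement_cost(p, m, t) == pytest.approx(
            a * t * j / (j - 1), rel=1e-9
        )

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="interior"):
            optimal_duration(MetabolicParams(a=100, b=0.0, i=1, j=3), 2.0)
        with pytest.raises(ValueError, match="interior"):
            optimal_duration(MetabolicParams(a=100, b=1.0, i=1, j=0.9), 2.0)


def _design(masses=(2.44, 4.834, 7.127, 11.691), durations=(0.5, 0.7, 0.9, 1.1, 1.3, 1.5)):
    m, t = np.meshgrid(masses, durations)
    return m.ravel(), t.ravel()


class TestFitRateModel:
    def test_noiseless_recovery(self):
        m, t = _design()
        power = rate_model(REPORTED, 1.0, 1.0) * 0 + np.array(
            [rate_model(REPORTED, mi, ti) for mi, ti in zip(m, t)]
        )
        fit = fit_rate_model(m, t, power)
        for name in ("a", "b", "i", "j"):
            assert getattr(fit.params, name) == pytest.approx(
                getattr(REPORTED, name), rel=1e-4
            )
        assert fit.mse == pytest.approx(0.0, abs=1e-8)

    def test_noisy_recovery_across_seeds(self):
        """Condition-mean noise at the reported residual scale: a and j are
        recovered within 10 %, b and i within their reported SE scale."""
        m, t = _design()
        truth = np.array([rate_model(REPORTED, mi, ti) for mi, ti in zip(m, t)])
        ests = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            fit = fit_rate_model(m, t, truth + r.normal(0, 25 / np.sqrt(8), len(m)))
            ests.append([getattr(fit.params, k) for k in "abij"])
        mean = np.asarray(ests).mean(axis=0)
        assert mean[0] == pytest.approx(REPORTED.a, rel=0.10)
        assert mean[3] == pytest.approx(REPORTED.j, rel=0.10)
        assert abs(mean[1] - REPORTED.b) < 0.43   # reported SE scale for b
        assert abs(mean[2] - REPORTED.i) < 0.10   # reported SE scale for i

    def test_alternative_variant_k_near_zero(self, rng):
        m, t = _design()
        power = np.array([rate_model(REPORTED, mi, ti) for mi, ti in zip(m, t)])
        power = power + rng.normal(0, 5.0, len(m))
        fit = fit_rate_model(m, t, power, variant="alternative")
        assert abs(fit.params.k) < 2 * fit.se["k"]

    def test_single_mass_warns(self):
        t = np.array([0.5, 0.7, 0.9, 1.1, 1.3, 1.5, 0.6, 0.8])
        m = np.full_like(t, 3.0)
        power = np.array([rate_model(REPORTED, mi, ti) for mi, ti in zip(m, t)])
        with pytest.warns(UserWarning, match="unidentifiable"):
            fit_rate_model(m, t, power)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            fit_rate_model([2, 3], [0.5, 0.7], [100, 110])


class TestBootstrap:
    def test_deterministic_under_seed(self):
        m, t = _design()
        r = np.random.default_rng(0)
        power = np.array(
            [rate_model(REPORTED, mi, ti) for mi, ti in zip(m, t)]
        ) + r.normal(0, 10, len(m))
        b1 = bootstrap_optimal_durations(m, t, power, [2.44], n_rep=100, seed=42)
        b2 = bootstrap_optimal_durations(m, t, power, [2.44], n_rep=100, seed=42)
        assert np.array_equal(b1.replicates, b2.replicates)

    def test_noiseless_interval_collapses(self):
        m, t = _design()
        power = np.array([rate_model(REPORTED, mi, ti) for mi, ti in zip(m, t)])
        b = bootstrap_optimal_durations(m, t, power, [2.44, 11.691], n_rep=100, seed=1)
        assert np.all(b.ci_high - b.ci_low < 1e-6)
        assert b.mean[0] == pytest.approx(0.660, abs=2e-3)

    def test_minimum_replicate_count_enforced(self):
        m, t = _design()
        power = np.array([rate_model(REPORTED, mi, ti) for mi, ti in zip(m, t)])
        with pytest.raises(ValueError):
            bootstrap_optimal_durations(m, t, power, [2.44], n_rep=10, seed=0)
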