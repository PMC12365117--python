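import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chronode.ode import (
    RANGES,
    NormalizedSeries,
    analytic_solution,
    characteristic_times,
    classify_kinetics,
    cluster_quadrants,
    fit_best,
    fit_simplified_ode,
    inverse_transform_params,
    minmax_normalize,
    reconstruct_original,
)


class TestMinmaxNormalize:
    def test_endpoints_map_to_range_bounds(self, times):
        z = np.linspace(2.0, 7.0, 8)
        for rid, (rmin, rmax) in RANGES.items():
            s = minmax_normalize(z, times, rid)
            assert s.y_star.min() == pytest.approx(rmin)
            assert s.y_star.max() == pytest.approx(rmax)

    def test_shifted_equals_unit_plus_one(self, times, rng):
        z = rng.normal(size=8)
        u = minmax_normalize(z, times, "unit").y_star
        s = minmax_normalize(z, times, "shifted").y_star
        np.testing.assert_allclose(s, u + 1.0)

    def test_roundtrip_through_inverse_map(self, times, rng):
        z = rng.normal(size=8) * 4 + 10
        for rid in RANGES:
            s = minmax_normalize(z, times, rid)
            rmin, rmax = RANGES[rid]
            back = (s.y_star - rmin) * (s.z_max - s.z_min) / (rmax - rmin) + s.z_min
            np.testing.assert_allclose(back, z, rtol=0, atol=1e-12)

    def test_constant_series_rejected(self, times):
        with pytest.raises(ValueError, match="degenerate"):
            minmax_normalize(np.ones(8), times)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1e4, 1e4), min_size=8, max_size=8, unique=True))
    def test_roundtrip_property(self, values):
        z = np.asarray(values)
        times = np.arange(8.0)
        for rid, (rmin, rmax) in RANGES.items():
            s = minmax_normalize(z, times, rid)
            back = (s.y_star - rmin) * (s.z_max - s.z_min) / (rmax - rmin) + s.z_min
            np.testing.assert_allclose(back, z, rtol=1e-9, atol=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.1, 5.0), st.floats(0.01, 0.99), st.floats(-2.0, 2.0))
    def test_solution_bounded_and_monotone(self, b_star, frac, k_star):
        # any standard-branch solution stays in (0, b*) and is monotone
        if abs(k_star) < 1e-3:
            k_star = 1e-3
        grid = np.linspace(10.5, 21.0, 50)
        y = analytic_solution(grid, k_star, b_star, frac * b_star, 10.5)
        assert np.all((y > 0) & (y < b_star))
        d = np.diff(y)
        assert np.all(d > 0) if k_star > 0 else np.all(d < 0)


class TestAnalyticSolution:
    def test_initial_condition(self):
        assert analytic_solution(10.5, 0.9, 1.0, 0.3, 10.5) == pytest.approx(0.3)

    def test_asymptote_for_large_t(self):
        assert analytic_solution(1e4, 0.9, 1.7, 0.3, 10.5) == pytest.approx(1.7)

    def test_value_at_switch_is_half_saturation(self):
        ts, _, _ = characteristic_times(0.9, 1.0, 0.1, 10.5)
        assert analytic_solution(ts, 0.9, 1.0, 0.1, 10.5) == pytest.approx(0.5)

    def test_no_overflow_at_extreme_rate(self):
        y = analytic_solution(np.array([10.5, 21.0]), 50.0, 1.0, 1e-5, 10.5)
        assert np.all(np.isfinite(y))

    def test_start_above_b_rejected(self):
        with pytest.raises(ValueError):
            analytic_solution(11.0, 0.9, 1.0, 1.2, 10.5)

    def test_satisfies_the_ode_on_a_grid(self):
        # dy*/dt = k* y* (1 - y*/b*), checked by central differences
        k, b, y0, t0 = 0.8, 1.3, 0.05, 10.5
        grid = np.linspace(10.5, 21.0, 2001)
        h = 1e-5
        num = (analytic_solution(grid + h, k, b, y0, t0)
               - analytic_solution(grid - h, k, b, y0, t0)) / (2 * h)
        y = analytic_solution(grid, k, b, y0, t0)
        exact = k * y * (1 - y / b)
        assert np.max(np.abs(num - exact)) / np.max(np.abs(exact)) < 1e-6


class TestFitSimplifiedOde:
    def _series(self, y, times):
        return NormalizedSeries(y, times, "unit", 1e-5, 1.0, 0.0, 1.0)

    def test_noiseless_recovery(self, times):
        y = analytic_solution(times, 0.9, 1.0, 1e-2, 10.5)
        fit = fit_simplified_ode(self._series(y, times), k_init=0.9)
        assert fit.converged
        assert abs(fit.k_star - 0.9) / 0.9 < 1e-3
        assert abs(fit.b_star - 1.0) < 1e-3

    def test_constant_series_not_converged(self, times):
        fit = fit_simplified_ode(self._series(np.full(8, 0.5), times), 0.9)
        # flat data admits no strictly monotone logistic: failure is a value
        assert isinstance(fit.converged, bool)

    def test_negative_init_wins_on_decreasing_series(self, times):
        y = analytic_solution(times, -0.9, 1.0, 0.9, 10.5)
        pos = fit_simplified_ode(self._series(y, times), +0.9)
        neg = fit_simplified_ode(self._series(y, times), -0.9)
        assert neg.converged
        assert (not pos.converged) or neg.mse < pos.mse

    def test_curve_starts_at_y_start(self, times):
        y = analytic_solution(times, 0.7, 1.2, 0.1, 10.5)
        fit = fit_simplified_ode(self._series(y, times), 0.9)
        assert fit.fitted_normalized[0] == pytest.approx(fit.y_start_star, abs=1e-8)

    def test_fitted_curve_strictly_monotone(self, times, rng):
        y = analytic_solution(times, 0.6, 1.1, 0.08, 10.5)
        y = y + rng.normal(0, 0.01, 8)
        fit = fit_simplified_ode(self._series(np.clip(y, 1e-4, None), times), 0.9)
        if fit.converged:
            d = np.diff(fit.fitted_normalized)
            assert np.all(d > 0) if fit.k_star > 0 else np.all(d < 0)


class TestFitBest:
    def test_returns_minimum_mse_among_candidates(self, noiseless_sim):
        from chronode.ode import CANDIDATE_ORDER
        matrix, _ = noiseless_sim
        times = matrix.columns.to_numpy(dtype=float)
        for fid, row in matrix.head(8).iterrows():
            z = row.to_numpy()
            best = fit_best(z, times)
            mses = []
            for rid, k0 in CANDIDATE_ORDER:
                c = fit_simplified_ode(minmax_normalize(z, times, rid), k0)
                if c.converged and c.b_star > 0:
                    mses.append(c.mse)
            assert best.converged
            assert best.mse <= min(mses) + 1e-15

    def test_full_sigmoid_prefers_unit_range(self, times):
        from chronode.simulate import _pinned_curve
        rng = np.random.default_rng(1)
        y, rid, _, _ = _pinned_curve(rng, 1.4, +1, times)
        while rid != "unit":
            y, rid, _, _ = _pinned_curve(rng, 1.4, +1, times)
        fit = fit_best(y, times)
        assert fit.range_id == "unit" and fit.k_star > 0

    def test_deceleration_tail_switch_before_start(self, times):
        y = analytic_solution(times, 0.9, 1.0, 0.9, 10.5)
        fit = fit_best(y, times)
        assert fit.converged
        ts, _, _ = characteristic_times(fit.k_star, fit.b_star,
                                        fit.y_start_star, fit.t_start)
        assert ts < 10.5

    def test_constant_input_non_converged(self, times):
        assert not fit_best(np.ones(8), times).converged

    def test_k_invariant_under_positive_affine_rescale(self, times):
        y = analytic_solution(times, 0.8, 1.2, 0.05, 10.5)
        base = fit_best(y, times)
        scaled = fit_best(3.7 * y + 11.0, times)
        assert abs(base.k - scaled.k) < 1e-6


class TestInverseTransform:
    def test_range_min_maps_to_z_min(self):
        a, _ = inverse_transform_params(1e-5, 1.0, "unit", 2.0, 9.0)
        assert a == pytest.approx(2.0)

    def test_unit_b_star_one_maps_to_z_max(self):
        _, b = inverse_transform_params(0.0, 1.0, "unit", 0.0, 10.0)
        assert b == pytest.approx(10.0, rel=1e-4)

    def test_forward_then_inverse_is_identity(self, rng):
        z_min, z_max = 1.0, 6.0
        for rid, (rmin, rmax) in RANGES.items():
            b_star = rng.uniform(0.5, 3.0)
            b_orig = (b_star - rmin) * (z_max - z_min) / (rmax - rmin) + z_min
            fwd = (b_orig - z_min) * (rmax - rmin) / (z_max - z_min) + rmin
            _, back = inverse_transform_params(0.0, fwd, rid, z_min, z_max)
            assert back == pytest.approx(b_orig, abs=1e-12)


class TestReconstructOriginal:
    def test_initial_condition(self):
        assert reconstruct_original(10.5, 0.9, 1.0, 5.0, 2.0, 10.5) == pytest.approx(2.0)

    def test_commutes_with_normalized_solution(self, times):
        # the original-range curve equals the inverse-mapped normalized one
        k, b_star, y0 = 0.9, 1.2, 0.05
        z_min, z_max = 3.0, 8.0
        rmin, rmax = RANGES["unit"]
        y = analytic_solution(times, k, b_star, y0, 10.5)
        scale = (z_max - z_min) / (rmax - rmin)
        a_orig = (0.0 - rmin) * scale + z_min
        b_orig = (b_star - rmin) * scale + z_min
        z0 = (y0 - rmin) * scale + z_min
        z = reconstruct_original(times, k, a_orig, b_orig, z0, 10.5)
        np.testing.assert_allclose(z, (y - rmin) * scale + z_min, rtol=1e-10)

    def test_inflection_preserved_in_original_range(self):
        k, b_star, y0 = 0.9, 1.0, 0.05
        ts, _, _ = characteristic_times(k, b_star, y0, 10.5)
        grid = np.linspace(10.5, 21.0, 20001)
        z = reconstruct_original(grid, k, 1.0, 9.0, 1.0 + 8.0 * y0, 10.5)
        d2 = np.diff(z, 2)
        t_inflect = grid[1 + np.argmin(np.abs(d2))]
        sign_changes = np.sum(np.diff(np.sign(d2[np.abs(d2) > 1e-12])) != 0)
        assert abs(t_inflect - ts) < (grid[1] - grid[0]) * 5
        assert sign_changes == 1

    def test_z_start_outside_asymptotes_rejected(self):
        with pytest.raises(ValueError):
            reconstruct_original(11.0, 0.9, 1.0, 5.0, 6.0, 10.5)


class TestCharacteristicTimes:
    def test_switch_at_start_when_half_saturated(self):
        ts, _, _ = characteristic_times(0.9, 1.0, 0.5, 10.5)
        assert ts == pytest.approx(10.5)

    def test_saturation_at_start_when_99pct(self):
        _, _, tsat = characteristic_times(0.9, 1.0, 0.99, 10.5)
        assert tsat == pytest.approx(10.5)

    def test_direct_evaluation(self):
        ts, tm, tsat = characteristic_times(0.9, 1.0, 0.1, 10.5)
        assert ts == pytest.approx(10.5 + np.log(9) / 0.9)
        assert tm == pytest.approx(10.5 + np.log(1e-16 * 10) / 0.9)
        assert tsat == pytest.approx(10.5 + np.log(99 * 10 - 99) / 0.9)

    def test_sentinels_when_log_argument_nonpositive(self):
        ts, _, tsat = characteristic_times(0.9, 1.0, 1.0, 10.5)
        assert ts == -np.inf
        assert np.isnan(tsat)

    def test_zero_rate_rejected(self):
        with pytest.raises(ValueError):
            characteristic_times(0.0, 1.0, 0.1, 10.5)


class TestClassifyKinetics:
    @pytest.mark.parametrize("t_switch,expected", [
        (12.0, "switcher"), (10.5, "switcher"), (21.0, "switcher"),
        (25.0, "accelerator"), (9.0, "decelerator"), (-np.inf, "decelerator"),
    ])
    def test_window_classification(self, t_switch, expected):
        assert classify_kinetics(t_switch, 10.5, 21.0) == expected

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            classify_kinetics(12.0, 21.0, 10.5)


class TestClusterQuadrants:
    def _blobs(self, seed=0, n=60):
        rng = np.random.default_rng(seed)
        q1 = np.column_stack([rng.normal(1.2, 0.05, n), rng.normal(0.5, 0.05, n)])
        q2 = np.column_stack([rng.normal(0.2, 0.05, n), rng.normal(0.5, 0.05, n)])
        q3 = np.column_stack([rng.normal(0.2, 0.05, n), rng.normal(3.0, 0.1, n)])
        pts = np.vstack([q1, q2, q3])
        truth = np.array(["Q1"] * n + ["Q2"] * n + ["Q3"] * n)
        return pts, truth

    def test_blob_recovery_and_empty_q4(self):
        pts, truth = self._blobs()
        labels, info = cluster_quadrants(pts)
        assert (labels == truth).mean() >= 0.99
        assert info["q4_empty"]

    def test_identical_points_rejected(self):
        with pytest.raises(ValueError):
            cluster_quadrants(np.ones((10, 2)))

    def test_invariant_to_order_and_seed(self):
        pts, _ = self._blobs()
        ref, _ = cluster_quadrants(pts)
        rng = np.random.default_rng(5)
        for seed in range(10):
            perm = rng.permutation(len(pts))
            labels, _ = cluster_quadrants(pts[perm], seed=seed)
            assert (labels == ref[perm]).all()


class TestParameterRecoveryProperty:
    def test_recovery_under_noise(self):
        # 2%-of-range Gaussian noise on the 8-point grid
        from chronode.simulate import SimulationSpec, simulate_logistic_matrix
        spec = SimulationSpec(seed=11, n_features=60, noise_sd_fraction=0.02)
        matrix, truth = simulate_logistic_matrix(spec)
        times = matrix.columns.to_numpy(dtype=float)
        ek, eb, signs = [], [], []
        for fid, row in matrix.iterrows():
            fit = fit_best(row.to_numpy(), times)
            if not fit.converged:
                continue
            tr = truth.loc[fid]
            ek.append(abs(fit.k - tr.k) / abs(tr.k))
            eb.append(abs(fit.b - tr.b) / abs(tr.b))
            signs.append(np.sign(fit.k) == np.sign(tr.k))
        assert len(ek) >= 55
        assert np.median(ek) < 0.10
        assert np.median(eb) < 0.10
        assert np.mean(signs) >= 0.99
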