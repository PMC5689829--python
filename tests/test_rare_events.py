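"""Spatial filter, resampling, and tail estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import sparkfiber.rare_events as re_
import sparkfiber.synth as sy


def _flux(values, buffer_cells=2, dt=5.0):
    values = np.asarray(values, dtype=float)
    interior = np.zeros(values.shape[0], dtype=bool)
    interior[buffer_cells:values.shape[0] - buffer_cells] = True
    return re_.FluxMatrix(values=values, dt=dt, interior=interior)


def _brute_force_filter(values, w):
    """Naive triple loop over (x, t, k) of the moving-average definition."""
    n, m = values.shape
    half = (w - 1) // 2
    out = np.full((n, m), np.nan)
    for x in range(half, n - half):
        for t in range(m):
            acc = 0.0
            for k in range(-half, half + 1):
                acc += values[x + k, t]
            out[x, t] = acc / w
    return out


class TestSpatialFilter:
    def test_width_one_is_identity(self, rng):
        j = _flux(rng.uniform(0, 1, (9, 4)))
        assert np.array_equal(re_.spatial_filter(j, 1), j.values)

    def test_constant_field_unchanged(self):
        j = _flux(np.full((11, 5), 3.7))
        out = re_.spatial_filter(j, 5)
        valid = ~np.isnan(out)
        assert np.allclose(out[valid], 3.7)

    def test_matches_naive_loop_on_random_matrix(self, rng):
        values = rng.uniform(0, 2, (9, 4))
        j = _flux(values, buffer_cells=1)
        out = re_.spatial_filter(j, 3)
        expected = _brute_force_filter(values, 3)
        assert np.allclose(out, expected, equal_nan=True)

    @given(w=st.sampled_from([1, 3, 5, 7]),
           values=arrays(np.float64, (12, 6),
                         elements=st.floats(0, 10, allow_nan=False)))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_property_matches_loop_and_is_linear(self, w, values):
        j = _flux(values, buffer_cells=3)
        out = re_.spatial_filter(j, w)
        assert np.allclose(out, _brute_force_filter(values, w),
                           equal_nan=True)
        doubled = re_.spatial_filter(_flux(2 * values, buffer_cells=3), w)
        assert np.allclose(doubled, 2 * out, equal_nan=True)

    def test_even_or_out_of_range_w_rejected(self, rng):
        j = _flux(rng.uniform(0, 1, (9, 4)))
        for bad in (2, 0, -3, 11):
            with pytest.raises(ValueError):
                re_.spatial_filter(j, bad)


class TestJfMax:
    def test_single_time_point_returns_column(self, rng):
        m = rng.uniform(0, 1, (6, 1))
        assert np.array_equal(re_.jf_max(m), m[:, 0])

    def test_constant_rows_return_constant(self):
        m = np.tile(np.arange(5.0)[:, None], (1, 8))
        assert np.array_equal(re_.jf_max(m), np.arange(5.0))

    def test_matches_loop_with_earliest_tie(self, rng):
        m = rng.integers(0, 3, (10, 7)).astype(float)
        vals, tidx = re_.jf_max(m, return_times=True)
        for i in range(10):
            best, bt = -np.inf, -1
            for t in range(7):
                if m[i, t] > best:
                    best, bt = m[i, t], t
            assert vals[i] == best and tidx[i] == bt


class TestFitAndPredict:
    def test_recovers_true_w_with_unit_r2(self):
        params = sy.SyntheticProfileParams(n_cells=80, boundary_buffer=10,
                                           seed=7)
        j = sy.generate_profiles(params)
        v = sy.analytic_vmax_surrogate(j, true_w=7, gain=40.0, offset=-77.0)
        model = re_.fit_filter_model(j, np.nan_to_num(v, nan=-77.0),
                                     w_candidates=range(1, 16, 2),
                                     min_interior=40)
        assert model.w == 7
        assert model.r2 == pytest.approx(1.0, abs=1e-12)

    def test_decorrelated_vmax_gives_low_r2(self, rng):
        params = sy.SyntheticProfileParams(n_cells=80, boundary_buffer=10,
                                           seed=8)
        j = sy.generate_profiles(params)
        v = rng.normal(-77, 1, j.n_cells)
        model = re_.fit_filter_model(j, v, w_candidates=range(1, 16, 2),
                                     min_interior=40)
        assert model.r2 < 0.3

    def test_degenerate_fit_rejected(self):
        params = sy.SyntheticProfileParams(n_cells=80, boundary_buffer=10,
                                           seed=9)
        j = sy.generate_profiles(params)
        with pytest.raises(ValueError, match="degenerate"):
            re_.fit_filter_model(j, np.full(j.n_cells, -77.0),
                                 min_interior=40)

    def test_prediction_is_affine_and_order_preserving(self, rng):
        model = re_.FilterModel(w=3, mu_v=-77.0, sigma_v=0.7, mu_j=0.5,
                                sigma_j=0.01, r2=0.95)
        j = _flux(rng.uniform(0, 1, (30, 10)), buffer_cells=3)
        vf = re_.predict_vmax(j, model)
        jm = re_.jf_max(re_.spatial_filter(j, 3))
        ok = ~np.isnan(vf)
        # scalar oracle of the affine map
        assert np.allclose(
            vf[ok], -77.0 + (0.7 / 0.01) * (jm[ok] - 0.5))
        # ranking preserved
        assert np.array_equal(np.argsort(vf[ok]), np.argsort(jm[ok]))

    def test_mean_flux_maps_to_mean_v(self):
        model = re_.REFERENCE_FILTER_FITS["baseline"]
        j = _flux(np.full((90, 4), model.mu_j), buffer_cells=22)
        vf = re_.predict_vmax(j, model)
        assert np.allclose(vf[~np.isnan(vf)], -77.0)

    def test_unit_zscore_maps_to_one_sigma(self):
        m = re_.FilterModel(w=1, mu_v=-77.0, sigma_v=0.7, mu_j=0.5,
                            sigma_j=0.01, r2=1.0)
        j = _flux(np.full((5, 2), m.mu_j + m.sigma_j), buffer_cells=1)
        vf = re_.predict_vmax(j, m)
        assert np.allclose(vf, m.mu_v + m.sigma_v)


class TestSV:
    @pytest.mark.parametrize("key,expected", [
        ("baseline", 1.77), ("ik1_50", 2.27), ("ik1_50_ggap_50", 3.31)])
    def test_reference_conditions(self, key, expected):
        assert re_.s_v(re_.REFERENCE_FILTER_FITS[key]) == pytest.approx(
            expected, abs=0.005)

    def test_unit_case(self):
        m = re_.FilterModel(w=1, mu_v=0.0, sigma_v=1.0, mu_j=0.0,
                            sigma_j=1.0, r2=1.0)
        assert re_.s_v(m) == 1.0

    def test_smaller_w_gives_wider_predicted_distribution(self, rng):
        """Mechanism: S_V ~ SD of V^f_max rises as the window shrinks."""
        params = sy.SyntheticProfileParams(n_cells=120, boundary_buffer=20,
                                           seed=11)
        j = sy.generate_profiles(params)
        sds = []
        for w in (3, 9, 21):
            jm = re_.jf_max(re_.spatial_filter(j, w))
            sds.append(np.nanstd(jm[j.interior]) / 1.0)
        assert sds[0] > sds[1] > sds[2]


class TestShuffle:
    def test_interior_rows_preserved_as_multiset(self, rng):
        j = _flux(rng.uniform(0, 1, (20, 6)), buffer_cells=4)
        out = re_.shuffle_realization(j, rng, mode="permute")
        a = np.sort(j.values[j.interior].ravel())
        b = np.sort(out.values[out.interior].ravel())
        assert np.allclose(a, b)
        # boundary untouched
        assert np.array_equal(out.values[~j.interior],
                              j.values[~j.interior])

    def test_column_sums_invariant_under_permutation(self, rng):
        j = _flux(rng.uniform(0, 1, (20, 6)), buffer_cells=4)
        out = re_.shuffle_realization(j, rng, mode="permute")
        assert np.allclose(out.values[j.interior].sum(axis=0),
                           j.values[j.interior].sum(axis=0))

    def test_empty_pool_rejected(self, rng):
        j = _flux(np.ones((20, 3)), buffer_cells=4)
        with pytest.raises(ValueError):
            re_.shuffle_realization(j, rng, mode="replace",
                                    pool=np.empty((0, 3)))


class TestTail:
    def _setup(self, seed=21):
        params = sy.SyntheticProfileParams(n_cells=60, boundary_buffer=10,
                                           seed=seed)
        j = sy.generate_profiles(params)
        v = sy.analytic_vmax_surrogate(j, true_w=5, gain=30.0, offset=-77.0,
                                       noise_sd=0.05)
        model = re_.fit_filter_model(j, np.nan_to_num(v, nan=-77.0),
                                     w_candidates=range(1, 12, 2),
                                     min_interior=30)
        return j, model

    def test_probabilities_monotone_and_bounded(self):
        j, model = self._setup()
        tail = re_.estimate_tail(j, model, 300, np.arange(0, 4, 0.5), seed=1)
        assert np.all(np.diff(tail.probabilities) <= 0)
        assert np.all((tail.probabilities >= 0)
                      & (tail.probabilities <= 1))

    def test_low_threshold_probability_one(self):
        j, model = self._setup()
        tail = re_.estimate_tail(j, model, 100, [-1000.0], seed=2)
        assert tail.probabilities[0] == 1.0

    def test_se_decreases_with_more_realizations(self):
        j, model = self._setup()
        ths = np.arange(0.0, 2.0, 0.1)
        t_small = re_.estimate_tail(j, model, 100, ths, seed=3)
        t_big = re_.estimate_tail(j, model, 900, ths, seed=3)
        both = ((t_small.probabilities > 0) & (t_small.probabilities < 1)
                & (t_big.probabilities > 0) & (t_big.probabilities < 1))
        assert both.any()
        assert np.all(t_big.standard_errors[both]
                      < t_small.standard_errors[both])

    def test_matches_direct_monte_carlo_of_maxima(self):
        """Filter+shuffle tail vs direct simulation of i.i.d.-cell maxima.

        The oracle draws brand-new independent fibers (no shuffling) and
        computes the empirical exceedance directly; the shuffle-based
        estimate must agree within binomial 95% bands.
        """
        params = sy.SyntheticProfileParams(n_cells=60, boundary_buffer=10,
                                           seed=31)
        pool_j = sy.generate_profiles(params)
        v = sy.analytic_vmax_surrogate(pool_j, true_w=5, gain=30.0,
                                       offset=-77.0)
        model = re_.fit_filter_model(pool_j, np.nan_to_num(v, nan=-77.0),
                                     w_candidates=range(1, 12, 2),
                                     min_interior=30)
        thresholds = np.array([0.3, 0.6, 0.9])
        n = 2000
        # direct oracle: fresh independent fibers, explicit maxima
        rng = np.random.default_rng(77)
        direct = np.zeros(n)
        for i in range(n):
            p_i = sy.SyntheticProfileParams(n_cells=60, boundary_buffer=10,
                                            seed=int(rng.integers(2**31)))
            j_i = sy.generate_profiles(p_i)
            vf = re_.predict_vmax(j_i, model)
            direct[i] = np.nanmax(vf[j_i.interior]) - model.mu_v
        p_direct = np.array([(direct > th).mean() for th in thresholds])
        tail = re_.estimate_tail(pool_j, model, n, thresholds, seed=5,
                                 mode="replace")
        for pd_, ps, se in zip(p_direct, tail.probabilities,
                               tail.standard_errors):
            band = 1.96 * np.sqrt(se ** 2 + pd_ * (1 - pd_) / n) + 0.02
            assert abs(pd_ - ps) <= band


class TestWaitingTime:
    def test_certain_event_at_1hz(self):
        assert re_.expected_waiting_time(1.0, 1.0) == pytest.approx(
            1.157e-5, rel=1e-3)

    def test_rare_event_waiting_time(self):
        days = re_.expected_waiting_time(1e-6, 1.0)
        assert days == pytest.approx(11.574, rel=1e-3)

    def test_rate_scaling_and_zero_probability(self):
        assert re_.expected_waiting_time(0.01, 2.0) == pytest.approx(
            re_.expected_waiting_time(0.01, 1.0) / 2.0)
        assert np.isinf(re_.expected_waiting_time(0.0, 1.0))


class TestValidateMethod:
    def _fibers(self, n_fibers, seed0, coupling=0.0):
        fluxes, vmaxes = [], []
        for k in range(n_fibers):
            params = sy.SyntheticProfileParams(
                n_cells=70, boundary_buffer=10, seed=seed0 + k,
                coupling=coupling)
            j = sy.generate_profiles(params)
            v = sy.analytic_vmax_surrogate(j, true_w=5, gain=30.0,
                                           offset=-77.0, noise_sd=0.05,
                                           rng=np.random.default_rng(seed0 + k))
            vmaxes.append(np.nan_to_num(v, nan=-77.0))
            fluxes.append(j)
        return fluxes, vmaxes

    def test_synthetic_iid_fibers_small_bias(self):
        fluxes, vmaxes = self._fibers(10, 100)
        out = re_.validate_method(fluxes, vmaxes,
                                  w_candidates=range(1, 12, 2),
                                  n_shuffle=40, seed=0, min_interior=30)
        assert abs(out["bias_shuffle"]) < 0.2
        assert out["p_shuffle"] > 0.05

    def test_subset_pool_degrades_gracefully(self):
        fluxes, vmaxes = self._fibers(8, 200)
        out = re_.validate_method(fluxes, vmaxes,
                                  w_candidates=range(1, 12, 2),
                                  n_shuffle=20, seed=1, min_interior=30,
                                  subset_size=3)
        assert "bias_subset" in out and np.isfinite(out["bias_subset"])

    def test_too_few_fibers_rejected(self):
        fluxes, vmaxes = self._fibers(1, 300)
        with pytest.raises(ValueError):
            re_.validate_method(fluxes, vmaxes)
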