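import numpy as np
import pytest

import firmap as fm
from firmap.fitting import fit_coil_scale_batch


def curve_of(m0, m0s, t1s, t_ms):
    return m0s - (m0 + m0s) * np.exp(-t_ms / t1s)


class TestThreeParamFit:
    @pytest.mark.parametrize("t1s", [100.0, 600.0, 1000.0, 4000.0])
    def test_noiseless_round_trip(self, t1s, times999):
        m0, m0s = 1.0, 0.8
        fit = fm.fit_three_param(curve_of(m0, m0s, t1s, times999.t_ms), times999)
        assert fit.converged
        assert fit.m0 == pytest.approx(m0, rel=1e-6)
        assert fit.m0_star == pytest.approx(m0s, rel=1e-6)
        assert fit.t1_star_ms == pytest.approx(t1s, rel=1e-6)

    def test_round_trip_across_t1_star_range(self, times999):
        rng = np.random.default_rng(42)
        t1sv = rng.uniform(100.0, 4000.0, 64)
        m0v = rng.uniform(0.5, 1.5, 64)
        m0sv = rng.uniform(0.2, 1.0, 64)
        curves = curve_of(m0v[:, None], m0sv[:, None], t1sv[:, None], times999.t_ms[None])
        params, conv = fm.fit_three_param_batch(curves, times999)
        assert conv.all()
        truth = np.stack([m0v, m0sv, t1sv], axis=1)
        np.testing.assert_allclose(params, truth, rtol=1e-6)

    def test_fitted_null_point_matches_closed_form(self, times999):
        # with M0 = M0* = 1 and T1* = 1000 the curve vanishes at 1000 ln 2
        curve = curve_of(1.0, 1.0, 1000.0, times999.t_ms)
        fit = fm.fit_three_param(curve, times999)
        t_null = fit.t1_star_ms * np.log((fit.m0 + fit.m0_star) / fit.m0_star)
        assert t_null == pytest.approx(693.1471805599452, rel=1e-6)
        model_at_null = curve_of(fit.m0, fit.m0_star, fit.t1_star_ms, np.array([t_null]))
        assert abs(model_at_null[0]) < 1e-9

    def test_all_zero_curve_flagged(self, times999):
        fit = fm.fit_three_param(np.zeros(999), times999)
        assert not fit.converged
        assert fit.m0 == 0.0 and fit.m0_star == 0.0

    def test_warm_start_from_truth_is_stable(self, times999):
        m0, m0s, t1s = 1.2, 0.7, 800.0
        curve = curve_of(m0, m0s, t1s, times999.t_ms)
        fit = fm.fit_three_param(curve, times999, init=(m0, m0s, t1s))
        assert fit.converged
        assert fit.t1_star_ms == pytest.approx(t1s, rel=1e-9)

    def test_noisy_fit_matches_scipy_least_squares(self, times999):
        # independent oracle: scipy's generic trust-region least squares
        from scipy.optimize import least_squares

        rng = np.random.default_rng(7)
        t = times999.t_ms
        truth = (1.0, 0.6, 900.0)
        data = curve_of(*truth, t) + rng.normal(scale=0.01, size=t.size)
        params, conv = fm.fit_three_param_batch(data[None], times999)
        ref = least_squares(
            lambda p: p[1] - (p[0] + p[1]) * np.exp(-t / p[2]) - data,
            x0=[-data.min(), data.max(), 1000.0],
            method="lm",
        )
        np.testing.assert_allclose(params[0], ref.x, rtol=1e-6)

    def test_too_few_time_points_rejected(self):
        with pytest.raises(ValueError):
            fm.fit_three_param(np.array([1.0, 2.0]), fm.InversionTimeAxis(np.array([1.0, 2.0])))


class TestComputeT1:
    def test_arithmetic(self):
        t1, k = fm.compute_t1(1.4, 1.0, 1000.0)
        assert t1 == pytest.approx(1400.0)
        assert k == pytest.approx(1.4)

    def test_equal_amplitudes_give_t1_star(self):
        t1, k = fm.compute_t1(0.5, 0.5, 820.0)
        assert t1 == pytest.approx(820.0)
        assert k == pytest.approx(1.0)

    def test_scale_invariance(self):
        t1a, _ = fm.compute_t1(1.4, 1.0, 1000.0)
        t1b, _ = fm.compute_t1(140.0, 100.0, 1000.0)
        assert t1a == pytest.approx(t1b, rel=1e-12)

    def test_zero_steady_state_masked(self):
        t1, k = fm.compute_t1(np.array([1.0]), np.array([0.0]), np.array([1000.0]))
        assert np.isnan(t1[0]) and np.isnan(k[0])


class TestCoilScaleFit:
    def basis(self, k, t1s, t):
        return 1.0 - (k + 1.0) * np.exp(-t / t1s)

    def test_exact_representation_real(self, times999):
        k, t1s = 1.4, 700.0
        b = self.basis(k, t1s, times999.t_ms)
        scale = fm.fit_coil_scale(2.0 * b, k, t1s, times999)
        assert scale == pytest.approx(2.0 + 0.0j, rel=1e-12)

    def test_exact_representation_complex(self, times999):
        k, t1s = 0.9, 1200.0
        b = self.basis(k, t1s, times999.t_ms)
        scale = fm.fit_coil_scale((1 + 1j) * b, k, t1s, times999)
        assert scale == pytest.approx(1 + 1j, rel=1e-12)

    def test_matches_normal_equation_oracle_on_noisy_curves(self, times999):
        rng = np.random.default_rng(17)
        t = times999.t_ms
        n_curves = 100
        k = rng.uniform(0.8, 2.0, n_curves)
        t1s = rng.uniform(200.0, 2000.0, n_curves)
        data = np.empty((t.size, 1, n_curves), dtype=complex)
        expected = np.empty(n_curves, dtype=complex)
        for i in range(n_curves):
            b = self.basis(k[i], t1s[i], t)
            d = (0.5 + 0.2j) * b + rng.normal(scale=0.05, size=t.size) * (1 + 1j)
            data[:, 0, i] = d
            # independent oracle: per-part explicit normal equation
            expected[i] = (
                np.dot(d.real, b) / np.dot(b, b) + 1j * np.dot(d.imag, b) / np.dot(b, b)
            )
        scales, valid = fit_coil_scale_batch(data, k, t1s, times999)
        assert valid.all()
        np.testing.assert_allclose(scales[0], expected, rtol=1e-10, atol=1e-14)

    def test_zero_energy_basis_invalid(self, times999):
        scales, valid = fit_coil_scale_batch(
            np.ones((999, 1, 1), dtype=complex),
            np.array([np.nan]),
            np.array([np.nan]),
            times999,
        )
        assert not valid[0]
        assert scales[0, 0] == 0


class TestRebuildModel:
    def test_late_time_equals_coil_scales(self):
        times = fm.InversionTimeAxis(np.array([1e9]))
        scales = np.array([[[2 + 1j]], [[0.5 - 0.25j]]])  # (2, 1, 1)
        model = fm.rebuild_model(scales, np.array([[1.4]]), np.array([[700.0]]), times)
        np.testing.assert_allclose(model.images[0, :, 0, 0], scales[:, 0, 0], rtol=1e-12)

    def test_time_zero_is_minus_k_times_scale(self):
        times = fm.InversionTimeAxis(np.array([1e-12]))
        scales = np.array([[[2.0 + 0j]]])
        k = np.array([[1.4]])
        model = fm.rebuild_model(scales, k, np.array([[700.0]]), times)
        np.testing.assert_allclose(model.images[0, 0, 0, 0], -1.4 * 2.0, rtol=1e-9)

    def test_unfitted_pixels_are_zero(self):
        times = fm.InversionTimeAxis(np.array([10.0, 20.0]))
        scales = np.ones((1, 2, 2), dtype=complex)
        k = np.array([[1.0, np.nan], [1.0, 1.0]])
        t1s = np.array([[700.0, 700.0], [np.nan, 700.0]])
        model = fm.rebuild_model(scales, k, t1s, times)
        assert np.all(model.images[:, :, 0, 1] == 0)
        assert np.all(model.images[:, :, 1, 0] == 0)
        assert np.all(model.images[:, :, 1, 1] != 0)

    def test_round_trip_through_generator(self, times999):
        # fit a noiseless simulated pixel, rebuild, compare to the original
        m0, m0s, t1s = 1.1, 0.7, 600.0
        sens = np.array([0.8 * np.exp(0.3j), 0.6 * np.exp(-0.5j)])
        curve = curve_of(m0, m0s, t1s, times999.t_ms)
        fitp = fm.fit_three_param(curve, times999)
        t1, k = fm.compute_t1(fitp.m0, fitp.m0_star, fitp.t1_star_ms)
        coil_data = np.einsum("c,t->tc", sens, curve)[:, :, None]
        scales, valid = fit_coil_scale_batch(
            coil_data, np.array([k]), np.array([fitp.t1_star_ms]), times999
        )
        assert valid[0]
        model = fm.rebuild_model(
            scales.reshape(2, 1, 1),
            np.array([[k]]),
            np.array([[fitp.t1_star_ms]]),
            times999,
        )
        np.testing.assert_allclose(
            model.images[:, :, 0, 0], np.einsum("c,t->tc", sens, curve), rtol=1e-6, atol=1e-9
        )
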