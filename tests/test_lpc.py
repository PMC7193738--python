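"""Predictive-model mathematics: autocorrelation, Yule-Walker,
Levinson-Durbin, poles, dominant frequency, AR spectra, streaming."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.signal import lfilter

from lpcsep.lpc import (
    AutocorrSet,
    LpcModel,
    StreamingLpc,
    ar_psd,
    autocorr,
    dominant_frequency,
    fit_lpc,
    levinson_durbin,
    poles_of_order2,
    separation_feature,
    yule_walker,
)
from lpcsep.preprocess import preprocess_session
from lpcsep.synthlfp import ar2_coefficients

FS = 1000.0


def _ar_series(denom_coeffs, n, seed, burn=2000):
    rng = np.random.default_rng(seed)
    e = rng.standard_normal(n + burn)
    return lfilter([1.0], denom_coeffs, e)[burn:]


class TestAutocorr:
    def test_hand_worked_example(self):
        ac = autocorr([1.0, 2.0, 3.0], maxlag=2)
        np.testing.assert_allclose(ac.lags, [14 / 3, 8 / 3, 1.0])
        assert ac.L == 3
        assert ac.estimator == "biased"

    def test_white_noise_lag1_vanishes(self, rng):
        x = rng.standard_normal(100_000)
        ac = autocorr(x, 1)
        assert abs(ac.lags[1] / ac.lags[0]) < 3 / np.sqrt(len(x))

    def test_sinusoid_autocorrelation_is_cosine(self):
        f0 = 25.0
        t = np.arange(int(20 * FS)) / FS
        x = np.sin(2 * np.pi * f0 * t)
        ac = autocorr(x, 40)
        expected = ac.lags[0] * np.cos(2 * np.pi * f0 * np.arange(41) / FS)
        np.testing.assert_allclose(ac.lags, expected, atol=5e-3 * ac.lags[0])

    def test_maxlag_must_be_below_length(self):
        with pytest.raises(ValueError, match="maxlag"):
            autocorr([1.0, 2.0], 2)

    @given(
        st.lists(
            st.floats(min_value=-100, max_value=100, allow_nan=False),
            min_size=3,
            max_size=60,
        ).filter(lambda v: any(abs(x) > 1e-9 for x in v))
    )
    def test_biased_estimator_bounded_by_lag_zero(self, values):
        ac = autocorr(values, min(5, len(values) - 1))
        assert ac.r0 > 0
        assert np.all(np.abs(ac.lags) <= ac.r0 * (1 + 1e-12))


class TestYuleWalker:
    def test_order1_closed_form(self):
        ac = AutocorrSet(lags=[14 / 3, 8 / 3], L=3)
        np.testing.assert_allclose(yule_walker(ac, 1), [4 / 7])

    def test_order2_matrix_inversion_oracle(self):
        ac = AutocorrSet(lags=[14 / 3, 8 / 3, 1.0], L=3)
        # independent oracle: explicit 2x2 inversion
        big_r = np.array([[14 / 3, 8 / 3], [8 / 3, 14 / 3]])
        expected = np.linalg.solve(big_r, [8 / 3, 1.0])
        np.testing.assert_allclose(yule_walker(ac, 2), expected)
        np.testing.assert_allclose(expected, [2 / 3, -1 / 6])

    def test_white_noise_gives_zero_coefficients(self):
        ac = AutocorrSet(lags=[1.0, 0.0, 0.0, 0.0], L=1000)
        np.testing.assert_allclose(yule_walker(ac, 3), 0.0, atol=1e-15)

    def test_singular_system_rejected_with_conditioning_message(self):
        # expectation-level autocorrelation of a constant series: all lags
        # equal, so the Toeplitz matrix is exactly singular
        ac = AutocorrSet(lags=[9.0, 9.0, 9.0], L=100)
        with pytest.raises(np.linalg.LinAlgError, match="condition"):
            yule_walker(ac, 2)

    def test_sample_constant_series_near_unit_coefficient(self):
        # the biased time-average tapers r(l) by (1 - l/L), so the sample
        # system of a constant series is well posed with a1 near 1
        ac = autocorr(np.full(100, 3.0), 1)
        assert yule_walker(ac, 1)[0] == pytest.approx(0.99)

    def test_zero_series_rejected(self):
        ac = AutocorrSet(lags=[0.0, 0.0], L=10)
        with pytest.raises(ValueError, match="zero"):
            yule_walker(ac, 1)


class TestLevinsonDurbin:
    def test_matches_direct_solve_on_worked_example(self):
        ac = AutocorrSet(lags=[14 / 3, 8 / 3, 1.0], L=3)
        coeffs, residuals = levinson_durbin(ac, 2)
        np.testing.assert_allclose(coeffs[1], [2 / 3, -1 / 6], rtol=1e-12)
        np.testing.assert_allclose(coeffs[0], [4 / 7], rtol=1e-12)
        assert np.all(np.diff(residuals) <= 1e-12)

    def test_first_step_closed_form(self):
        ac = AutocorrSet(lags=[2.0, 0.8], L=100)
        coeffs, residuals = levinson_durbin(ac, 1)
        a1 = 0.8 / 2.0
        np.testing.assert_allclose(coeffs[0], [a1])
        assert residuals[0] == pytest.approx(2.0 * (1 - a1**2))

    def test_white_noise_all_reflections_zero(self):
        ac = AutocorrSet(lags=[3.0, 0.0, 0.0, 0.0, 0.0], L=1000)
        coeffs, residuals = levinson_durbin(ac, 4)
        np.testing.assert_allclose(coeffs[-1], 0.0, atol=1e-15)
        np.testing.assert_allclose(residuals, 3.0)

    def test_invalid_autocorrelation_rejected(self):
        ac = AutocorrSet(lags=[1.0, 1.5], L=10)  # |r(1)| > r(0)
        with pytest.raises(np.linalg.LinAlgError, match="reflection"):
            levinson_durbin(ac, 1)

    @given(st.integers(0, 2**31 - 1), st.integers(1, 8))
    def test_equals_direct_toeplitz_solve(self, seed, order):
        x = np.random.default_rng(seed).standard_normal(64)
        ac = autocorr(x, order)
        a_ld = levinson_durbin(ac, order)[0][-1]
        a_direct = yule_walker(ac, order)
        np.testing.assert_allclose(a_ld, a_direct, rtol=1e-10, atol=1e-12)

    def test_residual_nonincreasing_in_order(self, rng):
        x = _ar_series([1.0, -0.7, 0.2], 5000, seed=3)
        _, residuals = levinson_durbin(autocorr(x, 8), 8)
        assert np.all(np.diff(residuals) <= 1e-12)
        assert residuals[0] <= autocorr(x, 0).r0


class TestFitLpc:
    def test_recovers_ar1_coefficient(self):
        x = _ar_series([1.0, -0.9], 60_000, seed=11, burn=200)
        model = fit_lpc(x, FS, order=1)
        assert abs(model.coeffs[0] - 0.9) < 0.01
        assert model.residual <= autocorr(x, 0).r0

    def test_white_noise_near_zero_model(self, rng):
        x = rng.standard_normal(60_000)
        model = fit_lpc(x, FS, order=2)
        np.testing.assert_allclose(model.coeffs, 0.0, atol=0.02)
        assert model.residual == pytest.approx(autocorr(x, 0).r0, rel=0.01)

    def test_recovers_ar2_conjugate_pole_pair(self):
        a1, a2 = ar2_coefficients(0.95, 14.0, FS)
        x = _ar_series([1.0, -a1, -a2], 60_000, seed=5, burn=200)
        model = fit_lpc(x, FS, order=2)
        np.testing.assert_allclose(model.coeffs, [a1, a2], atol=0.01)
        assert model.pole_radius == pytest.approx(0.95, abs=0.01)
        assert model.is_stable

    def test_order_beyond_two_rejected(self):
        with pytest.raises(ValueError, match="order"):
            fit_lpc(np.zeros(100), FS, order=3)


class TestPolesAndDominantFrequency:
    def test_conjugate_pair_worked_example(self):
        p1, p2 = poles_of_order2([2 / 3, -1 / 6])
        assert p1 == pytest.approx(1 / 3 + 0.23570226j, abs=1e-7)
        assert p2 == pytest.approx(np.conj(p1))
        assert abs(p1) == pytest.approx(np.sqrt(1 / 6))

    def test_real_roots_worked_example(self):
        p1, p2 = poles_of_order2([0.5, 0.24])
        assert sorted([p1.real, p2.real]) == pytest.approx([-0.3, 0.8])
        assert p1.imag == p2.imag == 0
        assert dominant_frequency((p1, p2), FS) is None

    @given(
        st.floats(min_value=0.05, max_value=0.999),
        st.floats(min_value=0.01, max_value=np.pi - 0.01),
    )
    def test_conjugate_construction_identity(self, radius, theta):
        a1, a2 = 2 * radius * np.cos(theta), -(radius**2)
        p1, p2 = poles_of_order2([a1, a2])
        assert abs(p1) == pytest.approx(radius, rel=1e-9)
        assert abs(np.angle(p1)) == pytest.approx(theta, rel=1e-6)

    def test_pole_phase_maps_to_hertz(self):
        a = ar2_coefficients(0.95, 14.0, FS)
        np.testing.assert_allclose(a, [1.892654, -0.9025], atol=1e-6)
        f0 = dominant_frequency(poles_of_order2(a), FS)
        assert f0 == pytest.approx(14.0, abs=1e-9)

    def test_negative_real_axis_limit_is_nyquist(self):
        # theta = pi: a = (-2A, -A^2), double pole at -A
        f0 = dominant_frequency(poles_of_order2([-1.8, -0.81]), FS)
        assert f0 == pytest.approx(FS / 2)


class TestSeparationFeature:
    def test_scaling_worked_example(self):
        model = LpcModel(order=1, coeffs=np.array([0.99714]), residual=0.1, fs=FS)
        assert separation_feature(model) == pytest.approx(2.86)
        model1 = LpcModel(order=1, coeffs=np.array([1.0]), residual=0.0, fs=FS)
        assert separation_feature(model1) == 0.0

    def test_broader_bandwidth_gives_larger_feature(self):
        narrow = _ar_series(
            [1.0, *(-c for c in ar2_coefficients(0.99, 13.0, FS))], 60_000, seed=8
        )
        broad = _ar_series(
            [1.0, *(-c for c in ar2_coefficients(0.90, 13.0, FS))], 60_000, seed=8
        )
        f_narrow = separation_feature(fit_lpc(narrow, FS, 1))
        f_broad = separation_feature(fit_lpc(broad, FS, 1))
        assert f_broad > f_narrow > 0

    def test_requires_order_one(self):
        model = LpcModel(order=2, coeffs=np.array([0.5, 0.1]), residual=0.1, fs=FS)
        with pytest.raises(ValueError, match="order-1"):
            separation_feature(model)


class TestArPsd:
    def test_white_model_flat_at_j_ts(self):
        model = LpcModel(order=1, coeffs=np.array([0.0]), residual=2.0, fs=FS)
        psd = ar_psd(model, np.linspace(0, FS / 2, 100))
        np.testing.assert_allclose(psd, 2.0 / FS)

    def test_ar1_spectrum_monotone_decreasing(self):
        model = LpcModel(order=1, coeffs=np.array([0.9]), residual=1.0, fs=FS)
        psd = ar_psd(model, np.linspace(1.0, FS / 2, 200))
        assert np.all(np.diff(psd) < 0)

    def test_ar2_spectral_peak_near_pole_frequency(self):
        # narrowband regime: at radius 0.995 the spectral maximum sits at
        # the pole frequency (broad peaks are pulled toward lower f)
        a = np.array(ar2_coefficients(0.995, 14.0, FS))
        model = LpcModel(order=2, coeffs=a, residual=1.0, fs=FS)
        grid = np.arange(0.0, 100.0, 0.05)
        peak = grid[np.argmax(ar_psd(model, grid))]
        assert abs(peak - 14.0) < 0.5

    def test_grid_beyond_nyquist_rejected(self):
        model = LpcModel(order=1, coeffs=np.array([0.5]), residual=1.0, fs=FS)
        with pytest.raises(ValueError, match="fs/2"):
            ar_psd(model, np.array([600.0]))


class TestStreaming:
    @pytest.mark.parametrize("order", [1, 2])
    def test_matches_batch_fit_on_every_prefix(self, order):
        a1, a2 = ar2_coefficients(0.95, 14.0, FS)
        x = _ar_series([1.0, -a1, -a2], 60_000, seed=21, burn=200)
        stream = StreamingLpc(order=order, fs=FS)
        for start in range(0, len(x), 1000):
            stream.update(x[start : start + 1000])
            batch = fit_lpc(x[: start + 1000], FS, order)
            np.testing.assert_allclose(
                stream.model().coeffs, batch.coeffs, rtol=1e-9
            )

    def test_empty_update_leaves_state_unchanged(self, rng):
        stream = StreamingLpc(order=1, fs=FS).update(rng.standard_normal(5000))
        before = stream.coefficient()
        stream.update(np.array([]))
        assert stream.coefficient() == before
        assert stream.count == 5000

    def test_uneven_chunk_sizes_equivalent(self, rng):
        x = rng.standard_normal(10_000)
        s1 = StreamingLpc(order=2, fs=FS).update(x)
        s2 = StreamingLpc(order=2, fs=FS)
        for chunk in np.array_split(x, [3, 10, 501, 502, 7000]):
            s2.update(chunk)
        np.testing.assert_allclose(s1.model().coeffs, s2.model().coeffs, rtol=1e-12)

    def test_two_condition_traces_separate_within_60_s(self, short_sessions):
        """Expanding-window feature traces of the two condition presets
        stabilize and stay apart after the first minute (real-time view)."""
        traces = {}
        for name, rec in short_sessions.items():
            series = preprocess_session(rec)
            stream = StreamingLpc(order=1, fs=rec.fs)
            trace = []
            for start in range(0, len(series), 1000):
                stream.update(series[start : start + 1000])
                trace.append(1000.0 * (1.0 - stream.coefficient()))
            traces[name] = np.asarray(trace)
        after_60s = {k: v[60:] for k, v in traces.items()}
        assert after_60s["saline"].max() < after_60s["levodopa"].min()
        for v in after_60s.values():
            assert v.std() < 0.2
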