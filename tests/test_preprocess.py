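"""Smoothing, arPLS baseline, solvent-front mask and internal standard."""

import numpy as np
import pytest

from chromyield.chromdata import PDAChromatogram
from chromyield.errors import (
    InternalStandardError,
    ParameterError,
    ValidationError,
)
from chromyield.preprocess import (
    arpls_baseline,
    correct_baseline,
    internal_standard_scale,
    mask_solvent_front,
    smooth,
)
from chromyield.simulate import simulate_sample


def _pda_from_matrix(a, dt=1.0):
    times = np.arange(a.shape[0], dtype=float) * dt
    wl = np.linspace(200.0, 800.0, a.shape[1])
    return PDAChromatogram(times, wl, a)


def _gradient_drift(t, amplitude=0.05):
    phi = np.interp(t, [0, 30, 390, 420, 450, 480],
                    [0.05, 0.05, 1.0, 1.0, 0.05, 0.05])
    return amplitude * (phi - 0.05) / 0.95


class TestSmooth:
    def test_constant_matrix_unchanged(self):
        pda = _pda_from_matrix(np.full((50, 5), 0.7))
        out = smooth(pda, window=7, polyorder=3)
        np.testing.assert_allclose(out.absorbance, pda.absorbance,
                                   atol=1e-12)

    def test_noise_variance_strictly_reduced(self):
        rng = np.random.default_rng(0)
        pda = _pda_from_matrix(rng.normal(0, 0.01, (200, 4)))
        out = smooth(pda)
        var_before = pda.absorbance.var(axis=0)
        var_after = out.absorbance.var(axis=0)
        assert np.all(var_after < var_before)

    def test_gaussian_peak_area_preserved(self):
        t = np.arange(200.0)
        peak = np.exp(-0.5 * ((t - 100) / 10.0) ** 2)
        pda = _pda_from_matrix(peak[:, None] * np.ones((1, 3)))
        out = smooth(pda, window=7, polyorder=3)
        a0 = np.trapezoid(pda.absorbance[:, 0], t)
        a1 = np.trapezoid(out.absorbance[:, 0], t)
        assert abs(a1 - a0) / a0 < 0.005

    @pytest.mark.parametrize("window,polyorder", [(8, 3), (5, 5), (501, 3)])
    def test_bad_window_raises(self, window, polyorder):
        pda = _pda_from_matrix(np.zeros((400, 3)))
        with pytest.raises(ParameterError):
            smooth(pda, window=window, polyorder=polyorder)


class TestArpls:
    def test_zero_trace_fixed_point(self):
        res = arpls_baseline(np.zeros(100))
        np.testing.assert_allclose(res.baseline, 0.0, atol=1e-12)
        assert res.converged

    def test_constant_trace_converges_first_iteration(self):
        res = arpls_baseline(np.full(50, 2.5))
        assert res.iterations == 1 and res.converged
        np.testing.assert_allclose(res.baseline, 2.5, atol=1e-9)

    def test_drift_only_ramp_recovered(self):
        t = np.arange(300.0)
        y = 0.001 * t  # peak-free linear drift
        res = arpls_baseline(y)
        assert np.max(np.abs(y - res.baseline)) < 0.01 * (y.max() - y.min())

    def test_peak_on_ramp_baseline_and_area(self):
        t = np.arange(481.0)
        ramp = 0.0002 * t
        peak = 1.0 * np.exp(-0.5 * ((t - 200) / 5.0) ** 2)
        res = arpls_baseline(ramp + peak)
        under = slice(180, 221)
        assert np.max(np.abs(res.baseline[under] - ramp[under])) \
            < 0.02 * ramp.max()
        corrected = ramp + peak - res.baseline
        true_area = np.trapezoid(peak, t)
        assert abs(np.trapezoid(corrected[under], t[under]) - true_area) \
            < 0.02 * true_area

    def test_weights_bounded(self):
        rng = np.random.default_rng(3)
        y = np.cumsum(rng.normal(0, 0.01, 200)) \
            + np.exp(-0.5 * ((np.arange(200) - 80) / 4.0) ** 2)
        res = arpls_baseline(y)
        assert res.weights.min() >= 0.0 and res.weights.max() <= 1.0

    def test_baseline_invariant_under_added_sharp_peak(self):
        t = np.arange(481.0)
        drift = _gradient_drift(t)
        rng = np.random.default_rng(1)
        noise = rng.normal(0, 0.002, t.size)
        base_only = arpls_baseline(drift + noise).baseline
        with_peak = arpls_baseline(
            drift + noise + 0.8 * np.exp(-0.5 * ((t - 150) / 3.0) ** 2)
        ).baseline
        drift_area = np.trapezoid(np.abs(drift) + 1e-6, t)
        assert np.trapezoid(np.abs(with_peak - base_only), t) \
            < 0.001 * max(drift_area, 1.0) + 0.05

    def test_nan_rejected(self):
        y = np.zeros(50)
        y[10] = np.nan
        with pytest.raises(ValidationError):
            arpls_baseline(y)

    @pytest.mark.parametrize("lambda_s,ratio", [(-1.0, 1e-6), (1e4, 2.0)])
    def test_bad_parameters(self, lambda_s, ratio):
        with pytest.raises(ParameterError):
            arpls_baseline(np.zeros(50), lambda_s=lambda_s, ratio=ratio)


class TestCorrectBaseline:
    def test_zero_matrix_fixed_point(self):
        pda = _pda_from_matrix(np.zeros((100, 4)))
        out = correct_baseline(pda)
        np.testing.assert_allclose(out.absorbance, 0.0, atol=1e-12)

    def test_drift_free_simulation_nearly_unchanged(self, single_analyte,
                                                    constants, gradient):
        pda, _, _ = simulate_sample(
            [single_analyte], constants=constants, gradient=gradient,
            noise_sigma=0.0, drift_amplitude=0.0, seed=0, ms_noise=0.0,
            solvent_front_height=0.0)
        out = correct_baseline(pda)
        assert np.max(np.abs(out.absorbance - pda.absorbance)) < 1e-3

    def test_gradient_drift_removed_in_peak_free_windows(
            self, single_analyte, constants, gradient):
        # detector noise present: arPLS's asymmetric reweighting is defined
        # by the statistics of the noise about the baseline
        pda, _, truth = simulate_sample(
            [single_analyte], constants=constants, gradient=gradient,
            noise_sigma=0.001, drift_amplitude=0.1, seed=0, ms_noise=0.0,
            solvent_front_height=0.0)
        out = correct_baseline(pda)
        # peak-free window away from analyte (200 s), standard (360 s),
        # boundaries and gradient corners
        sl = out.window_slice(60.0, 160.0)
        resid = out.absorbance[sl]
        assert float(np.sqrt(np.mean(resid ** 2))) < 0.005

    def test_approximately_idempotent(self, single_analyte, constants,
                                      gradient):
        pda, _, truth = simulate_sample(
            [single_analyte], constants=constants, gradient=gradient,
            noise_sigma=0.001, drift_amplitude=0.05, seed=4)
        once = correct_baseline(pda)
        twice = correct_baseline(once)
        j = int(np.argmin(np.abs(pda.wavelengths - 350.0)))
        sl = pda.window_slice(185.0, 215.0)
        a_once = np.trapezoid(once.absorbance[sl, j], pda.times[sl])
        a_twice = np.trapezoid(twice.absorbance[sl, j], pda.times[sl])
        assert abs(a_twice - a_once) < 0.01 * a_once


class TestSolventMask:
    def test_zero_dead_time_is_noop(self):
        pda = _pda_from_matrix(np.ones((50, 3)))
        out = mask_solvent_front(pda, 0.0)
        assert out.t_dead == 0.0
        assert np.all(out.live_mask)

    def test_mask_excludes_early_times(self):
        pda = _pda_from_matrix(np.ones((50, 3)))
        out = mask_solvent_front(pda, 24.0)
        assert not out.live_mask[:24].any()
        assert out.live_mask[24:].all()
        # data retained, not deleted
        np.testing.assert_array_equal(out.absorbance, pda.absorbance)

    def test_dead_time_beyond_run_rejected(self):
        pda = _pda_from_matrix(np.ones((50, 3)))
        with pytest.raises(ParameterError):
            mask_solvent_front(pda, 100.0)


class TestInternalStandard:
    def _pda_with_ist_peak(self, area=4.0, retention=360.0, sigma=3.0):
        t = np.arange(0.0, 481.0)
        wl = np.arange(200.0, 801.0, 100.0)
        a = np.zeros((t.size, wl.size))
        profile = area / (sigma * np.sqrt(2 * np.pi)) \
            * np.exp(-0.5 * ((t - retention) / sigma) ** 2)
        a[:, 1] = profile  # 300 nm channel
        return PDAChromatogram(t, wl, a)

    def test_factor_identity(self):
        pda = self._pda_with_ist_peak(area=4.0)
        scale = internal_standard_scale(pda, (345, 375), 300.0,
                                        nominal_area=4.0)
        assert scale.factor == pytest.approx(1.0, abs=0.01)
        assert not scale.out_of_range

    def test_factor_linearity(self):
        pda = self._pda_with_ist_peak(area=2.0)
        scale = internal_standard_scale(pda, (345, 375), 300.0,
                                        nominal_area=4.0,
                                        clip=(0.5, 4.0))
        assert scale.factor == pytest.approx(2.0, rel=0.01)
        assert scale.out_of_range

    def test_factor_clipped(self):
        pda = self._pda_with_ist_peak(area=1.0)
        scale = internal_standard_scale(pda, (345, 375), 300.0,
                                        nominal_area=4.0)
        assert scale.factor == pytest.approx(2.0)  # clipped from 4.0
        assert scale.out_of_range

    def test_missing_standard_raises(self):
        pda = self._pda_with_ist_peak(area=4.0)
        with pytest.raises(InternalStandardError, match="not found"):
            internal_standard_scale(pda, (100, 130), 300.0, nominal_area=4.0)

    def test_injection_perturbation_corrected(self, single_analyte,
                                              constants, gradient, config):
        """A x0.9 injection scales the standard too; the factor undoes it."""
        from chromyield.model import ReactionYieldModel

        results = {}
        for factor in (1.0, 0.9):
            pda, traces, _ = simulate_sample(
                [single_analyte], constants=constants, gradient=gradient,
                noise_sigma=0.0005, drift_amplitude=0.02, seed=11,
                injection_factor=factor)
            from chromyield.chromdata import AnalyteSpec
            spec = AnalyteSpec(smiles=single_analyte.smiles, exact_mass=485.0)
            from chromyield.quantify import TablePredictor
            pred = TablePredictor()
            pred.add(single_analyte.smiles, "water",
                     single_analyte.log10_eps_water, lambda_max=350.0)
            pred.add(single_analyte.smiles, "acetonitrile",
                     single_analyte.log10_eps_acn, lambda_max=350.0)
            res = ReactionYieldModel(pda, traces, spec, config=config,
                                     epsilon_predictor=pred).fit()
            results[factor] = res
        assert results[0.9].ist_factor == pytest.approx(1 / 0.9, rel=0.02)
        assert results[0.9].target_area == pytest.approx(
            results[1.0].target_area, rel=0.02)
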