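"""Observation models and least-squares estimation."""

import numpy as np
import pytest

from sonokinetics.errors import ArgumentError, DegenerateDataError
from sonokinetics.fitting import (calibrate_bleach, fit_trace, initialize_rate,
                                  model_2cm, model_3cm, model_decay, smooth_trace)
from sonokinetics.model import UptakeTrace

TIMES = np.arange(0.0, 1801.0, 30.0)


def make_trace(y, t=TIMES):
    return UptakeTrace(times=t, intensities=y)


class TestClosedForms:
    def test_decay_at_zero_and_flat(self):
        assert model_decay(0.0, 2.0, 3.0, 1e-3) == pytest.approx(5.0)
        t = np.linspace(0, 1000, 11)
        assert np.allclose(model_decay(t, 2.0, 3.0, 0.0), 5.0)

    def test_decay_value_continuous_laser(self):
        # exp(-2.63e-3 * 600) = exp(-1.578), cross-checked by log-linear slope
        value = model_decay(600.0, 0.0, 1.0, 2.63e-3)
        assert value == pytest.approx(np.exp(-1.578), rel=1e-12)
        assert value == pytest.approx(0.2064, abs=5e-5)
        slope = (np.log(model_decay(601.0, 0.0, 1.0, 2.63e-3)) - np.log(value))
        assert slope == pytest.approx(-2.63e-3, rel=1e-9)

    def test_2cm_fraction_at_one_time_constant(self):
        k_f = 7e-4
        frac = (model_2cm(1.0 / k_f, 0.0, 1.0, k_f))
        assert frac == pytest.approx(1 - np.exp(-1), rel=1e-12)
        assert model_2cm(0.0, 1.5, 2.0, k_f) == pytest.approx(1.5)

    def test_2cm_half_hour_fraction(self):
        assert model_2cm(1800.0, 0.0, 1.0, 1.02e-3) == pytest.approx(0.8405, abs=5e-5)

    def test_3cm_reduces_to_2cm_without_bleaching(self):
        t = np.linspace(0.0, 1800.0, 200)
        a = model_3cm(t, 0.3, 2.0, 1.02e-3, 0.0)
        b = model_2cm(t, 0.3, 2.0, 1.02e-3)
        assert np.allclose(a, b, rtol=0, atol=1e-14)

    def test_3cm_limit_as_kpb_vanishes(self):
        t = np.linspace(0.0, 1800.0, 500)
        diff = model_3cm(t, 0.0, 1.0, 1e-3, 1e-12) - model_2cm(t, 0.0, 1.0, 1e-3)
        assert np.max(np.abs(diff)) < 1e-8

    def test_3cm_peak_time_closed_form(self):
        k_f, k_pb = 1.02e-3, 2.63e-3
        t_peak = np.log(k_pb / k_f) / (k_pb - k_f)
        assert t_peak == pytest.approx(588.0, abs=1.0)
        t = np.linspace(0.0, 3000.0, 300001)  # dense grid argmax
        y = model_3cm(t, 0.0, 1.0, k_f, k_pb)
        assert t[np.argmax(y)] == pytest.approx(t_peak, abs=0.02)

    def test_3cm_equal_rate_continuity(self):
        t = np.linspace(0.0, 1800.0, 200)
        exact = model_3cm(t, 0.0, 1.0, 1e-3, 1e-3)
        nearby = model_3cm(t, 0.0, 1.0, 1e-3, 1e-3 + 1e-9)
        scale = np.max(np.abs(exact))
        assert np.max(np.abs(exact - nearby)) / scale < 1e-6


class TestInitializeRate:
    @pytest.mark.parametrize("k_true", [1e-3, 3e-3])
    def test_rise_guess_within_factor_two(self, k_true):
        trace = make_trace(model_2cm(TIMES, 0.0, 1.0, k_true))
        k0 = initialize_rate(trace, "rise")
        assert 0.5 * k_true <= k0 <= 2.0 * k_true

    def test_decay_guess_within_factor_two(self):
        trace = make_trace(model_decay(TIMES, 0.0, 1.0, 2.63e-3))
        k0 = initialize_rate(trace, "decay")
        assert 0.5 * 2.63e-3 <= k0 <= 2.0 * 2.63e-3

    def test_constant_trace_rejected(self):
        with pytest.raises(DegenerateDataError):
            initialize_rate(make_trace(np.ones_like(TIMES)), "rise")


class TestFitRecovery:
    @pytest.mark.parametrize("k_true", [1e-4, 4.1e-4, 1.02e-3, 2.63e-3, 6.53e-3, 1e-2])
    @pytest.mark.parametrize("model", ["decay", "2cm", "3cm"])
    def test_noiseless_recovery(self, model, k_true):
        """Exact parameter recovery on noiseless model-generated data."""
        baseline, amplitude = 0.7, 5.0
        if model == "decay":
            y = model_decay(TIMES, baseline, amplitude, k_true)
            fit = fit_trace(make_trace(y), "decay")
            k_hat = fit.k_pb
        elif model == "2cm":
            y = model_2cm(TIMES, baseline, amplitude, k_true)
            fit = fit_trace(make_trace(y), "2cm")
            k_hat = fit.k_f
        else:
            k_pb = 2.63e-3
            y = model_3cm(TIMES, baseline, amplitude, k_true, k_pb)
            fit = fit_trace(make_trace(y), "3cm", fixed_k_pb=k_pb)
            k_hat = fit.k_f
        assert fit.converged
        assert abs(k_hat - k_true) / k_true < 1e-6
        assert fit.baseline == pytest.approx(baseline, rel=1e-5, abs=1e-6)
        assert fit.amplitude == pytest.approx(amplitude, rel=1e-5)

    def test_too_few_points_rejected(self):
        trace = UptakeTrace(times=np.array([0.0, 30.0, 60.0]),
                            intensities=np.array([0.0, 1.0, 2.0]))
        with pytest.raises(DegenerateDataError):
            fit_trace(trace, "2cm")

    def test_3cm_requires_fixed_bleach_rate(self):
        y = model_3cm(TIMES, 0.0, 1.0, 1e-3, 2e-3)
        with pytest.raises(ArgumentError):
            fit_trace(make_trace(y), "3cm")

    def test_noisy_median_bias_small(self, rng):
        """Median k_f bias under 5 % multiplicative noise stays below 5 %."""
        k_true = 1.02e-3
        clean = model_2cm(TIMES, 0.1, 5.0, k_true)
        estimates = []
        for _ in range(200):
            noisy = clean * (1.0 + 0.05 * rng.standard_normal(clean.shape))
            fit = fit_trace(make_trace(noisy), "2cm")
            if fit.converged:
                estimates.append(fit.k_f)
        bias = np.median(estimates) / k_true - 1.0
        assert abs(bias) < 0.05

    def test_bleaching_inflates_uncorrected_2cm_rate(self):
        """A 2CM fit of rise-and-bleach data overestimates the generating k_f."""
        k_f, k_pb = 1.02e-3, 2.63e-3
        y = model_3cm(TIMES, 0.0, 5.0, k_f, k_pb)
        fit = fit_trace(make_trace(y), "2cm")
        assert fit.k_f > k_f


class TestBleachCalibration:
    def test_two_point_solution(self):
        cal = calibrate_bleach(0.033, 0.41e-3, 1.0, 2.63e-3)
        # hand solve: k_laser = (2.63 - 0.41)e-3 / 0.967, k_dark = 0.41e-3 - 0.033 k_laser
        assert cal.k_laser == pytest.approx(2.2958e-3, abs=1e-7)
        assert cal.k_dark == pytest.approx(0.3342e-3, abs=1e-7)
        assert cal.rate(0.033) == pytest.approx(0.41e-3, rel=1e-12)
        assert cal.rate(1.0) == pytest.approx(2.63e-3, rel=1e-12)

    def test_flat_and_proportional_cases(self):
        flat = calibrate_bleach(0.0, 5e-4, 1.0, 5e-4)
        assert flat.k_laser == 0.0 and flat.k_dark == pytest.approx(5e-4)
        prop = calibrate_bleach(0.0, 0.0, 1.0, 7e-4)
        assert prop.k_dark == 0.0 and prop.k_laser == pytest.approx(7e-4)

    def test_equal_duty_cycles_rejected(self):
        with pytest.raises(ArgumentError):
            calibrate_bleach(0.5, 1e-3, 0.5, 2e-3)

    def test_negative_solution_clipped_with_warning(self):
        with pytest.warns(UserWarning):
            cal = calibrate_bleach(0.0, 1e-3, 1.0, 5e-4)
        assert cal.k_laser == 0.0


class TestSmoothTrace:
    def test_constant_trace_unchanged(self):
        t = np.arange(0.0, 540.0, 1.0)
        trace = UptakeTrace(times=t, intensities=np.full_like(t, 3.3))
        out = smooth_trace(trace, 20.0)
        assert np.allclose(out.intensities, 3.3)

    def test_linear_ramp_block_means_are_midpoints(self):
        t = np.arange(0.0, 540.0, 1.0)
        trace = UptakeTrace(times=t, intensities=2.0 * t)
        out = smooth_trace(trace, 20.0)
        assert len(out) == 27
        assert np.allclose(out.intensities, 2.0 * out.times)

    def test_window_below_sampling_interval_rejected(self):
        t = np.arange(0.0, 300.0, 30.0)
        trace = UptakeTrace(times=t, intensities=t)
        with pytest.raises(ArgumentError):
            smooth_trace(trace, 10.0)
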