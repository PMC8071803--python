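"""Filter construction: truncation rule, ACF, step response, convolution."""

import numpy as np
import pytest
import scipy.signal
from hypothesis import given
from hypothesis import strategies as st

import ionideal as ii
from ionideal.filters import attenuation_factor, untruncated_acf

FS = 5e4


def oracle_acf(poles, cutoff, max_lag, oversample=1000):
    """Independent ACF oracle: dense impulse response via scipy.signal.impulse,
    autocorrelation by numerical integration on the oversampled grid."""
    b, a = scipy.signal.bessel(poles, 2 * np.pi * cutoff, analog=True, norm="mag")
    t_end = 80.0
    t = np.linspace(0, t_end, int(t_end * oversample) + 1)
    _, h = scipy.signal.impulse((b, a), T=t)
    g = np.array(
        [np.trapezoid(h[: len(h) - k] * h[k:], dx=1.0 / oversample)
         for k in range(0, max_lag * oversample + 1, oversample)]
    )
    return g / g[0]


class TestTruncationRule:
    def test_standard_filter_truncates_at_11(self, std_filter):
        assert std_filter.m == 11
        assert std_filter.kind == "bessel"

    def test_acf_below_threshold_beyond_m(self, std_filter):
        rho = untruncated_acf(std_filter, np.arange(12, 64))
        assert np.all(np.abs(rho) < 1e-3)
        # and lag 11 is genuinely the first lag from which this holds
        assert abs(untruncated_acf(std_filter, np.array([10]))[0]) >= 1e-3

    def test_dominating_threshold_gives_degenerate_kernel(self):
        filt = ii.make_filter(4, 0.1, FS, acf_threshold=0.95)
        assert filt.m == 0
        # convolution degenerates toward the identity on samples
        sig = ii.StepSignal(change_times=[0.01], levels=[1.0, 3.0], end=0.02)
        out = ii.convolve_step_signal(sig, filt, [0.005, 0.015])
        np.testing.assert_allclose(out, [1.0, 3.0])

    def test_m_matches_oversampled_quadrature_oracle(self):
        threshold = 1e-2
        rho = oracle_acf(4, 0.1, max_lag=30)
        above = np.nonzero(np.abs(rho[1:]) >= threshold)[0]
        m_oracle = int(above[-1]) + 2  # +1 for lag offset, +1 for the rule
        filt = ii.make_filter(4, 0.1, FS, acf_threshold=threshold)
        assert filt.m == m_oracle

    def test_lag1_acf_matches_quadrature_oracle(self, std_filter):
        rho_oracle = oracle_acf(4, 0.1, max_lag=2)
        analytic = untruncated_acf(std_filter, np.array([1.0]))[0]
        assert abs(analytic - rho_oracle[1]) < 1e-4

    def test_m_monotone_in_threshold(self):
        ms = [
            ii.make_filter(4, 0.1, FS, acf_threshold=thr).m
            for thr in (1e-4, 1e-3, 1e-2, 1e-1)
        ]
        assert all(a >= b for a, b in zip(ms, ms[1:]))
        assert ms[1] == 11

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"poles": 3},
            {"poles": 10},
            {"cutoff": 0.7},
            {"cutoff": 0.0},
            {"sample_rate": -1.0},
            {"acf_threshold": 0.0},
            {"acf_threshold": 1.0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        params = dict(poles=4, cutoff=0.1, sample_rate=FS, acf_threshold=1e-3)
        params.update(kwargs)
        with pytest.raises(ValueError):
            ii.make_filter(**params)


class TestKernelAndAcf:
    def test_acf_normalization_and_truncation(self, std_filter):
        rho = ii.kernel_acf(std_filter)
        assert rho[0] == 1.0
        assert len(rho) == std_filter.m + 1
        # beyond the truncated support the sampled-noise ACF vanishes exactly
        assert rho[-1] == 0.0

    def test_truncated_acf_close_to_untruncated(self, std_filter):
        rho_t = ii.kernel_acf(std_filter)
        rho_u = untruncated_acf(std_filter, np.arange(std_filter.m + 1))
        assert np.max(np.abs(rho_t - rho_u)) < 2e-3

    def test_kernel_unit_integral(self, std_filter):
        t = np.linspace(0, std_filter.m / FS, 20001)
        integral = np.trapezoid(std_filter.kernel(t), t)
        assert abs(integral - 1.0) < 1e-6

    def test_step_response_limits(self, std_filter):
        assert std_filter.step_response([-1e-3, 0.0]).max() == 0.0
        t_end = std_filter.m / FS
        np.testing.assert_allclose(
            std_filter.step_response([t_end, t_end + 1e-3]), 1.0, atol=1e-12
        )

    def test_cutoff_conversion(self, std_filter):
        assert std_filter.cutoff_hz == pytest.approx(5000.0)
        assert std_filter.filter_length == pytest.approx(11 / FS)

    def test_fingerprint_stable(self, std_filter):
        assert std_filter.fingerprint == ii.make_filter(4, 0.1, FS).fingerprint
        assert std_filter.fingerprint != ii.make_filter(2, 0.1, FS).fingerprint


class TestConvolution:
    def test_constant_preserved(self, std_filter):
        sig = ii.StepSignal(change_times=[], levels=[2.5], end=0.01)
        t = np.linspace(0, 0.01, 101)
        np.testing.assert_allclose(
            ii.convolve_step_signal(sig, std_filter, t), 2.5, atol=1e-12
        )

    def test_single_jump_limits_and_bounds(self, std_filter):
        tau = 0.005
        sig = ii.StepSignal(change_times=[tau], levels=[0.0, 1.0], end=0.02)
        t = np.linspace(0, 0.02, 2001)
        out = ii.convolve_step_signal(sig, std_filter, t)
        assert np.all(out[t <= tau] == 0.0)
        np.testing.assert_allclose(
            out[t >= tau + std_filter.m / FS], 1.0, atol=1e-12
        )
        # bounded between the levels up to the (sub-percent) Bessel overshoot
        assert out.min() >= -1e-2 and out.max() <= 1.0 + 1e-2

    def test_short_peak_attenuated(self, std_filter):
        # a peak of half the filter length never reaches its own level
        width = 0.5 * std_filter.m / FS
        sig = ii.StepSignal(
            change_times=[0.005, 0.005 + width], levels=[0.0, -1.0, 0.0], end=0.02
        )
        t = np.linspace(0, 0.02, 4001)
        out = ii.convolve_step_signal(sig, std_filter, t)
        assert out.min() > -1.0

    def test_eval_outside_support_rejected(self, std_filter):
        sig = ii.StepSignal(change_times=[], levels=[0.0], end=0.01)
        with pytest.raises(ValueError):
            ii.convolve_step_signal(sig, std_filter, [0.02])

    @given(
        a=st.floats(-5, 5),
        b=st.floats(-5, 5),
        levels=st.lists(st.floats(-2, 2), min_size=3, max_size=5),
    )
    def test_linearity_in_levels(self, std_filter, a, b, levels):
        taus = np.linspace(0.002, 0.008, len(levels) - 1)
        f = ii.StepSignal(change_times=taus, levels=levels, end=0.012)
        g = ii.StepSignal(
            change_times=taus, levels=np.ones(len(levels)), end=0.012
        )
        combo = ii.StepSignal(
            change_times=taus,
            levels=a * np.asarray(levels) + b,
            end=0.012,
        )
        t = np.linspace(0, 0.012, 97)
        lhs = ii.convolve_step_signal(combo, std_filter, t)
        rhs = a * ii.convolve_step_signal(f, std_filter, t) + b * (
            ii.convolve_step_signal(g, std_filter, t)
        )
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)


class TestAttenuation:
    def test_monotone_in_peak_length(self, std_filter):
        att = [attenuation_factor(std_filter, l) for l in (1, 2, 4, 8, 16, 40)]
        assert all(a < b for a, b in zip(att, att[1:]))
        assert att[0] < 0.5
        # the ramp still occupies ~m/2 of a 40-sample window: 1 - O(m/l)
        assert att[-1] > 0.95
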