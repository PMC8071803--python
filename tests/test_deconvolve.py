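"""Local deconvolution: parameter recovery, isolation rules, flagging."""

import numpy as np
import pytest

import ionideal as ii
from ionideal.deconvolve import isolation_distance, mark_no_deconvolution
from ionideal.segment import MultiscaleFit

FS = 5e4


def _grid_fit(trace, seg_starts, levels, regime="homogeneous", seg_sigma=None):
    """A MultiscaleFit stand-in built directly from grid segment data."""
    n = trace.n
    return MultiscaleFit(
        fit=ii.StepSignal(
            change_times=(np.asarray(seg_starts[1:]) + 0.5) / FS,
            levels=np.asarray(levels, dtype=float),
            start=0.0,
            end=n / FS,
        ),
        seg_starts=np.asarray(seg_starts, dtype=int),
        sample_rate=FS,
        n=n,
        method="jsmurf",
        noise_regime=regime,
        sigma=0.1,
        seg_sigma=None if seg_sigma is None else np.asarray(seg_sigma, float),
    )


def _rss(trace, signal, filt):
    model = ii.convolve_step_signal(signal, filt, trace.times)
    return float(np.sum((trace.values - model) ** 2))


class TestSingleChange:
    def test_noise_free_fractional_change_time_recovered(self, std_filter, store):
        tau = 17.37 / FS
        truth = ii.StepSignal(change_times=[tau], levels=[0.0, 1.0], end=0.05)
        tr = ii.simulate_trace(truth, std_filter, n=800, sigma=0.0, seed=0)
        cfg = ii.MethodConfig(method="jsmurf", r=200, seed=3)
        fit = ii.jsmurf(tr, std_filter, cfg, store)
        out = ii.local_deconvolution(tr, std_filter, fit)
        assert out.n_changes == 1
        assert abs(out.change_times[0] - tau) <= 1.0 / (100 * FS)
        np.testing.assert_allclose(out.levels, [0.0, 1.0], atol=1e-6)
        assert out.deconvolved.all()

    def test_rss_not_worse_than_grid_fit(self, std_filter, store):
        truth = ii.StepSignal(
            change_times=[0.01 + 0.37 / FS], levels=[0.0, 1.0], end=0.05
        )
        tr = ii.simulate_trace(truth, std_filter, n=1200, sigma=0.2, seed=44)
        cfg = ii.MethodConfig(method="jsmurf", r=200, seed=3)
        fit = ii.jsmurf(tr, std_filter, cfg, store)
        out = ii.local_deconvolution(tr, std_filter, fit)
        assert _rss(tr, out, std_filter) <= _rss(tr, fit.fit, std_filter) + 1e-9


class TestIsolatedPeaks:
    @pytest.mark.parametrize("length", [2.0, 3.3, 6.0, 11.0])
    def test_noise_free_peak_recovery_including_sub_filter(
        self, std_filter, store, length
    ):
        """Times to 1/(100 f_s), amplitudes to 1% down to 0.3 filter lengths:
        the deconvolution inverts the kernel attenuation a grid fit cannot."""
        t1 = 0.0100037
        t2 = t1 + length / FS
        truth = ii.StepSignal(change_times=[t1, t2], levels=[0.0, 1.0, 0.0], end=0.05)
        tr = ii.simulate_trace(truth, std_filter, n=1200, sigma=0.0, seed=0)
        cfg = ii.MethodConfig(method="jules", r=200, seed=3)
        fit = ii.jules_detect(tr, std_filter, cfg, store)
        out = ii.local_deconvolution(tr, std_filter, fit)
        assert out.n_changes == 2
        assert abs(out.change_times[0] - t1) <= 1.0 / (100 * FS)
        assert abs(out.change_times[1] - t2) <= 1.0 / (100 * FS)
        amp = out.levels[1] - (out.levels[0] + out.levels[2]) / 2
        assert abs(amp - 1.0) < 0.01
        # the grid fit underestimates the amplitude of sub-filter peaks
        if length < std_filter.m:
            grid_amp = fit.fit.levels[1] - (fit.fit.levels[0] + fit.fit.levels[2]) / 2
            assert grid_amp < amp

    def test_pair_deconvolution_at_homogeneous_isolation(self, std_filter):
        """Two close changes >= 3 filter lengths from other events: jointly
        deconvolved as a peak in the homogeneous regime."""
        m = std_filter.m
        assert isolation_distance(std_filter, "homogeneous") == 3 * m
        assert isolation_distance(std_filter, "heterogeneous") == 5 * m
        n = 1200
        truth = ii.StepSignal(
            change_times=[300 / FS, 303 / FS], levels=[0.0, 1.0, 0.0], end=n / FS
        )
        tr = ii.simulate_trace(truth, std_filter, n, sigma=0.0, seed=0)
        grid = _grid_fit(tr, [0, 300, 305], [0.0, 0.5, 0.0])
        out = ii.local_deconvolution(tr, std_filter, grid, regime="homogeneous")
        assert out.deconvolved.all()
        assert not out.no_deconvolution

    def test_isolation_threshold_depends_on_noise_regime(self, std_filter):
        """A third change 4 filter lengths away: still isolated under the
        homogeneous rule (3 m), part of a cluster under the heterogeneous
        rule (5 m)."""
        m = std_filter.m
        n = 2000
        k3 = 303 + 4 * m
        truth = ii.StepSignal(
            change_times=[300 / FS, 303 / FS, k3 / FS],
            levels=[0.0, 1.0, 0.0, 0.5],
            end=n / FS,
        )
        tr = ii.simulate_trace(truth, std_filter, n, sigma=0.0, seed=0)
        grid_h = _grid_fit(tr, [0, 300, 305, k3 + 1], [0.0, 0.5, 0.0, 0.5])
        out_hom = ii.local_deconvolution(tr, std_filter, grid_h, regime="homogeneous")
        assert out_hom.deconvolved.all()
        grid_x = _grid_fit(
            tr, [0, 300, 305, k3 + 1], [0.0, 0.5, 0.0, 0.5],
            regime="heterogeneous", seg_sigma=[0.1, 0.1, 0.1, 0.1],
        )
        with pytest.warns(UserWarning, match="deconvolved"):
            out_het = ii.local_deconvolution(
                tr, std_filter, grid_x, regime="heterogeneous"
            )
        assert not out_het.deconvolved.any()
        assert out_het.no_deconvolution


class TestClusters:
    def test_three_close_changes_flagged_not_deconvolved(self, std_filter):
        n = 1000
        tr = ii.Trace(np.zeros(n), FS)
        grid = _grid_fit(
            tr, [0, 400, 404, 408], [0.0, 1.0, 0.2, 0.8]
        )
        with pytest.warns(UserWarning, match="could not be deconvolved"):
            out = ii.local_deconvolution(tr, std_filter, grid)
        assert out.n_changes == 3  # counts preserved
        assert out.no_deconvolution == frozenset({1, 2})
        assert not out.deconvolved.any()
        # grid times kept for the flagged cluster
        np.testing.assert_allclose(
            out.change_times, (np.array([400, 404, 408]) + 0.5) / FS
        )

    def test_mark_no_deconvolution_variants(self, std_filter):
        n = 3000
        tr = ii.Trace(np.zeros(n), FS)
        # no clusters
        single = _grid_fit(tr, [0, 500], [0.0, 1.0])
        assert mark_no_deconvolution(single, std_filter) == frozenset()
        # two disjoint clusters
        grid = _grid_fit(
            tr,
            [0, 400, 404, 408, 1500, 1504, 1508],
            [0.0, 1.0, 0.2, 0.8, 0.1, 0.9, 0.3],
        )
        flagged = mark_no_deconvolution(grid, std_filter)
        assert flagged == frozenset({1, 2, 4, 5})

    def test_counts_and_order_preserved_on_mixed_fit(self, std_filter, store):
        n = 4096
        truth = ii.StepSignal(
            change_times=[0.02, 0.02 + 3 / FS, n / FS * 0.45],
            levels=[0.0, 2.0, 0.0, 3.0],
            end=n / FS,
            noise_levels=[0.2, 0.3, 0.2, 0.6],
        )
        tr = ii.simulate_trace(truth, std_filter, n, sigma=None, seed=6)
        cfg = ii.MethodConfig(
            method="hilde", noise="heterogeneous", r=150, seed=9, l_max=8
        )
        fit = ii.hilde_detect(tr, std_filter, cfg, store)
        out = ii.local_deconvolution(tr, std_filter, fit)
        assert out.n_changes == fit.fit.n_changes
        assert np.all(np.diff(out.change_times) > 0)
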