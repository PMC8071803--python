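"""Short-event detection: all-scale criterion + postfilter, local tests."""

import numpy as np
import pytest

import ionideal as ii
from ionideal.multiscale import StepFitResult

FS = 5e4


class TestJules:
    def test_noise_free_jump_staircase_collapses_to_one_change(
        self, std_filter, store
    ):
        """The all-scale criterion splits the convolution ramp of an abrupt
        change into incremental steps; the postfilter must fuse them."""
        truth = ii.StepSignal(
            change_times=[0.0100037], levels=[0.0, 1.0], end=0.05
        )
        tr = ii.simulate_trace(truth, std_filter, n=1200, sigma=0.0, seed=0)
        cfg = ii.MethodConfig(method="jules", r=200, seed=3)
        fit = ii.jules_detect(tr, std_filter, cfg, store)
        assert fit.fit.n_changes == 1
        np.testing.assert_allclose(fit.fit.levels, [0.0, 1.0], atol=0.02)

    def test_noise_free_short_peak_two_changes_attenuated_middle(
        self, std_filter, store
    ):
        truth = ii.StepSignal(
            change_times=[0.0100037, 0.0100037 + 2 / FS],
            levels=[0.0, 1.0, 0.0],
            end=0.05,
        )
        tr = ii.simulate_trace(truth, std_filter, n=1200, sigma=0.0, seed=0)
        cfg = ii.MethodConfig(method="jules", r=200, seed=3)
        fit = ii.jules_detect(tr, std_filter, cfg, store)
        assert fit.fit.n_changes == 2
        mid = fit.fit.levels[1]
        # before deconvolution the middle level is attenuated toward baseline
        assert 0.2 < mid < 0.8
        assert fit.fit.levels[0] < mid and fit.fit.levels[2] < mid

    def test_heterogeneous_regime_refused(self, std_filter, store):
        cfg = ii.MethodConfig(method="jsmurf", noise="heterogeneous", r=200, seed=3)
        tr = ii.Trace(np.zeros(100) + 0.1, FS)
        with pytest.raises(ValueError, match="hilde"):
            ii.jules_detect(tr, std_filter, cfg, store)

    def test_postfilter_idempotent(self, std_filter, store):
        # synthetic staircase: monotone micro-steps then a genuine far change
        res = StepFitResult(
            seg_starts=np.array([0, 100, 103, 106, 109, 300]),
            levels=np.array([0.0, 0.3, 0.6, 0.9, 1.0, 2.0]),
            n_changes=5,
        )
        once = ii.postfilter(res, std_filter.m, 400)
        twice = ii.postfilter(once, std_filter.m, 400)
        np.testing.assert_array_equal(once.seg_starts, twice.seg_starts)
        np.testing.assert_array_equal(once.levels, twice.levels)
        assert once.n_changes == 2  # staircase fused, distant change kept

    def test_postfilter_keeps_opposite_sign_peaks(self, std_filter):
        res = StepFitResult(
            seg_starts=np.array([0, 100, 103]),
            levels=np.array([0.0, 1.0, 0.05]),
            n_changes=2,
        )
        out = ii.postfilter(res, std_filter.m, 400)
        assert out.n_changes == 2


class TestHilde:
    def test_empty_scale_set_equals_stage_one(self, std_filter, store):
        n = 1024
        truth = ii.StepSignal(
            change_times=[400 / FS], levels=[0.0, 1.0], end=n / FS
        )
        tr = ii.simulate_trace(truth, std_filter, n, sigma=0.2, seed=8)
        cfg = ii.MethodConfig(method="hilde", r=200, seed=6, l_max=5, scale_set=())
        fit = ii.hilde_detect(tr, std_filter, cfg, store)
        stage1 = ii.jsmurf(
            tr,
            std_filter,
            ii.MethodConfig(method="jsmurf", alpha=cfg.alpha1, r=200, seed=6),
            store,
        )
        np.testing.assert_array_equal(fit.seg_starts, stage1.seg_starts)
        np.testing.assert_array_equal(fit.fit.levels, stage1.fit.levels)

    @pytest.mark.parametrize("trace_seed", [5, 7, 15])
    def test_finds_subfilter_peak_that_stage_one_misses(
        self, std_filter, store, trace_seed
    ):
        """A 3-sample peak (well below the filter length m = 11): the
        above-filter-length stage alone returns a constant fit, the local
        tests resolve the peak as two changes near its true position."""
        n = 2048
        truth = ii.StepSignal(
            change_times=[900 / FS, 903 / FS], levels=[0.0, 0.65, 0.0], end=n / FS
        )
        tr = ii.simulate_trace(
            truth, std_filter, n, sigma=0.1,
            seed=np.random.default_rng([trace_seed, 9]),
        )
        stage1 = ii.jsmurf(
            tr,
            std_filter,
            ii.MethodConfig(method="jsmurf", alpha=0.01, r=300, seed=13),
            store,
        )
        assert stage1.fit.n_changes == 0
        cfg = ii.MethodConfig(method="hilde", r=300, seed=13, l_max=10)
        fit = ii.hilde_detect(tr, std_filter, cfg, store)
        assert fit.fit.n_changes == 2
        assert abs(fit.seg_starts[1] - 900) <= 2 * std_filter.m

    def test_stage_one_changes_are_subset_of_output(self, std_filter, store):
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
        stage1 = ii.jsmurf(
            tr,
            std_filter,
            ii.MethodConfig(
                method="jsmurf", noise="heterogeneous", alpha=cfg.alpha1,
                r=150, seed=9,
            ),
            store,
        )
        assert set(stage1.seg_starts[1:]).issubset(set(fit.seg_starts[1:]))
        assert fit.fit.n_changes >= stage1.fit.n_changes

    def test_detection_power_drops_with_peak_length_below_filter(
        self, std_filter, store
    ):
        n, reps = 1024, 80
        cfg = ii.MethodConfig(method="hilde", r=300, seed=21, l_max=10)
        power = []
        for length in (2, 4, 8):
            hits = 0
            for i in range(reps):
                truth = ii.StepSignal(
                    change_times=[500 / FS, (500 + length) / FS],
                    levels=[0.0, 1.8, 0.0],
                    end=n / FS,
                )
                tr = ii.simulate_trace(
                    truth, std_filter, n, sigma=0.3,
                    seed=np.random.default_rng([i, length, 5]),
                )
                hits += (
                    ii.hilde_detect(tr, std_filter, cfg, store).fit.n_changes >= 1
                )
            power.append(hits / reps)
        # attenuation: power non-increasing as the peak shrinks below m
        assert power[0] <= power[1] <= power[2]
        assert power[2] > power[0] + 0.3

    def test_short_segment_windows_skipped_with_warning(self, std_filter, store):
        n = 256
        tr = ii.simulate_null(n, std_filter, seed=2)
        cfg = ii.MethodConfig(
            method="hilde", r=100, seed=2, l_max=250, scale_set=(245,)
        )
        with pytest.warns(UserWarning, match="skipped"):
            ii.hilde_detect(tr, std_filter, cfg, store)
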