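"""Multiscale detection on scales above the filter length (JSMURF-style).

After low-pass filtering, a conductance change produces a ramp occupying at
most m samples; outside these transitions the convolved signal equals the
underlying step function exactly.  The detector therefore considers all
interval scales above the filter length and ignores the first m data points of
every interval, so each retained stretch is unaffected by an event at its left
edge.  The returned idealization has the minimal number of jumps consistent
with the multiscale constraints at the calibrated critical value, which bounds
the probability of any false-positive change on model-conform data by the
error level alpha.

Homogeneous regime: one global robust noise level standardizes all intervals.
Heterogeneous regime (open-channel noise): every interval is studentized with
its own difference-based local noise estimate, and the fit carries per-segment
noise levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import MethodConfig
from .critval import CritvalStore, get_critical_value
from .filters import LowpassFilter
from .multiscale import (
    IntervalSystem,
    StepFitResult,
    fit_minimal_steps,
    robust_noise_scale,
    scale_penalty,
)
from .signals import StepSignal, Trace

__all__ = ["MultiscaleFit", "jsmurf", "estimate_noise"]


@dataclass
class MultiscaleFit:
    """A multiscale step fit with its sample-index bookkeeping.

    The idealization proper (change times in seconds, levels in nS) lives in
    ``fit``; ``seg_starts`` keeps the per-segment sample index ranges on the
    sampling grid, which downstream steps (local tests, deconvolution) need.
    """

    fit: StepSignal
    seg_starts: np.ndarray
    sample_rate: float
    n: int
    method: str
    noise_regime: str
    #: global noise level (homogeneous) — also set in the heterogeneous case
    #: as the all-data estimate
    sigma: float
    #: per-segment noise levels (heterogeneous) or None
    seg_sigma: np.ndarray | None = None
    #: per-segment flag: noise estimate inherited from a neighbor
    seg_sigma_inherited: np.ndarray | None = None
    #: attained multiscale statistic of the fit (nan if sigma == 0)
    statistic: float = float("nan")

    @property
    def seg_ends(self) -> np.ndarray:
        """Inclusive end sample index of each segment."""
        return np.concatenate([self.seg_starts[1:] - 1, [self.n - 1]])


def _grid_times(seg_starts: np.ndarray, fs: float) -> np.ndarray:
    """Grid change times: a change at sample index k stands for a true change
    time in ((k)/fs, (k+1)/fs]; its midpoint (k + 0.5)/fs is the grid
    representative (refined later by local deconvolution)."""
    return (seg_starts[1:] + 0.5) / fs


def _build_fit(
    result: StepFitResult,
    trace: Trace,
    method: str,
    config: MethodConfig,
    sigma: float,
    seg_sigma: np.ndarray | None = None,
    seg_inherit: np.ndarray | None = None,
    statistic: float = float("nan"),
) -> MultiscaleFit:
    fs = trace.sample_rate
    signal = StepSignal(
        change_times=_grid_times(result.seg_starts, fs),
        levels=result.levels,
        start=0.0,
        end=trace.n / fs,
        noise_levels=seg_sigma,
    )
    return MultiscaleFit(
        fit=signal,
        seg_starts=result.seg_starts,
        sample_rate=fs,
        n=trace.n,
        method=method,
        noise_regime=config.noise,
        sigma=sigma,
        seg_sigma=seg_sigma,
        seg_sigma_inherited=seg_inherit,
        statistic=statistic,
    )


def estimate_noise(
    trace: Trace,
    filt: LowpassFilter,
    fit: MultiscaleFit | None = None,
    regime: str = "homogeneous",
) -> float | tuple[np.ndarray, np.ndarray]:
    """Robust difference-based noise-level estimation.

    Homogeneous: lag-(m+1) differences of the whole trace (samples that far
    apart are uncorrelated under the truncated-kernel model, so the difference
    SD is sigma * sqrt(2)), reduced by a median-absolute-deviation scale that
    is insensitive to the conductance jumps and to gross outliers.

    Heterogeneous: the same estimator restricted to each fitted segment with
    the first m (ramp) samples dropped.  Segments too short to carry at least
    two differences get their estimate from the nearest longer neighbor and are
    flagged.

    Returns
    -------
    float (homogeneous) or ``(levels, inherited_flags)`` per segment.
    """
    m = filt.m
    y = trace.values
    lag = m + 1
    if regime == "homogeneous":
        if trace.n < lag + 2:
            raise ValueError("trace too short for noise estimation")
        d = y[lag:] - y[:-lag]
        return float(robust_noise_scale(d))
    if fit is None:
        raise ValueError("heterogeneous noise estimation requires a fit")
    starts, ends = fit.seg_starts, fit.seg_ends
    out = np.full(len(starts), np.nan)
    for i, (a, b) in enumerate(zip(starts, ends)):
        seg = y[a + m : b + 1]
        if seg.size >= lag + 2:
            d = seg[lag:] - seg[:-lag]
            out[i] = robust_noise_scale(d)
    inherited = np.isnan(out)
    if np.all(inherited):
        raise ValueError("no segment long enough for noise estimation")
    if np.any(inherited):
        idx = np.nonzero(~inherited)[0]
        for i in np.nonzero(inherited)[0]:
            out[i] = out[idx[np.argmin(np.abs(idx - i))]]
    return out, inherited


def attained_statistic(
    y: np.ndarray,
    system: IntervalSystem,
    sigma: float | None,
    result: StepFitResult,
) -> float:
    """Maximal standardized residual statistic of the fit over the system."""
    n = system.n
    starts = result.seg_starts
    ends = np.concatenate([starts[1:] - 1, [n - 1]])
    best = -np.inf
    for l, mu, scale in system.scale_stats(y, sigma):
        pen = scale_penalty(n, l)
        for (a, b), c in zip(zip(starts, ends), result.levels):
            if b - a + 1 < l:
                continue
            sl = slice(a, b - l + 2)
            t = np.abs(mu[sl] - c) / (
                scale[sl] if isinstance(scale, np.ndarray) else scale
            )
            if t.size:
                best = max(best, float(np.max(t) - pen))
    return best


def jsmurf(
    trace: Trace,
    filt: LowpassFilter,
    config: MethodConfig,
    store: CritvalStore | None = None,
) -> MultiscaleFit:
    """Multiscale idealization on scales above the filter length.

    Returns the fit with the minimal number of changes such that every system
    interval inside a fitted segment passes the standardized local-mean test
    at the Monte-Carlo-calibrated critical value; the probability that the fit
    contains any false-positive change on model-conform data is bounded
    (approximately) by ``config.alpha``.
    """
    m = filt.m
    if trace.n <= 2 * (m + 1):
        raise ValueError(f"trace too short: need n > 2(m+1) = {2 * (m + 1)}")
    if store is None:
        store = CritvalStore()
    hetero = config.noise == "heterogeneous"
    system = IntervalSystem.for_method(
        trace.n, m, filt.acf, drop_m=True, heterogeneous=hetero
    )
    q = get_critical_value(config, trace.n, filt, store)
    y = trace.values
    sigma_global = estimate_noise(trace, filt, regime="homogeneous")
    result = fit_minimal_steps(y, system, q, None if hetero else sigma_global)

    seg_sigma = seg_inherit = None
    stat = float("nan")
    partial = _build_fit(result, trace, "jsmurf", config, sigma_global)
    if hetero:
        seg_sigma, seg_inherit = estimate_noise(
            trace, filt, fit=partial, regime="heterogeneous"
        )
    if sigma_global > 0:
        stat = attained_statistic(
            y, system, None if hetero else sigma_global, result
        )
    return _build_fit(
        result, trace, "jsmurf", config, sigma_global, seg_sigma, seg_inherit, stat
    )
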