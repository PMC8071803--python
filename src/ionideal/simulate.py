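"""Synthetic traces from the filtered step-signal observation model.

The generator emulates the recording process: a piecewise-constant conductance
f is convolved with the truncated analogue filter kernel, and stationary
colored Gaussian noise (white noise passed through the same kernel) is added,

    Y_i = (F_m * f)(i / f_s) + eps_i,    i = 1..n,

where eps has the filter's autocorrelation rho(0..m) and marginal SD equal to
the configured noise level sigma.  sigma is parameterized as the *post-filter*
marginal SD (rho is normalized to rho(0) = 1), which is what one estimates from
quiet stretches of already-filtered recordings.

Colored noise is produced by a moving-average filter whose m+1 weights come
from spectral factorization of the truncated-kernel band covariance, so the
ACF of the simulated noise matches rho exactly at every lag (not just
asymptotically).

Heterogeneous (e.g. open-channel) noise is supported through per-segment noise
levels on the truth signal; the level switches at the sample straddling each
conductance change (transition samples inherit the right segment's level).
"""

from __future__ import annotations

import numpy as np

from .filters import LowpassFilter, convolve_step_signal
from .signals import StepSignal, Trace

__all__ = ["ma_weights", "simulate_noise", "simulate_trace", "simulate_null"]


def ma_weights(filt: LowpassFilter) -> np.ndarray:
    """MA(m) weights reproducing the filter's noise ACF exactly.

    Finds w_0..w_m with sum_k w_k w_{k+h} = rho(h) for h = 0..m by factoring
    the covariance generating polynomial sum_h rho(|h|) z^{h+m}: its roots come
    in (z, 1/z) pairs, and the minimum-phase factor (roots inside the unit
    circle) yields the weights.
    """
    rho = filt.acf
    m = filt.m
    if m == 0:
        return np.ones(1)
    c = np.concatenate([rho[::-1], rho[1:]])  # lags -m..m
    roots = np.polynomial.polynomial.polyroots(c)
    inside = roots[np.abs(roots) < 1.0]
    if inside.size != m:  # pragma: no cover - guards numerically degenerate input
        raise RuntimeError("spectral factorization failed: roots on unit circle")
    w = np.polynomial.polynomial.polyfromroots(inside).real
    return w / np.sqrt(np.sum(w * w))


def simulate_noise(
    n: int, filt: LowpassFilter, rng: np.random.Generator
) -> np.ndarray:
    """Stationary colored Gaussian noise, unit marginal SD, ACF = filter ACF."""
    w = ma_weights(filt)
    z = rng.standard_normal(n + w.size - 1)
    return np.convolve(z, w, mode="valid")


def _resolve_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_trace(
    truth: StepSignal,
    filt: LowpassFilter,
    n: int,
    sigma: float | None = None,
    seed: int | np.random.Generator = 0,
) -> Trace:
    """Simulate n samples from the observation model.

    Parameters
    ----------
    truth
        The underlying step signal; must span at least n / f_s seconds.
    filt
        The low-pass filter of the virtual measurement device.
    n
        Number of samples; sample i is taken at t_i = i / f_s.
    sigma
        Homogeneous post-filter noise SD (nS).  ``sigma=0`` returns the
        noise-free convolution; ``sigma=None`` requires per-segment
        ``truth.noise_levels`` (heterogeneous regime).
    seed
        Integer seed or a ``numpy.random.Generator``; the output is
        deterministic given the seed.
    """
    fs = filt.sample_rate
    if truth.end < n / fs - 1e-12:
        raise ValueError(
            f"truth spans [{truth.start}, {truth.end}] s but {n} samples at "
            f"{fs} Hz need {n / fs} s"
        )
    times = np.arange(1, n + 1) / fs
    mean = convolve_step_signal(truth, filt, times)
    if sigma is None:
        if truth.noise_levels is None:
            raise ValueError("sigma=None requires truth.noise_levels")
        scale = truth.noise_at(times)
    else:
        if sigma < 0:
            raise ValueError("sigma must be >= 0")
        if sigma == 0.0:
            return Trace(values=mean, sample_rate=fs)
        scale = sigma
    rng = _resolve_rng(seed)
    eps = simulate_noise(n, filt, rng)
    return Trace(values=mean + scale * eps, sample_rate=fs)


def simulate_null(
    n: int, filt: LowpassFilter, seed: int | np.random.Generator = 0
) -> Trace:
    """Pure-noise trace: constant conductance 0, unit noise level.

    Used to calibrate critical values of the detection statistics by Monte
    Carlo simulation.
    """
    rng = _resolve_rng(seed)
    eps = simulate_noise(n, filt, rng)
    return Trace(values=eps, sample_rate=filt.sample_rate)
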