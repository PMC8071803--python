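"""Truncated analogue Bessel low-pass filter kernels.

Patchclamp amplifiers low-pass filter the recorded current in hardware, almost
always with an analogue Bessel filter with an even number of poles.  The
observation model treats the recorded samples as the underlying step signal f
*convolved* with the (truncated) filter kernel F_m plus filtered Gaussian noise.
This module constructs that kernel from the filter's pole set, exposes its step
response and the autocorrelation of filtered-and-sampled white noise, and
convolves step signals with the kernel exactly (as a finite sum of step-response
differences over the jumps of f).

Conventions
-----------
* ``cutoff`` is the normalized cutoff frequency in (0, 0.5), i.e. the fraction
  of the sampling rate at which the magnitude response is -3 dB (the hardware
  convention: a 4-pole Bessel filter at normalized cutoff 0.1 sampled at
  50 kHz has a 5 kHz time-domain cutoff).
* The kernel is causal and supported on ``[0, m / f_s]`` after truncation; no
  zero-phase correction is applied, so a jump at tau produces a ramp occupying
  roughly ``[tau, tau + m/f_s]`` in the convolved signal.
* The truncated kernel is renormalized to unit integral so constants are
  preserved by convolution.

The truncation length m is chosen by the working rule that the autocorrelation
of the *untruncated* analogue kernel is below a threshold (default 1e-3) at all
sample lags >= m; for the 4-pole filter at cutoff 0.1 this gives m = 11.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .signals import StepSignal

__all__ = ["LowpassFilter", "make_filter", "kernel_acf", "convolve_step_signal"]

_SUPPORTED_POLES = (2, 4, 6, 8)


def _bessel_poles_residues(poles: int, cutoff: float):
    """Residues/poles of the analogue Bessel transfer function, time in samples.

    The -3 dB point is placed at angular frequency 2*pi*cutoff (cycles per
    sample), so the impulse response h(t) = sum_i r_i exp(p_i t), t >= 0, is a
    function of time measured in samples.
    """
    b, a = scipy.signal.bessel(poles, 2.0 * np.pi * cutoff, analog=True, norm="mag")
    r, p, k = scipy.signal.residue(b, a)
    if len(k):  # pragma: no cover - cannot happen for all-pole filters
        raise RuntimeError("unexpected direct term in Bessel partial fractions")
    return r, p


def _untruncated_acf(r: np.ndarray, p: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """Normalized ACF of the untruncated kernel at the given sample lags.

    gamma(h) = int_0^inf h(t) h(t+h) dt reduces, with h a sum of exponentials,
    to sum_ij r_i r_j exp(p_j h) / -(p_i + p_j): exact, no quadrature error.
    """
    lags = np.asarray(lags, dtype=float)
    g = np.zeros(lags.shape, dtype=complex)
    for i in range(len(r)):
        for j in range(len(r)):
            g += r[i] * r[j] * np.exp(p[j] * lags) / (-(p[i] + p[j]))
    g0 = 0.0j
    for i in range(len(r)):
        for j in range(len(r)):
            g0 += r[i] * r[j] / (-(p[i] + p[j]))
    return (g / g0).real


def _truncated_autocovariance(
    r: np.ndarray, p: np.ndarray, m: int, lags: np.ndarray
) -> np.ndarray:
    """Autocovariance of the kernel truncated to [0, m] (sample time units).

    gamma_T(h) = int_0^{m-h} h(t) h(t+h) dt, again a closed-form sum of
    exponentials; zero for |h| > m.
    """
    lags = np.asarray(lags, dtype=float)
    g = np.zeros(lags.shape, dtype=complex)
    inside = np.abs(lags) <= m
    h = np.abs(lags[inside])
    acc = np.zeros(h.shape, dtype=complex)
    for i in range(len(r)):
        for j in range(len(r)):
            pij = p[i] + p[j]
            acc += r[i] * r[j] * np.exp(p[j] * h) * (np.exp(pij * (m - h)) - 1.0) / pij
    g[inside] = acc
    return g.real


@dataclass(frozen=True, eq=False)
class LowpassFilter:
    """Truncated analogue low-pass Bessel filter.

    Attributes
    ----------
    kind : str
        Filter family; only ``"bessel"`` is supported.
    poles : int
        Number of poles (even, 2..8).
    cutoff : float
        Normalized -3 dB cutoff frequency, fraction of the sampling rate.
    sample_rate : float
        Sampling rate f_s in Hz.
    m : int
        Truncation length in samples; the kernel is supported on [0, m/f_s].
    acf : np.ndarray
        rho(0..m): normalized autocovariance at integer sample lags of
        continuous-time white noise passed through the truncated kernel and
        sampled at f_s.  rho(0) = 1 and rho(h) = 0 for h > m.
    """

    kind: str
    poles: int
    cutoff: float
    sample_rate: float
    m: int
    acf: np.ndarray = field(repr=False)
    _residues: np.ndarray = field(repr=False)
    _poles_s: np.ndarray = field(repr=False)
    _norm: float = field(repr=False)

    @property
    def cutoff_hz(self) -> float:
        """Time-domain -3 dB cutoff frequency in Hz (cutoff * f_s)."""
        return self.cutoff * self.sample_rate

    @property
    def filter_length(self) -> float:
        """Support of the truncated kernel, m / f_s, in seconds."""
        return self.m / self.sample_rate

    @property
    def fingerprint(self) -> str:
        """Stable identifier of (kind, poles, cutoff, m) for cache keying."""
        return f"{self.kind}-p{self.poles}-c{self.cutoff:.8g}-m{self.m}"

    # -- kernel and responses -----------------------------------------------

    def _step_raw(self, u: np.ndarray) -> np.ndarray:
        """Integral of the untruncated impulse response, time u in samples."""
        u = np.asarray(u, dtype=float)
        out = np.zeros(u.shape, dtype=complex)
        up = np.maximum(u, 0.0)
        for ri, pi in zip(self._residues, self._poles_s):
            out += ri / pi * (np.exp(pi * up) - 1.0)
        return out.real

    def kernel(self, t: np.ndarray | float) -> np.ndarray:
        """Truncated, renormalized kernel density (1/s) at times t (s)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        u = t * self.sample_rate
        if self.m == 0:
            raise ValueError("degenerate m = 0 filter has no density")
        out = np.zeros(u.shape, dtype=complex)
        for ri, pi in zip(self._residues, self._poles_s):
            out += ri * np.exp(pi * u)
        out = out.real * self.sample_rate / self._norm
        out[(u < 0) | (u > self.m)] = 0.0
        return out

    def step_response(self, t: np.ndarray | float) -> np.ndarray:
        """Response to a unit step at time 0, evaluated at times t (seconds).

        Equals 0 for t <= 0 and exactly 1 for t >= m/f_s (the truncated kernel
        is renormalized to unit integral).
        """
        t = np.atleast_1d(np.asarray(t, dtype=float))
        u = t * self.sample_rate
        if self.m == 0:
            return (u > 0).astype(float)
        return self._step_raw(np.clip(u, 0.0, float(self.m))) / self._norm


def make_filter(
    poles: int,
    cutoff: float,
    sample_rate: float,
    acf_threshold: float = 1e-3,
) -> LowpassFilter:
    """Construct a truncated analogue Bessel low-pass filter.

    The truncation length m is the smallest integer such that the ACF of the
    untruncated analogue kernel satisfies ``|rho(h)| < acf_threshold`` for all
    sample lags ``h >= m`` (equivalently m = 1 + the last lag at or above the
    threshold).  For poles=4, cutoff=0.1 and the default threshold this gives
    m = 11.

    Parameters
    ----------
    poles
        Number of filter poles; one of 2, 4, 6, 8.
    cutoff
        Normalized -3 dB cutoff frequency in (0, 0.5).
    sample_rate
        Sampling rate f_s in Hz.
    acf_threshold
        Truncation threshold on the normalized ACF, in (0, 1); default 1e-3.
    """
    if poles not in _SUPPORTED_POLES:
        raise ValueError(f"poles must be one of {_SUPPORTED_POLES}, got {poles}")
    if not 0.0 < cutoff < 0.5:
        raise ValueError("normalized cutoff must be in (0, 0.5)")
    if sample_rate <= 0:
        raise ValueError("sample rate must be positive")
    if not 0.0 < acf_threshold < 1.0:
        raise ValueError("acf_threshold must be in (0, 1)")

    r, p = _bessel_poles_residues(poles, cutoff)

    # scan lags until the ACF envelope has clearly decayed below threshold
    n_lags = 64
    while True:
        lags = np.arange(1, n_lags + 1)
        rho = _untruncated_acf(r, p, lags)
        above = np.nonzero(np.abs(rho) >= acf_threshold)[0]
        # decay is eventually exponential: once the last 1/4 of the window is
        # far below threshold, no later lag can rise above it again
        tail = np.abs(rho[-n_lags // 4 :])
        if np.all(tail < acf_threshold * 1e-3) or n_lags > 1 << 16:
            break
        n_lags *= 2
    m = int(lags[above[-1]]) + 1 if above.size else 0

    if m > 0:
        norm = float(
            np.sum(
                [ri / pi * (np.exp(pi * m) - 1.0) for ri, pi in zip(r, p)]
            ).real
        )
        gam = _truncated_autocovariance(r, p, m, np.arange(m + 1))
        acf = gam / gam[0]
    else:
        norm = 1.0
        acf = np.ones(1)

    return LowpassFilter(
        kind="bessel",
        poles=poles,
        cutoff=float(cutoff),
        sample_rate=float(sample_rate),
        m=m,
        acf=acf,
        _residues=r,
        _poles_s=p,
        _norm=norm,
    )


def kernel_acf(filt: LowpassFilter) -> np.ndarray:
    """rho(0..m) of the truncated kernel (rho(0) = 1).

    This is the autocorrelation of the stationary noise sequence obtained by
    filtering continuous-time white noise with the truncated kernel and
    sampling at f_s; it is the correlation structure all detection statistics
    standardize against.
    """
    return filt.acf.copy()


def untruncated_acf(filt: LowpassFilter, lags: np.ndarray) -> np.ndarray:
    """Normalized ACF of the *untruncated* analogue kernel at sample lags."""
    return _untruncated_acf(filt._residues, filt._poles_s, np.asarray(lags))


@functools.lru_cache(maxsize=4096)
def attenuation_factor(filt: LowpassFilter, l: int, phase_step: float = 0.01) -> float:
    """Windowed mean response of a unit peak of length l samples.

    A peak shorter than the filter length is smoothed so strongly that the
    convolved signal never reaches the peak level; the maximal mean of the
    convolved unit peak over an l-sample window (maximized over the peak's
    sub-sample phase, searched on a ``phase_step``-sample grid) quantifies that
    attenuation.  Local short-event tests divide by this factor so their
    statistic estimates the true (unattenuated) peak amplitude, and
    deconvolution inverts the same smoothing.

    Tends to 1 for l >> m and to 0 as l -> 0.
    """
    if l < 1:
        raise ValueError("peak length must be >= 1 sample")
    dt = 1.0 / filt.sample_rate
    win_t = np.arange(1, l + 1) * dt  # window sample times
    onsets = np.arange(-(filt.m + 1), 1.0 + phase_step / 2, phase_step) * dt
    # response of a unit peak [tau, tau + l*dt) evaluated at the window times
    resp = filt.step_response(
        win_t[None, :] - onsets[:, None]
    ) - filt.step_response(win_t[None, :] - onsets[:, None] - l * dt)
    return float(np.max(resp.mean(axis=1)))


def convolve_step_signal(
    signal: StepSignal,
    filt: LowpassFilter,
    eval_times: np.ndarray | float,
) -> np.ndarray:
    """Evaluate (F_m * f)(t) exactly at the requested times.

    Uses the identity that the convolution of a step function with the kernel
    is the base level plus a sum of step-response differences over the jumps:
    ``(F_m * f)(t) = c_0 + sum_j (c_j - c_{j-1}) R(t - tau_j)`` with R the
    kernel's step response.  No numerical convolution of sampled sequences is
    involved.

    Raises
    ------
    ValueError
        If any evaluation time lies outside ``[start, end]``.
    """
    t = np.atleast_1d(np.asarray(eval_times, dtype=float))
    if t.size and (t.min() < signal.start - 1e-12 or t.max() > signal.end + 1e-12):
        raise ValueError(
            f"evaluation times must lie within [{signal.start}, {signal.end}]"
        )
    out = np.full(t.shape, signal.levels[0], dtype=float)
    jumps = np.diff(signal.levels)
    for tau, dc in zip(signal.change_times, jumps):
        if dc != 0.0:
            out += dc * filt.step_response(t - tau)
    return out
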