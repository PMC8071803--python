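"""Filter-aware, time-continuous local deconvolution of detected events.

Detection places change points on the sampling grid and — for peaks shorter
than the filter length — underestimates their amplitude, because the convolved
signal never reaches the true level (kernel attenuation).  Deconvolution
refines every *isolated* event by least squares against the exact forward
model (the convolved two- or three-level step), with the change times searched
on a continuous grid of resolution (1/100)/f_s via three-stage grid
refinement:

* isolated single change: fit (tau, c_left, c_right);
* isolated peak (two close changes): joint fit (tau1, tau2, c_left, c_mid,
  c_right), which inverts the attenuation;
* clusters of >= 3 closely spaced changes cannot be deconvolved; they are left
  at grid resolution and flagged (``no_deconvolution``), with a warning.

"Isolated" means neighboring events at least 3 filter lengths away
(homogeneous noise) or 5 filter lengths (heterogeneous, where local noise
levels must also be estimable).  In the heterogeneous regime residuals are
weighted by the segment noise levels, transition samples by the right
segment's level.
"""

from __future__ import annotations

import warnings

import numpy as np

from .filters import LowpassFilter
from .segment import MultiscaleFit
from .signals import StepSignal, Trace

__all__ = ["local_deconvolution", "mark_no_deconvolution", "isolation_distance"]


def isolation_distance(filt: LowpassFilter, regime: str) -> int:
    """Minimal separation (samples) between events deconvolvable in isolation:
    3 filter lengths for homogeneous noise, 5 for heterogeneous."""
    factor = 5 if regime == "heterogeneous" else 3
    return factor * filt.m


def _classify(changes: np.ndarray, iso: int) -> list[list[int]]:
    """Group change indices into clusters closer than the isolation distance."""
    groups: list[list[int]] = []
    for j, k in enumerate(changes):
        if groups and k - changes[groups[-1][-1]] < iso:
            groups[-1].append(j)
        else:
            groups.append([j])
    return groups


def _ls_rss(t, y, w, cols):
    """Weighted least squares; returns (coef, rss)."""
    A = np.column_stack(cols)
    if w is not None:
        A = A * w[:, None]
        y = y * w
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return coef, float(resid @ resid)


def _refine_grid(center: float, half: float, step: float) -> np.ndarray:
    return np.arange(center - half, center + half + step / 2, step)


def _fit_single(
    t: np.ndarray,
    y: np.ndarray,
    w: np.ndarray | None,
    filt: LowpassFilter,
    k: int,
) -> tuple[float, float, float, float]:
    """LS fit of a single convolved change near grid index k.

    Returns (tau, c_left, c_right, rss)."""
    dt = 1.0 / filt.sample_rate
    best = None
    # stage 1: coarse grid covering the grid-placement uncertainty; includes
    # the grid representative (k + 0.5) dt so the refined fit can never be
    # worse than the grid-aligned one
    # detection guarantees the grid change within ~m samples of the truth only
    taus = _refine_grid((k + 0.5) * dt, (filt.m + 1.5) * dt, 0.25 * dt)
    for stage, (half, step) in enumerate(
        [(None, None), (0.3, 0.05), (0.06, 0.01)]
    ):
        if stage > 0:
            taus = _refine_grid(best[0], half * dt, step * dt)
        for tau in taus:
            R = filt.step_response(t - tau)
            coef, rss = _ls_rss(t, y, w, [1.0 - R, R])
            if best is None or rss < best[3]:
                best = (float(tau), float(coef[0]), float(coef[1]), rss)
    return best


def _fit_pair(
    t: np.ndarray,
    y: np.ndarray,
    w: np.ndarray | None,
    filt: LowpassFilter,
    k1: int,
    k2: int,
) -> tuple[float, float, float, float, float, float]:
    """Joint LS fit of an isolated peak (two changes near grid k1 < k2).

    Returns (tau1, tau2, c_left, c_mid, c_right, rss)."""
    dt = 1.0 / filt.sample_rate
    m = filt.m
    best = None
    # grid placement of a peak's edges is systematically offset: the falling
    # edge is detected near the convolution maximum (a few samples after the
    # true change for short peaks) or at the overshoot-decay onset (up to ~m
    # samples before it for peaks longer than the filter).  The coarse grid is
    # therefore wide and asymmetric, and refined in two further stages.
    w_half = 0.5 * m + 2.0
    g1 = np.arange((k1 + 0.5 - w_half) * dt, (k1 + 0.5 + 3.5) * dt, 0.25 * dt)
    g2 = np.arange((k2 + 0.5 - w_half) * dt, (k2 + 0.5 + m + 1.5) * dt, 0.25 * dt)
    for stage, (half, step) in enumerate(
        [(None, None), (0.3, 0.05), (0.06, 0.01)]
    ):
        if stage > 0:
            g1 = _refine_grid(best[0], half * dt, step * dt)
            g2 = _refine_grid(best[1], half * dt, step * dt)
        for tau1 in g1:
            R1 = filt.step_response(t - tau1)
            for tau2 in g2:
                if tau2 - tau1 < 0.009 * dt:
                    continue
                R2 = filt.step_response(t - tau2)
                coef, rss = _ls_rss(t, y, w, [1.0 - R1, R1 - R2, R2])
                if best is None or rss < best[5]:
                    best = (
                        float(tau1),
                        float(tau2),
                        float(coef[0]),
                        float(coef[1]),
                        float(coef[2]),
                        rss,
                    )
    return best


def local_deconvolution(
    trace: Trace,
    filt: LowpassFilter,
    fit: MultiscaleFit,
    regime: str | None = None,
) -> StepSignal:
    """Refine the change times and levels of a grid fit by local deconvolution.

    The number of changes is never altered; only times (made time-continuous)
    and levels are updated.  Clusters of three or more changes closer than the
    isolation distance keep their grid values, their interior segments are
    flagged in the result's ``no_deconvolution`` set, and a warning is raised.
    """
    regime = regime or fit.noise_regime
    m = filt.m
    fs = filt.sample_rate
    dt = 1.0 / fs
    y = trace.values
    n = trace.n
    times = trace.times
    iso = isolation_distance(filt, regime)

    changes = fit.seg_starts[1:].astype(int)
    K = len(changes)
    new_times = (changes + 0.5) * dt
    new_levels = fit.fit.levels.copy()
    deconvolved = np.zeros(K, dtype=bool)
    no_deconv: set[int] = set()

    if K == 0:
        return StepSignal(
            change_times=np.array([]),
            levels=new_levels,
            start=0.0,
            end=n / fs,
            noise_levels=fit.seg_sigma,
        )

    groups = _classify(changes, iso)
    seg_sigma = fit.seg_sigma

    def window(prev_k: int, next_k: int) -> np.ndarray:
        # reach to the neighboring events minus a buffer of m samples beyond
        # their transitions: the previous event's ramp occupies
        # [prev_k, prev_k + m], the next one starts at next_k
        lo = max(prev_k + 2 * m + 1, 0)
        hi = min(next_k - m - 1, n - 1)
        return np.arange(lo, hi + 1)

    for gi, group in enumerate(groups):
        prev_k = changes[groups[gi - 1][-1]] if gi > 0 else -n
        next_k = changes[groups[gi + 1][0]] if gi + 1 < len(groups) else 2 * n
        if len(group) == 1:
            j = group[0]
            idx = window(prev_k, next_k)
            w = None
            if regime == "heterogeneous" and seg_sigma is not None:
                sig = np.where(
                    idx < changes[j], seg_sigma[j], seg_sigma[j + 1]
                ).astype(float)
                w = 1.0 / sig
            tau, cl, cr, _ = _fit_single(times[idx], y[idx], w, filt, changes[j])
            new_times[j] = tau
            new_levels[j] = cl
            new_levels[j + 1] = cr
            deconvolved[j] = True
        elif len(group) == 2:
            j1, j2 = group
            idx = window(prev_k, next_k)
            w = None
            if regime == "heterogeneous" and seg_sigma is not None:
                sig = np.where(
                    idx < changes[j1],
                    seg_sigma[j1],
                    np.where(idx < changes[j2], seg_sigma[j1 + 1], seg_sigma[j2 + 1]),
                ).astype(float)
                w = 1.0 / sig
            tau1, tau2, cl, cm, cr, _ = _fit_pair(
                times[idx], y[idx], w, filt, changes[j1], changes[j2]
            )
            new_times[j1], new_times[j2] = tau1, tau2
            new_levels[j1] = cl
            new_levels[j1 + 1] = cm
            new_levels[j2 + 1] = cr
            deconvolved[[j1, j2]] = True
        else:
            # cluster: segments between its first and last change are flagged,
            # grid values kept
            no_deconv.update(range(group[0] + 1, group[-1] + 1))
    if no_deconv:
        warnings.warn(
            "at least one segment could not be deconvolved since two "
            "successive short segments occurred; affected segments are "
            "flagged in no_deconvolution"
        )

    return StepSignal(
        change_times=new_times,
        levels=new_levels,
        start=0.0,
        end=n / fs,
        noise_levels=seg_sigma,
        deconvolved=deconvolved,
        no_deconvolution=frozenset(no_deconv),
    )


def mark_no_deconvolution(
    fit: MultiscaleFit | StepSignal,
    filt: LowpassFilter | None = None,
    regime: str = "homogeneous",
) -> frozenset[int]:
    """Indices of segments inside non-deconvolvable clusters.

    For a deconvolved :class:`StepSignal` this returns the stored flags; for a
    grid :class:`MultiscaleFit` the clusters are computed from the change
    spacing and the isolation distance of the given filter/regime.  Downstream
    export can blank the flagged segments (set their values to NA).
    """
    if isinstance(fit, StepSignal):
        return fit.no_deconvolution
    if filt is None:
        raise ValueError("marking a grid fit requires the filter")
    iso = isolation_distance(filt, regime)
    changes = fit.seg_starts[1:].astype(int)
    flagged: set[int] = set()
    for group in _classify(changes, iso):
        if len(group) >= 3:
            flagged.update(range(group[0] + 1, group[-1] + 1))
    return frozenset(flagged)
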