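"""Downstream analysis of idealizations: histograms, conductance levels,
dwell times.

The idealized conductance levels form a mixture around the true conductance
levels (measurement plus idealization error), so their modes identify the
channel's states.  The half sample mode is used as a robust mode estimator.
Segments are then assigned to states via disjoint conductance intervals —
which also merges consecutive segments assigned to the same state and removes
artifact segments far from every state — and per-state dwell times are
extracted and fitted with (left-truncated) exponential distributions, the
truncation acting as a crude guard against missed short events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .signals import StepSignal, Trace

__all__ = [
    "Histograms",
    "histograms",
    "half_sample_mode",
    "assign_levels",
    "dwell_times",
    "DwellTimeSummary",
]


@dataclass
class Histograms:
    """Raw vectors behind the three standard histograms.

    * ``point_amplitude``: every recorded sample (raw data);
    * ``event``: one entry per fitted segment (its conductance level);
    * ``amplitude``: differences between consecutive segment levels.
    """

    point_amplitude: np.ndarray
    event: np.ndarray
    amplitude: np.ndarray

    def binned(self, which: str, bins=50):
        """``numpy.histogram`` of one of the three vectors."""
        return np.histogram(getattr(self, which), bins=bins)


def histograms(trace: Trace, idealization: StepSignal) -> Histograms:
    """Point-amplitude, event and amplitude histogram data for a fit."""
    if idealization.n_segments < 1:
        raise ValueError("idealization must contain at least one segment")
    levels = idealization.levels
    return Histograms(
        point_amplitude=trace.values.copy(),
        event=levels.copy(),
        amplitude=np.diff(levels),
    )


def half_sample_mode(values: np.ndarray) -> float:
    """Robust mode estimate by the recursive half-sample method.

    Repeatedly keeps the ceil(k/2)-point contiguous window of the sorted
    sample with the smallest range (leftmost on ties) until at most three
    points remain; for three points the mean of the closer pair is returned
    (the middle point on a tie), for fewer their mean.
    """
    x = np.sort(np.asarray(values, dtype=float).ravel())
    if x.size == 0:
        raise ValueError("need at least one value")
    while x.size > 3:
        h = int(np.ceil(x.size / 2))
        ranges = x[h - 1 :] - x[: x.size - h + 1]
        i = int(np.argmin(ranges))
        x = x[i : i + h]
    if x.size == 3:
        d01 = x[1] - x[0]
        d12 = x[2] - x[1]
        if d01 < d12:
            return float((x[0] + x[1]) / 2)
        if d12 < d01:
            return float((x[1] + x[2]) / 2)
        return float(x[1])
    return float(np.mean(x))


def assign_levels(
    idealization: StepSignal,
    level_intervals: list[tuple[float, float, float]],
) -> tuple[StepSignal, np.ndarray]:
    """Map segment levels to discrete conductance states and merge.

    ``level_intervals`` is a list of disjoint ``(low, high, target)`` triples:
    every segment whose fitted level lies in ``[low, high)`` is assigned the
    target conductance; segments outside all intervals (typically artifacts)
    are left unassigned (NaN).  Consecutive segments with the same assigned
    target are merged into one — removing spurious events — so the output
    never has more segments than the input.

    Returns the assigned (merged) signal and the per-output-segment target
    array (NaN marks unassigned segments).
    """
    iv = sorted(level_intervals)
    for (l1, h1, _), (l2, h2, _) in zip(iv, iv[1:]):
        if h1 > l2:
            raise ValueError("level intervals must be disjoint")
        if h1 <= l1 or h2 <= l2:
            raise ValueError("level intervals must be non-empty")

    def target_of(level: float) -> float:
        for lo, hi, t in iv:
            if lo <= level < hi:
                return t
        return np.nan

    targets = np.array([target_of(c) for c in idealization.levels])

    bounds = idealization.boundaries
    keep_t: list[float] = [targets[0]]
    keep_start: list[float] = [bounds[0]]
    for j in range(1, len(targets)):
        same = (
            np.isfinite(targets[j])
            and np.isfinite(keep_t[-1])
            and targets[j] == keep_t[-1]
        )
        if not same:
            keep_t.append(targets[j])
            keep_start.append(bounds[j])
    merged = StepSignal(
        change_times=np.asarray(keep_start[1:]),
        levels=np.asarray(keep_t),
        start=idealization.start,
        end=idealization.end,
    )
    return merged, np.asarray(keep_t)


@dataclass
class DwellTimeSummary:
    """Per-state dwell-time durations and exponential fits."""

    #: state conductance -> array of dwell durations (s); first/last segments
    #: are excluded (their true extent is unknown) as are unassigned segments
    durations: dict[float, np.ndarray]
    #: state conductance -> ML exponential rate (1/s), left-truncated
    rates: dict[float, float]
    #: truncation limit used (s)
    resolution_limit: float
    #: Pearson correlation of consecutive dwell pairs (NaN if < 3 segments)
    lag1_correlation: float = field(default=float("nan"))


def dwell_times(
    assigned: StepSignal,
    resolution_limit: float = 0.0,
) -> DwellTimeSummary:
    """Extract per-state dwell times and fit exponential rates.

    Under a Markov gating model the dwell times in each state are independent
    and exponentially distributed; the maximum-likelihood rate with left
    truncation at the resolution limit t0 is 1 / (mean(d) - t0) over dwells
    d >= t0 (memorylessness), a crude correction for events too short to
    detect.  The lag-1 Pearson correlation of consecutive dwells offers a
    quick check of the independence assumption.
    """
    if assigned.n_segments < 2:
        raise ValueError("need at least two assigned segments")
    levels = assigned.levels
    durs = assigned.durations()
    # interior segments only: the first/last extent is censored by the window
    interior = slice(1, assigned.n_segments - 1) if assigned.n_segments > 2 else slice(0, 0)
    lv = levels[interior]
    du = durs[interior]
    ok = np.isfinite(lv)
    lv, du = lv[ok], du[ok]

    durations: dict[float, np.ndarray] = {}
    rates: dict[float, float] = {}
    for state in np.unique(lv):
        d = du[lv == state]
        durations[float(state)] = d
        d_obs = d[d >= resolution_limit]
        if d_obs.size and np.mean(d_obs) > resolution_limit:
            rates[float(state)] = float(1.0 / (np.mean(d_obs) - resolution_limit))
        else:
            rates[float(state)] = float("nan")

    lag1 = float("nan")
    if du.size >= 3 and np.ptp(du[:-1]) > 0 and np.ptp(du[1:]) > 0:
        lag1 = float(scipy.stats.pearsonr(du[:-1], du[1:])[0])
    return DwellTimeSummary(
        durations=durations,
        rates=rates,
        resolution_limit=resolution_limit,
        lag1_correlation=lag1,
    )
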