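"""Detection of events at and below the filter length.

Two complementary strategies:

* ``jules_detect`` (homogeneous noise): the multiscale criterion is applied to
  *all* temporal scales (dyadic grid down to single samples, no m-sample
  dropping; standardization uses the full noise correlation).  Because the
  convolution ramp of an abrupt change then satisfies the small-scale
  constraints only as a staircase of incremental steps, a postfilter collapses
  every monotone run of closely spaced changes (intermediate segments shorter
  than the filter length) into a single change.

* ``hilde_detect`` (homogeneous or heterogeneous noise): a three-step
  procedure — the above-filter-length detector at level alpha1, then local
  tests for additional short events inside each fitted segment at level
  alpha2, then (downstream) local deconvolution.  The local test compares the
  windowed mean against the segment level, standardized with the kernel
  attenuation factor for a peak of that window length, so a significant window
  directly estimates the *unattenuated* peak amplitude.  Per-scale critical
  values split alpha2 equally across the scale set; the overall probability of
  any false positive is approximately alpha1 + alpha2.
"""

from __future__ import annotations

import warnings

import numpy as np

from .config import MethodConfig
from .critval import CritvalStore, get_critical_value
from .filters import LowpassFilter, attenuation_factor
from .multiscale import (
    IntervalSystem,
    StepFitResult,
    fit_minimal_steps,
    mean_sd_factor,
)
from .segment import MultiscaleFit, _build_fit, attained_statistic, estimate_noise, jsmurf
from .signals import Trace

__all__ = ["jules_detect", "hilde_detect", "postfilter"]


#: ringing cleanup: a change this small relative to an adjacent change within
#: one filter length is a convolution artifact, not an event (the 4-pole
#: Bessel step-response overshoot is below 1%, genuine flickers are comparable
#: in size to their neighbors)
RINGING_TOL = 0.05


def _collapse_monotone(changes: list[int], levels: list[float], m: int) -> bool:
    """One pass of monotone-staircase collapsing; True if anything changed."""
    K = len(changes)
    if K < 2:
        return False
    new_changes: list[int] = []
    new_levels: list[float] = [levels[0]]
    i = 0
    collapsed = False
    while i < K:
        j = i
        diff = levels[j + 1] - levels[j]
        while (
            j + 1 < K
            and changes[j + 1] - changes[j] < m
            and diff != 0.0
            and (levels[j + 2] - levels[j + 1]) * diff > 0
        ):
            j += 1
        if j > i:
            collapsed = True
        new_changes.append(changes[i])
        new_levels.append(levels[j + 1])
        i = j + 1
    changes[:] = new_changes
    levels[:] = new_levels
    return collapsed


def _cleanup_ringing(
    changes: list[int], levels: list[float], m: int, n: int
) -> bool:
    """Remove one residual ringing micro-step, if any; True if removed.

    The filter's step response over- and undershoots by a fraction of a
    percent, which the exact all-scale criterion resolves into tiny extra
    steps right next to a large change.  A change whose amplitude is below
    ``RINGING_TOL`` times that of an adjacent change within m samples is such
    an artifact; it is removed and its two segments merged with
    duration-weighted levels.
    """
    K = len(changes)
    if K < 2:
        return False
    amps = [levels[j + 1] - levels[j] for j in range(K)]
    best_j, best_ratio = -1, RINGING_TOL
    for j in range(K):
        for nb in (j - 1, j + 1):
            # ringing trails the causing change by up to ~2 filter lengths
            if 0 <= nb < K and abs(changes[nb] - changes[j]) < 2 * m and amps[nb] != 0:
                ratio = abs(amps[j]) / abs(amps[nb])
                if ratio < best_ratio:
                    best_j, best_ratio = j, ratio
    if best_j < 0:
        return False
    j = best_j
    bounds = changes + [n]
    left_len = bounds[j] - (changes[j - 1] if j > 0 else 0)
    right_len = bounds[j + 1] - bounds[j]
    merged = (left_len * levels[j] + right_len * levels[j + 1]) / (
        left_len + right_len
    )
    del changes[j]
    del levels[j + 1]
    levels[j] = merged
    return True


def postfilter(result: StepFitResult, m: int, n: int) -> StepFitResult:
    """Remove incremental steps left by the all-scale criterion.

    The convolution ramp of an abrupt change satisfies the exact small-scale
    constraints only as a staircase of monotone incremental steps; any maximal
    run of >= 2 consecutive changes that is monotone in level and whose
    intermediate segments are each shorter than the filter length (m samples)
    is collapsed to a single change at the run's first change.  Residual
    ringing micro-steps (the sub-percent over/undershoot of the Bessel step
    response) are then removed.  Both passes iterate to a fixpoint, so the
    operation is idempotent.  Closely spaced changes of *opposite* sign and
    comparable size (true short peaks) are untouched.
    """
    changes = [int(c) for c in result.seg_starts[1:]]
    levels = [float(c) for c in result.levels]
    while True:
        did = _collapse_monotone(changes, levels, m)
        did = _cleanup_ringing(changes, levels, m, n) or did
        if not did:
            break
    return StepFitResult(
        seg_starts=np.asarray([0] + changes, dtype=int),
        levels=np.asarray(levels),
        n_changes=len(changes),
    )


def jules_detect(
    trace: Trace,
    filt: LowpassFilter,
    config: MethodConfig,
    store: CritvalStore | None = None,
) -> MultiscaleFit:
    """All-scale multiscale idealization with incremental-step postfilter.

    Homogeneous noise only (the all-scale statistic is not studentizable on
    single-sample windows); for heterogeneous noise with short events use
    ``hilde_detect``.
    """
    if config.noise != "homogeneous":
        raise ValueError(
            "jules supports homogeneous noise only; use hilde_detect for "
            "heterogeneous noise"
        )
    if store is None:
        store = CritvalStore()
    m = filt.m
    system = IntervalSystem.for_method(
        trace.n, m, filt.acf, drop_m=False, heterogeneous=False
    )
    cfg = config if config.method == "jules" else config.with_(method="jules")
    q = get_critical_value(cfg, trace.n, filt, store)
    sigma = estimate_noise(trace, filt, regime="homogeneous")
    result = fit_minimal_steps(trace.values, system, q, sigma)
    result = postfilter(result, m, trace.n)
    stat = (
        attained_statistic(trace.values, system, sigma, result)
        if sigma > 0
        else float("nan")
    )
    return _build_fit(result, trace, "jules", cfg, sigma, statistic=stat)


def _merge_same_scale(
    cands: list[tuple[int, float]], l: int, m: int
) -> list[tuple[int, float]]:
    """Merge significant windows of one scale; keep the strongest of each run.

    The convolved response of a single true peak spans roughly its length plus
    the filter length, so significant windows cluster densely; windows that
    overlap or lie within m samples of each other are treated as one event
    (two distinct peaks that close could not be deconvolved anyway)."""
    if not cands:
        return []
    cands = sorted(cands)
    merged = []
    cur_end = cands[0][0] + l
    best_s, best_stat = cands[0]
    for s, stat in cands[1:]:
        if s < cur_end + m:
            cur_end = s + l
            if stat > best_stat:
                best_s, best_stat = s, stat
        else:
            merged.append((best_s, best_stat))
            best_s, best_stat = s, stat
            cur_end = s + l
    merged.append((best_s, best_stat))
    return merged


def hilde_detect(
    trace: Trace,
    filt: LowpassFilter,
    config: MethodConfig,
    store: CritvalStore | None = None,
) -> MultiscaleFit:
    """Two-stage idealization: multiscale stage plus local short-event tests.

    Stage 1 runs the above-filter-length detector at level alpha1
    (homogeneous or heterogeneous).  Stage 2 scans, inside every fitted
    segment, windows of each length l in the scale set; a window whose
    attenuation-corrected standardized mean deviation from the segment level
    exceeds the per-scale critical value becomes a peak candidate (two
    changes, middle level corrected for the kernel attenuation).  Overlapping
    windows of one scale are merged; across scales the smallest significant
    scale wins.  Stage-1 changes are always a subset of the output.
    """
    if store is None:
        store = CritvalStore()
    m = filt.m
    hetero = config.noise == "heterogeneous"
    cfg = config if config.method == "hilde" else config.with_(method="hilde")
    crit = get_critical_value(cfg, trace.n, filt, store)

    stage1_cfg = MethodConfig(
        method="jsmurf",
        noise=cfg.noise,
        alpha=cfg.alpha1,
        r=cfg.r,
        seed=cfg.seed,
    )
    fit1 = jsmurf(trace, filt, stage1_cfg, store)
    if not cfg.scale_set:
        return fit1

    y = trace.values
    cs = np.concatenate(([0.0], np.cumsum(y)))
    att = {l: attenuation_factor(filt, l) for l in cfg.scale_set}
    sdf = {l: mean_sd_factor(l, filt.acf) for l in cfg.scale_set}

    starts, ends = fit1.seg_starts, fit1.seg_ends
    seg_sigma = fit1.seg_sigma if hetero else None
    skipped = False
    # per scale: candidate windows (start, statistic, segment index)
    events: list[tuple[int, int, float, int]] = []  # (s, l, amp-stat, seg)
    per_scale: dict[int, list[tuple[int, float, int]]] = {}
    for seg_i, (a, b) in enumerate(zip(starts, ends)):
        c = fit1.fit.levels[seg_i]
        sig = float(seg_sigma[seg_i]) if hetero else fit1.sigma
        for l in cfg.scale_set:
            lo = a + m
            # windows end at least m clear of the segment's right edge: a
            # late-placed stage-1 boundary would otherwise leak its ramp into
            # trailing windows
            hi = b - l + 1 - m  # last window start
            if hi < lo:
                skipped = True
                continue
            mu = (cs[lo + l : hi + l + 1] - cs[lo : hi + 1]) / l
            stats = np.abs(mu - c) / (att[l] * sig * sdf[l])
            sig_idx = np.nonzero(stats > crit["local"][l])[0]
            for i in sig_idx:
                per_scale.setdefault(l, []).append((lo + int(i), float(stats[i]), seg_i))
    if skipped:
        warnings.warn(
            "some local-test windows were skipped: fitted segments shorter "
            "than m + l exist (consider a smaller l_max)"
        )

    # merge within scale, then across scales (smallest scale wins)
    accepted: list[tuple[int, int, int]] = []  # (s, l, seg)
    for l in sorted(per_scale):
        seg_of = {s: seg for s, _, seg in per_scale[l]}
        merged = _merge_same_scale([(s, st) for s, st, _ in per_scale[l]], l, m)
        for s, _ in merged:
            if all(s + l + m <= s2 or s >= s2 + l2 + m for s2, l2, _ in accepted):
                accepted.append((s, l, seg_of[s]))

    if not accepted:
        return fit1

    # splice accepted peaks into the stage-1 segmentation
    new_starts: list[int] = []
    new_levels: list[float] = []
    by_seg: dict[int, list[tuple[int, int]]] = {}
    for s, l, seg in accepted:
        by_seg.setdefault(seg, []).append((s, l))
    for seg_i, (a, b) in enumerate(zip(starts, ends)):
        c = float(fit1.fit.levels[seg_i])
        new_starts.append(int(a))
        new_levels.append(c)
        for s, l in sorted(by_seg.get(seg_i, [])):
            mu = float((cs[s + l] - cs[s]) / l)
            amp = (mu - c) / att[l]
            new_starts.extend([s, s + l])
            new_levels.extend([c + amp, c])
    # drop empty segments (a peak flush against a segment end leaves none)
    keep = [
        i
        for i in range(len(new_starts))
        if i == len(new_starts) - 1 or new_starts[i] < new_starts[i + 1]
    ]
    result = StepFitResult(
        seg_starts=np.asarray([new_starts[i] for i in keep], dtype=int),
        levels=np.asarray([new_levels[i] for i in keep]),
        n_changes=len(keep) - 1,
    )
    out = _build_fit(
        result, trace, "hilde", cfg, fit1.sigma, statistic=fit1.statistic
    )
    if hetero:
        seg_sig, inherit = estimate_noise(trace, filt, fit=out, regime="heterogeneous")
        out = _build_fit(
            result, trace, "hilde", cfg, fit1.sigma, seg_sig, inherit,
            statistic=fit1.statistic,
        )
    return out
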