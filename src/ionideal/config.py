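"""Method configuration: error levels, Monte-Carlo repetitions, scales, seeds."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = ["MethodConfig"]

_METHODS = ("jsmurf", "jules", "hilde")
_NOISE = ("homogeneous", "heterogeneous")

#: Default Monte-Carlo repetitions per method (the heavier short-event search
#: uses fewer repetitions by default).
DEFAULT_R = {"jsmurf": 10_000, "jules": 10_000, "hilde": 1_000}


@dataclass(frozen=True)
class MethodConfig:
    """Tuning parameters of the idealization methods.

    Parameters
    ----------
    method
        One of ``jsmurf`` (multiscale detection on scales above the filter
        length), ``jules`` (all scales plus postfilter; homogeneous noise
        only), ``hilde`` (jsmurf stage plus filter-aware local tests for short
        events).
    noise
        ``homogeneous`` (one global noise level) or ``heterogeneous``
        (segment-wise noise levels, e.g. open-channel noise).
    alpha
        Error level: the probability of one or more false-positive detections
        on model-conform data is bounded (approximately) by alpha.  For
        ``hilde`` this is derived: alpha = alpha1 + alpha2.
    alpha1, alpha2
        hilde split: alpha1 calibrates the multiscale (jsmurf) stage, alpha2
        the local short-event tests (divided equally across the scale set).
    r
        Monte-Carlo repetitions for critical-value calibration; defaults to
        10,000 for jsmurf/jules and 1,000 for hilde.
    l_max
        Largest local-test scale (samples) for hilde.
    scale_set
        Scales (subset of 1..l_max) actually tested; defaults to all of them.
        Omitting scales saves run time or shifts power to the kept scales.
    seed
        Master seed; all Monte-Carlo streams are derived from it.
    """

    method: str = "jsmurf"
    noise: str = "homogeneous"
    alpha: float = 0.05
    alpha1: float = 0.01
    alpha2: float = 0.04
    r: int | None = None
    l_max: int = 20
    scale_set: tuple[int, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}, got {self.method!r}")
        if self.noise not in _NOISE:
            raise ValueError(f"noise must be one of {_NOISE}, got {self.noise!r}")
        if self.method == "jules" and self.noise == "heterogeneous":
            raise ValueError(
                "jules supports homogeneous noise only; use hilde for "
                "heterogeneous noise with short events"
            )
        if self.method == "hilde":
            object.__setattr__(self, "alpha", self.alpha1 + self.alpha2)
        for name in ("alpha", "alpha1", "alpha2"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.r is None:
            object.__setattr__(self, "r", DEFAULT_R[self.method])
        if self.r < 1:
            raise ValueError("r must be a positive integer")
        if self.l_max < 1:
            raise ValueError("l_max must be a positive integer")
        if self.scale_set is None:
            object.__setattr__(self, "scale_set", tuple(range(1, self.l_max + 1)))
        else:
            ss = tuple(sorted(set(int(s) for s in self.scale_set)))
            if ss and not all(1 <= s <= self.l_max for s in ss):
                raise ValueError("scale_set must be a subset of 1..l_max")
            object.__setattr__(self, "scale_set", ss)

    def with_(self, **kwargs) -> "MethodConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)
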