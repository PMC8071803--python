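"""In-memory containers: piecewise-constant conductance signals and sampled traces.

A :class:`StepSignal` represents the underlying conductance f as a right-continuous
step function on ``[start, end)``: K change times ``tau_1 < ... < tau_K`` and K+1
levels ``c_0, ..., c_K``, with segment j occupying the half-open interval
``[tau_j, tau_{j+1})``.  Optionally a per-segment noise level ``s_j > 0`` models
heterogeneous (e.g. open-channel) noise that may jump only where the conductance
jumps.

A :class:`Trace` holds equidistant samples ``Y_1..Y_n`` recorded at rate ``f_s``,
with implicit sample times ``t_i = i / f_s``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StepSignal", "Trace"]


@dataclass
class StepSignal:
    """Piecewise-constant conductance (and optionally noise-level) signal.

    Parameters
    ----------
    change_times
        Strictly increasing change times tau_1..tau_K in seconds, all inside
        ``(start, end)``.  May be empty (constant signal).
    levels
        Conductance levels c_0..c_K in nS; one more than there are changes.
    start, end
        Support of the signal; segments partition ``[start, end)``.
    noise_levels
        Optional per-segment noise SDs s_0..s_K (nS), all positive.
    deconvolved
        Per-change flag: True where the change time/levels were refined by
        time-continuous local deconvolution rather than left on the sampling grid.
    no_deconvolution
        Indices of segments inside clusters of >= 3 close changes that could not
        be deconvolved (see the deconvolve module).
    """

    change_times: np.ndarray
    levels: np.ndarray
    start: float = 0.0
    end: float = 1.0
    noise_levels: np.ndarray | None = None
    deconvolved: np.ndarray | None = None
    no_deconvolution: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.change_times = np.asarray(self.change_times, dtype=float)
        self.levels = np.asarray(self.levels, dtype=float)
        if self.levels.size != self.change_times.size + 1:
            raise ValueError(
                f"need #levels = #changes + 1, got {self.levels.size} levels "
                f"for {self.change_times.size} changes"
            )
        if self.change_times.size and np.any(np.diff(self.change_times) <= 0):
            raise ValueError("change times must be strictly increasing")
        if not (self.start < self.end):
            raise ValueError("need start < end")
        if self.change_times.size and (
            self.change_times[0] <= self.start or self.change_times[-1] >= self.end
        ):
            raise ValueError("change times must lie strictly inside (start, end)")
        if self.noise_levels is not None:
            self.noise_levels = np.asarray(self.noise_levels, dtype=float)
            if self.noise_levels.size != self.levels.size:
                raise ValueError("noise_levels must have one entry per segment")
            if np.any(self.noise_levels <= 0):
                raise ValueError("noise levels must be positive")
        if self.deconvolved is None:
            self.deconvolved = np.zeros(self.change_times.size, dtype=bool)
        else:
            self.deconvolved = np.asarray(self.deconvolved, dtype=bool)

    # -- segment bookkeeping -------------------------------------------------

    @property
    def n_changes(self) -> int:
        return int(self.change_times.size)

    @property
    def n_segments(self) -> int:
        return int(self.levels.size)

    @property
    def boundaries(self) -> np.ndarray:
        """All segment boundaries: start, tau_1..tau_K, end."""
        return np.concatenate(([self.start], self.change_times, [self.end]))

    def segment_index(self, t: np.ndarray | float) -> np.ndarray:
        """Index of the segment containing each time (end maps to the last one)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.change_times, t, side="right")
        return idx

    def level_at(self, t: np.ndarray | float) -> np.ndarray:
        """Evaluate f(t); the signal is extended by c_0 / c_K outside its support."""
        return self.levels[self.segment_index(t)]

    def noise_at(self, t: np.ndarray | float) -> np.ndarray:
        """Evaluate sigma(t); requires heterogeneous noise levels."""
        if self.noise_levels is None:
            raise ValueError("signal has no per-segment noise levels")
        return self.noise_levels[self.segment_index(t)]

    def durations(self) -> np.ndarray:
        """Per-segment durations in seconds."""
        return np.diff(self.boundaries)


@dataclass
class Trace:
    """Equidistantly sampled conductance recording.

    Sample i (1-based) is taken at ``t_i = i / sample_rate`` seconds.
    """

    values: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("trace must be a non-empty 1-d array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")
        if self.sample_rate <= 0:
            raise ValueError("sample rate must be positive")

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def times(self) -> np.ndarray:
        """Sample times t_i = i / f_s, i = 1..n."""
        return np.arange(1, self.n + 1) / self.sample_rate

    @property
    def duration(self) -> float:
        return self.n / self.sample_rate
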