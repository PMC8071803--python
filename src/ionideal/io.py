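"""Reading traces and writing idealizations (CSV; ABF delegated to pyabf).

CSV dialect: comma separator, dot decimal, header row, UTF-8; times in
seconds, conductance in nS.  Idealization files use half-open segments
``[leftEnd, rightEnd)``.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .signals import StepSignal, Trace

__all__ = ["read_trace", "write_idealization", "read_idealization"]

#: maximal relative deviation of time steps tolerated as "equidistant"
EQUIDISTANCE_RTOL = 1e-6


def _check_equidistant(t: np.ndarray) -> float:
    dt = np.diff(t)
    step = float(np.median(dt))
    if step <= 0:
        raise ValueError("time column must be strictly increasing")
    bad = np.nonzero(np.abs(dt - step) > EQUIDISTANCE_RTOL * step)[0]
    if bad.size:
        raise ValueError(
            f"trace is not equidistantly sampled: time step {dt[bad[0]]:g} s at "
            f"row {bad[0] + 1} deviates from the median step {step:g} s"
        )
    return 1.0 / step


def read_trace(
    path: str | Path,
    format: str = "csv",
    as_conductance: bool = True,
    channels: tuple[int, int] | None = None,
) -> Trace:
    """Read an equidistantly sampled conductance trace.

    CSV: two numeric columns (time [s], conductance [nS]) or three columns
    (time, current [pA], voltage [mV]) which are converted to conductance
    current/voltage (pA/mV = nS) when ``as_conductance`` is set.  Equidistant
    sampling is validated to a relative tolerance of 1e-6 of the step.

    ABF: delegated to the optional ``pyabf`` reader; ``channels`` selects the
    (current, voltage) channel indices explicitly.
    """
    if format == "abf":
        return _read_abf(path, as_conductance, channels)
    if format != "csv":
        raise ValueError(f"unknown format {format!r}")
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("trace csv needs >= 2 numeric columns (time, conductance)")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    fs = _check_equidistant(t)
    if df.shape[1] >= 3 and as_conductance:
        current = df.iloc[:, 1].to_numpy(dtype=float)
        voltage = df.iloc[:, 2].to_numpy(dtype=float)
        values = current / voltage
    else:
        values = df.iloc[:, 1].to_numpy(dtype=float)
    return Trace(values=values, sample_rate=fs)


def _read_abf(path, as_conductance, channels):  # pragma: no cover - optional dep
    try:
        import pyabf
    except ImportError as exc:
        raise ImportError(
            "reading Axon Binary Format files requires the optional 'pyabf' "
            "package: pip install pyabf (or export the recording as CSV)"
        ) from exc
    abf = pyabf.ABF(str(path))
    if channels is None:
        raise ValueError(
            "ABF channel conventions vary by rig; pass channels=(current_idx, "
            "voltage_idx) explicitly (or channels=(signal_idx, -1) for a "
            "single already-converted channel)"
        )
    ci, vi = channels
    abf.setSweep(0, channel=ci)
    cur = np.asarray(abf.sweepY, dtype=float)
    fs = float(abf.dataRate)
    if vi < 0 or not as_conductance:
        return Trace(values=cur, sample_rate=fs)
    abf.setSweep(0, channel=vi)
    volt = np.asarray(abf.sweepY, dtype=float)
    return Trace(values=cur / volt, sample_rate=fs)


def write_idealization(
    idealization: StepSignal,
    path: str | Path,
    keep_boundary: bool = False,
    no_deconvolution_as_missing: bool = False,
) -> pd.DataFrame:
    """Write an idealization as CSV (leftEnd, rightEnd, value, ...).

    By default the first and last segments are dropped, since their true start
    and end cannot be identified from the data; ``keep_boundary`` keeps them.
    With ``no_deconvolution_as_missing`` the values of segments flagged as
    non-deconvolvable are blanked (NA).  Returns the written frame.
    """
    bounds = idealization.boundaries
    df = pd.DataFrame(
        {
            "leftEnd": bounds[:-1],
            "rightEnd": bounds[1:],
            "value": idealization.levels,
        }
    )
    if idealization.noise_levels is not None:
        df["noiseLevel"] = idealization.noise_levels
    if idealization.deconvolved is not None and idealization.n_changes:
        dec = np.asarray(idealization.deconvolved, dtype=bool)
        # a segment counts as deconvolved if both its boundaries are refined
        seg_dec = np.concatenate(([dec[0]], dec[:-1] & dec[1:], [dec[-1]]))
        df["deconvolved"] = seg_dec
    if no_deconvolution_as_missing and idealization.no_deconvolution:
        idx = sorted(idealization.no_deconvolution)
        df.loc[idx, "value"] = np.nan
    if not keep_boundary:
        if len(df) < 3:
            warnings.warn(
                "fewer than 3 segments: dropping first and last leaves no "
                "rows; writing an empty table"
            )
        df = df.iloc[1:-1]
    df.to_csv(path, index=False)
    return df


def read_idealization(path: str | Path) -> StepSignal:
    """Read an idealization CSV back into a :class:`StepSignal`.

    Round-trips values written by :func:`write_idealization` exactly (to
    floating-point precision); requires contiguous segments.
    """
    df = pd.read_csv(path)
    if len(df) == 0:
        raise ValueError("idealization file contains no segments")
    left = df["leftEnd"].to_numpy(dtype=float)
    right = df["rightEnd"].to_numpy(dtype=float)
    if not np.allclose(left[1:], right[:-1], rtol=0, atol=1e-12):
        raise ValueError("segments must be contiguous")
    return StepSignal(
        change_times=left[1:],
        levels=df["value"].to_numpy(dtype=float),
        start=float(left[0]),
        end=float(right[-1]),
        noise_levels=(
            df["noiseLevel"].to_numpy(dtype=float) if "noiseLevel" in df else None
        ),
    )
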