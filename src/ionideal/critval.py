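"""Monte-Carlo calibration of critical values, with persistent caching.

Every detection statistic's null distribution depends on the trace length, the
filter and the interval/scale system, so critical values are obtained by
simulating r pure-noise traces (unit noise level — the statistics are
standardized, so one simulation serves all noise levels), evaluating the
statistic on each, and taking empirical quantiles.  These simulations can take
minutes, so the sorted null samples are cached, keyed by
(statistic family, n, filter fingerprint, scale set, r), and any error level
alpha can be answered from the stored sample without re-simulation.

Quantiles use the conservative "higher" empirical rule; alpha = 1 returns the
sample minimum (everything is significant), alpha -> 0 the maximum.
"""

from __future__ import annotations

import json
import warnings
import zlib
from pathlib import Path

import numpy as np

from .config import MethodConfig
from .filters import LowpassFilter, attenuation_factor
from .multiscale import (
    IntervalSystem,
    max_null_statistic,
    mean_sd_factor,
    robust_noise_scale,
)
from .simulate import simulate_null

__all__ = ["CritvalStore", "get_critical_value"]

MIN_REPETITIONS = 100


def _key_dict(
    family: str, n: int, filt: LowpassFilter, scales: tuple[int, ...], r: int
) -> dict:
    return {
        "family": family,
        "n": int(n),
        "filter": filt.fingerprint,
        "scales": ",".join(str(s) for s in scales),
        "r": int(r),
    }


def _key_id(key: dict) -> str:
    blob = json.dumps(key, sort_keys=True)
    return f"{zlib.crc32(blob.encode()):08x}"


class CritvalStore:
    """Cache of simulated null-statistic samples.

    In-memory always; if ``path`` is given, each entry is additionally stored
    as a small self-describing JSON file (key fields + version + the sorted
    sample), so repeated analyses with the same parameters simulate only once.
    """

    VERSION = 1

    def __init__(self, path: str | Path | None = None):
        self.path = Path(path) if path is not None else None
        if self.path is not None:
            self.path.mkdir(parents=True, exist_ok=True)
        self._mem: dict[str, np.ndarray] = {}

    def _file(self, key: dict) -> Path | None:
        if self.path is None:
            return None
        return self.path / f"critval-{_key_id(key)}.json"

    def get(self, key: dict) -> np.ndarray | None:
        kid = _key_id(key)
        if kid in self._mem:
            return self._mem[kid]
        f = self._file(key)
        if f is None or not f.exists():
            return None
        try:
            payload = json.loads(f.read_text())
            if payload.get("version") != self.VERSION or payload.get("key") != key:
                raise ValueError("stale or mismatched cache entry")
            sample = np.asarray(payload["sample"], dtype=float)
        except (ValueError, KeyError, json.JSONDecodeError) as exc:
            warnings.warn(
                f"corrupted critical-value cache entry {f.name} ({exc}); "
                "re-simulating"
            )
            return None
        self._mem[kid] = sample
        return sample

    def put(self, key: dict, sample: np.ndarray) -> None:
        self._mem[_key_id(key)] = sample
        f = self._file(key)
        if f is not None:
            payload = {
                "version": self.VERSION,
                "key": key,
                "sample": sample.tolist(),
            }
            f.write_text(json.dumps(payload))


def _null_rngs(seed: int, key: dict, r: int) -> list[np.random.Generator]:
    """One independent, reproducible stream per Monte-Carlo repetition."""
    kid = zlib.crc32(json.dumps(key, sort_keys=True).encode()) & 0x7FFFFFFF
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, kid])
    return [np.random.default_rng(child) for child in ss.spawn(r)]


def _simulate_sample(
    key: dict,
    n: int,
    filt: LowpassFilter,
    config: MethodConfig,
    messages: int | None,
) -> np.ndarray:
    """Simulate the null-statistic sample for one cache key."""
    family = key["family"]
    r = key["r"]
    m = filt.m
    rngs = _null_rngs(config.seed, key, r)

    if family in ("jsmurf-hom", "jsmurf-het", "jules"):
        system = IntervalSystem.for_method(
            n,
            m,
            filt.acf,
            drop_m=family.startswith("jsmurf"),
            heterogeneous=family.endswith("het"),
        )
        out = np.empty(r)
        for i, rng in enumerate(rngs):
            y = simulate_null(n, filt, rng).values
            sigma = (
                None
                if system.heterogeneous
                else float(robust_noise_scale(y[m + 1 :] - y[: -(m + 1)]))
            )
            out[i] = max_null_statistic(y, system, sigma)
            if messages and (i + 1) % messages == 0:
                print(f"critval [{family}]: {i + 1}/{r} repetitions")
        return np.sort(out)

    if family == "hilde-local":
        scales = tuple(int(s) for s in key["scales"].split(",") if s)
        att = np.array([attenuation_factor(filt, l) for l in scales])
        sdf = np.array([mean_sd_factor(l, filt.acf) for l in scales])
        out = np.empty((r, len(scales)))
        for i, rng in enumerate(rngs):
            y = simulate_null(n, filt, rng).values
            sigma = float(robust_noise_scale(y[m + 1 :] - y[: -(m + 1)]))
            c = float(np.mean(y[m:]))
            cs = np.concatenate(([0.0], np.cumsum(y)))
            for j, l in enumerate(scales):
                mu = (cs[l:] - cs[:-l]) / l  # all windows [s, s+l)
                mu = mu[m:]  # windows starting after the segment ramp
                out[i, j] = np.max(np.abs(mu - c)) / (att[j] * sigma * sdf[j])
            if messages and (i + 1) % messages == 0:
                print(f"critval [hilde-local]: {i + 1}/{r} repetitions")
        return np.sort(out, axis=0)

    raise ValueError(f"unknown statistic family {family!r}")


def _ensure_sample(
    family: str,
    n: int,
    filt: LowpassFilter,
    scales: tuple[int, ...],
    config: MethodConfig,
    store: CritvalStore,
    messages: int | None,
) -> np.ndarray:
    key = _key_dict(family, n, filt, scales, config.r)
    sample = store.get(key)
    if sample is None:
        sample = _simulate_sample(key, n, filt, config, messages)
        store.put(key, sample)
    return sample


def _quantile_higher(sample: np.ndarray, level: float) -> float:
    return float(np.quantile(sample, level, method="higher"))


def get_critical_value(
    config: MethodConfig,
    n: int,
    filt: LowpassFilter,
    store: CritvalStore | None = None,
    messages: int | None = None,
):
    """Critical value(s) for the configured method at trace length n.

    Returns a float for ``jsmurf``/``jules``.  For ``hilde`` returns a dict
    ``{"stage1": q1, "local": {l: q_l}}``: alpha1 calibrates the multiscale
    stage and alpha2, divided equally across the scale set (Bonferroni within
    the local tests), the per-scale local critical values.

    Deterministic given ``config.seed`` and the cache key; results are cached
    in ``store`` so each Monte-Carlo simulation runs once.
    """
    if config.r < MIN_REPETITIONS:
        raise ValueError(
            f"r = {config.r} Monte-Carlo repetitions give too large a "
            f"statistical error; need r >= {MIN_REPETITIONS}"
        )
    if store is None:
        store = CritvalStore()
    suffix = "het" if config.noise == "heterogeneous" else "hom"

    if config.method in ("jsmurf", "jules"):
        family = "jules" if config.method == "jules" else f"jsmurf-{suffix}"
        sample = _ensure_sample(family, n, filt, (), config, store, messages)
        return _quantile_higher(sample, 1.0 - config.alpha)

    # hilde: stage-1 jsmurf statistic at alpha1, local tests at alpha2
    stage1_sample = _ensure_sample(
        f"jsmurf-{suffix}", n, filt, (), config, store, messages
    )
    q1 = _quantile_higher(stage1_sample, 1.0 - config.alpha1)
    local: dict[int, float] = {}
    scales = config.scale_set
    if scales:
        sample = _ensure_sample(
            "hilde-local", n, filt, scales, config, store, messages
        )
        level = 1.0 - config.alpha2 / len(scales)
        for j, l in enumerate(scales):
            local[int(l)] = _quantile_higher(sample[:, j], level)
    return {"stage1": q1, "local": local}
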