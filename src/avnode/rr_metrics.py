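"""RR-series characteristics: mean, RMSSD and sample entropy, with
ectopic-interval exclusion and sliding-window trends.

An :class:`RRSeries` pairs the interval values (ms) with a per-interval
validity mask; intervals adjacent to an ectopic beat are marked invalid
and are skipped by every metric.  Sample entropy uses template length
``m`` and tolerance ``r`` times the sample standard deviation of the
series under evaluation (windowed trends use the window's own std), with
a strict ``<`` comparison; templates containing any invalid interval are
omitted from the counts at that template length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "RRSeries",
    "MetricConfig",
    "TrendSeries",
    "SampleEntropyUndefined",
    "rr_mean",
    "rr_rmssd",
    "rr_sample_entropy",
    "mask_ectopic",
    "sliding_trend",
]


class SampleEntropyUndefined(ValueError):
    """Sample entropy cannot be computed (zero variance or no template matches)."""


@dataclass
class RRSeries:
    """RR intervals (ms) with a validity mask (True = usable)."""

    intervals: np.ndarray
    valid: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        x = np.asarray(self.intervals, dtype=np.float64)
        if x.ndim != 1:
            raise ValueError("intervals must be one-dimensional")
        if np.any(x <= 0):
            raise ValueError("RR intervals must be > 0")
        if self.valid is None:
            v = np.ones(x.size, dtype=bool)
        else:
            v = np.asarray(self.valid, dtype=bool)
            if v.shape != x.shape:
                raise ValueError("valid mask must match intervals in length")
        self.intervals = x
        self.valid = v

    def __len__(self) -> int:
        return self.intervals.size

    @classmethod
    def from_beat_times(cls, beat_times_ms) -> "RRSeries":
        t = np.asarray(beat_times_ms, dtype=np.float64)
        return cls(np.diff(t))


@dataclass(frozen=True)
class MetricConfig:
    """Sample-entropy template length/tolerance and trend window lengths."""

    m: int = 2
    r: float = 0.2
    window_mean: int = 100
    window_var: int = 200

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not self.r > 0:
            raise ValueError("r must be > 0")
        if self.window_mean < self.m + 2 or self.window_var < self.m + 2:
            raise ValueError("windows must be >= m + 2")


@dataclass
class TrendSeries:
    """Sliding-window metric values timestamped (s) at each window's last beat."""

    time_s: np.ndarray
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=np.float64)
        v = np.asarray(self.values, dtype=np.float64)
        if t.shape != v.shape:
            raise ValueError("time and value arrays must match in length")
        if t.size > 1 and np.any(np.diff(t) < 0):
            raise ValueError("timestamps must be non-decreasing")
        self.time_s = t
        self.values = v


def rr_mean(rr: RRSeries) -> float:
    """Arithmetic mean (ms) over valid intervals."""
    x = rr.intervals[rr.valid]
    if x.size == 0:
        raise ValueError("no valid RR intervals")
    return float(np.mean(x))


def rr_rmssd(rr: RRSeries) -> float:
    """Root mean square of successive differences (ms).

    Differences spanning an invalid interval are omitted.
    """
    x = rr.intervals
    pair_ok = rr.valid[:-1] & rr.valid[1:]
    if not np.any(pair_ok):
        raise ValueError("no valid successive RR interval pair")
    d = np.diff(x)[pair_ok]
    return float(np.sqrt(np.mean(d * d)))


@njit(cache=True)
def _sampen_counts(x, valid, m, tol):
    """Ordered template-pair match counts (B_m, B_{m+1}).

    Both counts run over template start indices i = 0 .. n-m-1, so the
    (m+1)-length template exists for every counted index.  A template is
    omitted (at a given length) if it contains any invalid interval.
    Matching uses Chebyshev distance strictly below ``tol``.
    """
    n = x.shape[0]
    nt = n - m
    bm = 0
    bm1 = 0
    for i in range(nt):
        vi = True
        for k in range(m):
            if not valid[i + k]:
                vi = False
                break
        if not vi:
            continue
        vi1 = valid[i + m]
        for j in range(i + 1, nt):
            vj = True
            for k in range(m):
                if not valid[j + k]:
                    vj = False
                    break
            if not vj:
                continue
            dmax = 0.0
            for k in range(m):
                d = abs(x[i + k] - x[j + k])
                if d > dmax:
                    dmax = d
            if dmax < tol:
                bm += 2  # ordered pairs (i, j) and (j, i)
                if vi1 and valid[j + m]:
                    d = abs(x[i + m] - x[j + m])
                    if d > dmax:
                        dmax = d
                    if dmax < tol:
                        bm1 += 2
    return bm, bm1


def _sample_std(x: np.ndarray) -> float:
    if x.size < 2:
        return 0.0
    return float(np.std(x, ddof=1))


def rr_sample_entropy(rr: RRSeries, cfg: MetricConfig = MetricConfig()) -> float:
    """Sample entropy ``-ln(B_{m+1} / B_m)`` of the RR series.

    Raises :class:`SampleEntropyUndefined` when the series has zero
    variance or when there are no template matches at either length.
    """
    x = rr.intervals
    if x.size < cfg.m + 2:
        raise ValueError(f"need at least m + 2 = {cfg.m + 2} intervals")
    std = _sample_std(x[rr.valid])
    if std <= 0.0:
        raise SampleEntropyUndefined("series standard deviation is zero")
    tol = cfg.r * std
    bm, bm1 = _sampen_counts(x, rr.valid.astype(np.uint8), cfg.m, tol)
    if bm == 0:
        raise SampleEntropyUndefined("no template matches at length m")
    if bm1 == 0:
        raise SampleEntropyUndefined("no template matches at length m + 1")
    return float(-math.log(bm1 / bm))


def mask_ectopic(rr: RRSeries, ectopic_beat_flags) -> RRSeries:
    """Invalidate the intervals immediately before and after flagged beats.

    ``ectopic_beat_flags`` is indexed by beat (length = n_intervals + 1);
    interval ``i`` lies between beats ``i`` and ``i + 1``.
    """
    flags = np.asarray(ectopic_beat_flags, dtype=bool)
    n = len(rr)
    if flags.size != n + 1:
        raise ValueError(
            f"expected {n + 1} beat flags for {n} intervals, got {flags.size}"
        )
    valid = rr.valid.copy()
    for b in np.flatnonzero(flags):
        if b - 1 >= 0:
            valid[b - 1] = False
        if b < n:
            valid[b] = False
    return RRSeries(rr.intervals, valid)


@njit(cache=True)
def _sliding_sampen(x, valid, N, m, r):
    L = x.shape[0]
    nw = L - N + 1
    out = np.empty(nw, np.float64)
    for w in range(nw):
        # window sample std over valid intervals (ddof=1)
        cnt = 0
        s = 0.0
        for i in range(w, w + N):
            if valid[i]:
                cnt += 1
                s += x[i]
        if cnt < 2:
            out[w] = np.nan
            continue
        mean = s / cnt
        ss = 0.0
        for i in range(w, w + N):
            if valid[i]:
                ss += (x[i] - mean) ** 2
        std = np.sqrt(ss / (cnt - 1))
        if std <= 0.0:
            out[w] = np.nan
            continue
        bm, bm1 = _sampen_counts(x[w:w + N], valid[w:w + N], m, r * std)
        if bm == 0 or bm1 == 0:
            out[w] = np.nan
        else:
            out[w] = -np.log(bm1 / bm)
    return out


def sliding_trend(
    rr: RRSeries,
    beat_times_s,
    metric: str,
    window: int,
    cfg: MetricConfig = MetricConfig(),
) -> TrendSeries:
    """Trailing-window trend of a metric, one step per beat.

    ``beat_times_s`` gives the time (s) of each interval's closing beat;
    window ``i`` covers intervals ``i - window + 1 .. i`` and is
    timestamped at ``beat_times_s[i]``.  ``metric`` is one of ``"mean"``,
    ``"rmssd"``, ``"sampen"``.  Windows where sample entropy is undefined
    yield NaN rather than aborting the trend.
    """
    t = np.asarray(beat_times_s, dtype=np.float64)
    x = rr.intervals
    if t.shape != x.shape:
        raise ValueError("beat_times_s must have one entry per interval")
    N = int(window)
    if N > x.size:
        raise ValueError(f"window {N} exceeds series length {x.size}")
    v = rr.valid
    if metric == "mean":
        cv = np.concatenate(([0.0], np.cumsum(x * v)))
        cn = np.concatenate(([0], np.cumsum(v.astype(np.int64))))
        nums = cv[N:] - cv[:-N]
        cnts = cn[N:] - cn[:-N]
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(cnts > 0, nums / np.maximum(cnts, 1), np.nan)
    elif metric == "rmssd":
        d = np.diff(x)
        ok = (v[:-1] & v[1:]).astype(np.float64)
        cd = np.concatenate(([0.0], np.cumsum(d * d * ok)))
        cn = np.concatenate(([0.0], np.cumsum(ok)))
        # window i uses the N-1 successive differences inside the window
        nums = cd[N - 1:] - cd[:-(N - 1)] if N > 1 else np.zeros(x.size)
        cnts = cn[N - 1:] - cn[:-(N - 1)] if N > 1 else np.zeros(x.size)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(cnts > 0, np.sqrt(nums / np.maximum(cnts, 1)), np.nan)
    elif metric == "sampen":
        if N < cfg.m + 2:
            raise ValueError("window must be >= m + 2 for sample entropy")
        vals = _sliding_sampen(x, v.astype(np.uint8), N, cfg.m, cfg.r)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return TrendSeries(time_s=t[N - 1:], values=vals, name=metric)
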