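"""Fictive-swim bout detection, vigor, swim frequency, and eye kinematics.

The ventral-root (or tail) trace is reduced to a moving-standard-deviation
envelope; supra-threshold runs separated by less than the merge gap (100 ms
by default, strict inequality) form a single bout. Vigor is the 50-ms
rolling-SD envelope of the tail trace, median-filtered to extend vigor
information across whole bouts. The fictive swim frequency is the first
significant positive peak of the autocorrelation of the binarized in-bout
envelope.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage, signal
from sklearn.base import BaseEstimator

from .core import TimeSeries, BoutTable

__all__ = ["envelope", "detect_bouts", "BoutDetector", "vigor",
           "swim_frequency", "eye_kinematics", "rest_threshold"]


def envelope(trace: TimeSeries, sd_window: float = 0.010) -> TimeSeries:
    """Centered rolling standard deviation (population SD, shrink-to-valid
    at the boundaries), same length as the input."""
    w = int(round(sd_window * trace.rate))
    if w < 2:
        raise ValueError("window must span at least 2 samples")
    if w > trace.n:
        raise ValueError("window longer than trace")
    s = pd.Series(trace.data)
    env = s.rolling(w, center=True, min_periods=2).std(ddof=0)
    env = env.bfill().ffill()
    return TimeSeries(env.to_numpy(), trace.rate, trace.t0)


def rest_threshold(env: TimeSeries, k: float = 3.0) -> float:
    """Default binarization threshold: ``k`` times the envelope median
    (the median is dominated by rest periods)."""
    return k * float(np.median(env.data))


def _merge_runs(runs: list[tuple[float, float]], merge_gap: float) -> list[tuple[float, float]]:
    """Merge intervals whose gap is strictly less than ``merge_gap``.

    Gaps exactly equal to the merge gap stay split (1-ns float tolerance).
    """
    if not runs:
        return []
    merged = [list(runs[0])]
    for a, b in runs[1:]:
        if a - merged[-1][1] < merge_gap - 1e-9:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [tuple(r) for r in merged]


def detect_bouts(env: TimeSeries, threshold: float, merge_gap: float = 0.100,
                 min_duration: float = 0.0,
                 vigor_median_window: float = 0.200) -> BoutTable:
    """Supra-threshold runs of the envelope, merged across gaps shorter than
    ``merge_gap``; per-bout vigor summaries from the median-filtered envelope."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    x = env.data > threshold
    if not x.any():
        return BoutTable()
    d = np.diff(x.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if x[0]:
        starts = np.r_[0, starts]
    if x[-1]:
        ends = np.r_[ends, x.size]
    runs = [(env.t0 + s / env.rate, env.t0 + e / env.rate)
            for s, e in zip(starts, ends)]
    merged = [r for r in _merge_runs(runs, merge_gap) if r[1] - r[0] >= min_duration]
    if not merged:
        return BoutTable()

    w = max(int(round(vigor_median_window * env.rate)) | 1, 1)  # odd
    smooth = ndimage.median_filter(env.data, size=w, mode="nearest")
    rows = []
    for a, b in merged:
        i0 = max(int(round((a - env.t0) * env.rate)), 0)
        i1 = min(int(round((b - env.t0) * env.rate)), env.n)
        seg = smooth[i0:i1]
        rows.append(dict(t_on=a, t_off=b,
                         mean_vigor=float(seg.mean()) if seg.size else 0.0,
                         peak_vigor=float(seg.max()) if seg.size else 0.0))
    return BoutTable(pd.DataFrame(rows))


class BoutDetector(BaseEstimator):
    """Envelope-threshold bout detector with the <100-ms merge rule.

    ``fit`` learns the binarization threshold from the envelope median unless
    one is supplied; ``transform`` runs detection on a raw trace.
    """

    def __init__(self, sd_window=0.010, threshold=None, threshold_k=3.0,
                 merge_gap=0.100, min_duration=0.0, vigor_median_window=0.200):
        self.sd_window = sd_window
        self.threshold = threshold
        self.threshold_k = threshold_k
        self.merge_gap = merge_gap
        self.min_duration = min_duration
        self.vigor_median_window = vigor_median_window

    def fit(self, trace: TimeSeries, y=None) -> "BoutDetector":
        env = envelope(trace, self.sd_window)
        self.threshold_ = (self.threshold if self.threshold is not None
                           else rest_threshold(env, self.threshold_k))
        return self

    def transform(self, trace: TimeSeries) -> BoutTable:
        env = envelope(trace, self.sd_window)
        return detect_bouts(env, self.threshold_, self.merge_gap,
                            self.min_duration, self.vigor_median_window)

    def fit_transform(self, trace: TimeSeries, y=None) -> BoutTable:
        return self.fit(trace).transform(trace)


def vigor(tail_trace: TimeSeries, sd_window: float = 0.050,
          median_window: float = 0.200) -> TimeSeries:
    """Swim vigor: 50-ms rolling SD of the tail (or ventral-root) trace,
    median-filtered to extrapolate vigor across the entire bout."""
    if tail_trace.rate < 40:
        raise ValueError("tail trace must be sampled at >= 40 Hz")
    env = envelope(tail_trace, sd_window)
    w = max(int(round(median_window * tail_trace.rate)) | 1, 1)
    return TimeSeries(ndimage.median_filter(env.data, size=w, mode="nearest"),
                      env.rate, env.t0)


def _binary_autocorr(segments: list[np.ndarray], max_lag: int) -> np.ndarray:
    """Mean autocorrelation of demeaned binary segments up to ``max_lag``."""
    num = np.zeros(max_lag + 1)
    den = 0.0
    for seg in segments:
        z = seg - seg.mean()
        if z.size < 2:
            continue
        full = np.correlate(z, z, mode="full")[z.size - 1:z.size + max_lag]
        pad = np.zeros(max_lag + 1)
        pad[:full.size] = full
        num += pad
        den += np.sum(z * z)
    if den == 0:
        return np.zeros(max_lag + 1)
    return num / den


def swim_frequency(env: TimeSeries, threshold: float,
                   bouts: BoutTable | None = None, max_lag_s: float = 0.120,
                   n_shuffle: int = 100, seed: int = 0,
                   min_lag_s: float = 0.010):
    """Fictive swim frequency from the binarized envelope autocorrelation.

    Binarizes the envelope at ``threshold``, restricts to in-bout segments,
    averages their autocorrelation, and returns ``(frequency_hz, acf)`` for
    the first significant positive peak (peak height above the 95th
    percentile of a within-bout shuffled-sample null). Returns
    ``(nan, acf)`` when no significant peak exists.
    """
    if bouts is None:
        bouts = detect_bouts(env, threshold)
    max_lag = int(round(max_lag_s * env.rate))
    segs = []
    for a, b in zip(bouts.onsets, bouts.offsets):
        i0 = max(int(round((a - env.t0) * env.rate)), 0)
        i1 = min(int(round((b - env.t0) * env.rate)), env.n)
        if i1 - i0 >= 3:
            segs.append((env.data[i0:i1] > threshold).astype(float))
    acf = _binary_autocorr(segs, max_lag)
    min_lag = max(int(round(min_lag_s * env.rate)), 1)
    peaks, _ = signal.find_peaks(acf[min_lag:])
    peaks = peaks + min_lag
    if peaks.size == 0 or not segs:
        return float("nan"), acf

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_shuffle)
    for s in range(n_shuffle):
        shuffled = [rng.permutation(seg) for seg in segs]
        null_acf = _binary_autocorr(shuffled, max_lag)
        p, _ = signal.find_peaks(null_acf[min_lag:])
        null_max[s] = null_acf[p + min_lag].max() if p.size else 0.0
    bound = np.quantile(null_max, 0.95)
    sig = peaks[acf[peaks] > bound]
    if sig.size == 0:
        return float("nan"), acf
    lag = int(sig[0])
    # parabolic interpolation around the peak for sub-sample lag precision
    if 1 <= lag < max_lag:
        y0, y1, y2 = acf[lag - 1], acf[lag], acf[lag + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            lag = lag + 0.5 * (y0 - y2) / denom
    return float(env.rate / lag), acf


def eye_kinematics(left: TimeSeries, right: TimeSeries,
                   vel_smooth: float = 0.050) -> dict[str, TimeSeries]:
    """Twelve eye channels: per eye, signed position and velocity plus the
    positive- and negative-rectified version of each.

    Velocity is the boxcar-smoothed first difference (deg/s).
    """
    if left.rate != right.rate or left.n != right.n:
        raise ValueError("left and right eye traces must share a clock")
    out: dict[str, TimeSeries] = {}
    w = max(int(round(vel_smooth * left.rate)), 1)
    kern = np.ones(w) / w
    for name, ts in (("left", left), ("right", right)):
        pos = ts.data
        vel = np.convolve(np.gradient(pos) * ts.rate, kern, mode="same")
        chans = {
            f"eye_{name}_pos": pos,
            f"eye_{name}_vel": vel,
            f"eye_{name}_pos_p": np.maximum(pos, 0.0),
            f"eye_{name}_pos_n": np.maximum(-pos, 0.0),
            f"eye_{name}_vel_p": np.maximum(vel, 0.0),
            f"eye_{name}_vel_n": np.maximum(-vel, 0.0),
        }
        for k, v in chans.items():
            out[k] = TimeSeries(v, ts.rate, ts.t0)
    return out
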