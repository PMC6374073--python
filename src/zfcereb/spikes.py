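"""Complex/simple spike extraction from cell-attached traces.

Spikes are sorted purely by amplitude: one event per contiguous
supra-threshold excursion of the high-pass-filtered trace, timestamped at the
excursion peak. Simple-spike candidates falling within a blanking window
after a complex spike are discarded so the complex-spike waveform cannot be
double-counted.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator

from .core import TimeSeries, SpikeTrain, StimulusProtocol

__all__ = ["SortingParams", "SpikeSorter", "detect_spikes", "rate_from_train",
           "baseline_rate", "auto_thresholds"]


@dataclass
class SortingParams:
    highpass_cutoff: float = 3.0      # Hz, within the 1-10 Hz range
    cs_threshold: float = 5.0
    ss_threshold: float = 1.0
    blank_after_cs: float = 0.0025    # s
    rate_filter_width: float = 0.020  # s
    rectify: bool = False             # threshold |x| instead of +x

    def __post_init__(self) -> None:
        if not self.cs_threshold > self.ss_threshold > 0:
            raise ValueError("require cs_threshold > ss_threshold > 0")
        if self.blank_after_cs < 0:
            raise ValueError("blank_after_cs must be >= 0")


def _highpass(x: np.ndarray, rate: float, cutoff: float) -> np.ndarray:
    if cutoff <= 0:
        return x
    b, a = signal.butter(1, cutoff / (rate / 2.0), btype="highpass")
    return signal.filtfilt(b, a, x)


def _excursion_peaks(x: np.ndarray, thresh: float) -> tuple[np.ndarray, np.ndarray]:
    """Peak index and peak value of each contiguous supra-threshold run."""
    above = x > thresh
    if not above.any():
        return np.empty(0, dtype=int), np.empty(0)
    d = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, above.size]
    peaks = np.array([s + np.argmax(x[s:e]) for s, e in zip(starts, ends)])
    return peaks, x[peaks]


def detect_spikes(trace: TimeSeries, params: SortingParams) -> tuple[SpikeTrain, SpikeTrain]:
    """Amplitude-threshold sorting into (complex, simple) spike trains."""
    if trace.rate < 500:
        raise ValueError("trace sampling rate too low for spike detection")
    x = np.asarray(trace.data, dtype=float)
    if x.size == 0 or not np.all(np.isfinite(x)):
        raise ValueError("trace must be non-empty and finite")
    x = _highpass(x, trace.rate, params.highpass_cutoff)
    if params.rectify:
        x = np.abs(x)

    peaks, amps = _excursion_peaks(x, params.ss_threshold)
    times = trace.t0 + peaks / trace.rate
    is_cs = amps > params.cs_threshold
    cs_times = times[is_cs]
    ss_times = times[~is_cs]
    if cs_times.size and params.blank_after_cs > 0:
        # drop simple-spike candidates within the blanking window after a CS
        idx = np.searchsorted(cs_times, ss_times, side="right") - 1
        ok = idx < 0
        prev = np.where(idx >= 0, cs_times[np.maximum(idx, 0)], -np.inf)
        ok |= (ss_times - prev) > params.blank_after_cs
        ss_times = ss_times[ok]
    return SpikeTrain(cs_times, "complex"), SpikeTrain(ss_times, "simple")


def auto_thresholds(trace: TimeSeries, highpass_cutoff: float = 3.0,
                    noise_k: float = 4.0) -> tuple[float, float]:
    """Automatic (cs, ss) threshold initializer.

    Excursion-peak amplitudes above the robust noise floor (``noise_k``
    robust SDs, median/0.6745 of |x|) are split by a multi-level Otsu
    threshold on log amplitude into noise-adjacent, simple-spike and
    complex-spike classes; the upper split is the CS threshold, the lower
    one (floored at the noise level) the SS threshold.
    """
    from skimage.filters import threshold_multiotsu, threshold_otsu

    x = _highpass(np.asarray(trace.data, dtype=float), trace.rate, highpass_cutoff)
    noise_sd = np.median(np.abs(x)) / 0.6745
    floor = noise_k * noise_sd
    _, amps = _excursion_peaks(x, 0.5 * floor)
    amps = amps[amps > 0]
    if amps.size < 3 or np.ptp(amps) == 0:
        return 2.0 * floor, floor
    log_amps = np.log10(amps)
    try:
        lo, hi = 10.0 ** threshold_multiotsu(log_amps, classes=3,
                                             nbins=min(128, amps.size))
    except ValueError:
        hi = 10.0 ** threshold_otsu(log_amps)
        lo = floor
    ss_thr = max(float(lo), floor)
    cs_thr = float(hi)
    if cs_thr <= ss_thr:
        cs_thr = 2.0 * ss_thr
    return cs_thr, ss_thr


class SpikeSorter(BaseEstimator):
    """Estimator wrapper around amplitude-threshold spike sorting.

    ``fit`` initializes thresholds from the trace (Otsu split of excursion
    peak amplitudes) unless both are given; ``transform`` returns the
    (complex, simple) spike trains.
    """

    def __init__(self, cs_threshold=None, ss_threshold=None,
                 highpass_cutoff=3.0, blank_after_cs=0.0025, rectify=False):
        self.cs_threshold = cs_threshold
        self.ss_threshold = ss_threshold
        self.highpass_cutoff = highpass_cutoff
        self.blank_after_cs = blank_after_cs
        self.rectify = rectify

    def fit(self, trace: TimeSeries, y=None) -> "SpikeSorter":
        if self.cs_threshold is None or self.ss_threshold is None:
            cs_thr, ss_thr = auto_thresholds(trace, self.highpass_cutoff)
        else:
            cs_thr, ss_thr = self.cs_threshold, self.ss_threshold
        self.params_ = SortingParams(
            highpass_cutoff=self.highpass_cutoff, cs_threshold=cs_thr,
            ss_threshold=ss_thr, blank_after_cs=self.blank_after_cs,
            rectify=self.rectify)
        return self

    def transform(self, trace: TimeSeries) -> tuple[SpikeTrain, SpikeTrain]:
        return detect_spikes(trace, self.params_)

    def fit_transform(self, trace: TimeSeries, y=None):
        return self.fit(trace).transform(trace)


def rate_from_train(train: SpikeTrain, rate: float, width: float = 0.020,
                    duration: float | None = None, t0: float = 0.0) -> TimeSeries:
    """Delta train convolved with a unit-area boxcar: instantaneous firing
    rate in Hz whose integral equals the spike count."""
    if width <= 0:
        raise ValueError("filter width must be positive")
    if duration is None:
        duration = train.times.max(initial=0.0) - t0 + width
    n = max(int(round(duration * rate)), 1)
    deltas = np.zeros(n)
    idx = np.round((train.times - t0) * rate).astype(int)
    idx = idx[(idx >= 0) & (idx < n)]
    np.add.at(deltas, idx, 1.0)
    w = max(int(round(width * rate)), 1)
    kernel = np.full(w, 1.0 / (w / rate))  # unit area in seconds
    out = signal.fftconvolve(deltas, kernel)[:n] if w > 64 else np.convolve(deltas, kernel)[:n]
    return TimeSeries(out, rate, t0)


def baseline_rate(train: SpikeTrain, protocol: StimulusProtocol,
                  prestim_length: float = 2.0) -> float:
    """Baseline firing rate from blank trials, else from the pre-stimulus
    window at the start of each trial; error if neither exists."""
    windows = protocol.blank_windows()
    if not windows:
        windows = protocol.prestimulus_windows(prestim_length)
    if not windows:
        raise ValueError("no blank trials or pre-stimulus windows available")
    count = sum(train.count_in(a, b) for a, b in windows)
    total = sum(b - a for a, b in windows)
    return count / total
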