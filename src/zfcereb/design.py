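"""Sensory and motor design matrices for encoding-model regression.

Two measurement modes are supported: ``imaging`` regressors are convolved
with a single-exponential GCaMP kernel (tau = 1.6 s by default), ``ephys``
regressors with a 20-ms unit-area boxcar to match the convolution of spiking
into firing rates. The canonical electrophysiology design has 24 columns
(17 sensory + 7 swim-related); complex-spike analyses drop two derived
swim-timing variants, leaving 22.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import TimeSeries, StimulusProtocol, BoutTable

__all__ = ["KernelSpec", "RegressorMatrix", "sensory_regressors",
           "motor_regressors", "convolve_kernel", "smooth_rate",
           "build_design", "CS_DROPPED_COLUMNS"]

#: derived swim-timing variants excluded from complex-spike designs (24 -> 22)
CS_DROPPED_COLUMNS = ("swim_offset_window", "swim_duration_graded")


@dataclass
class KernelSpec:
    """Single-exponential indicator kernel k(t) = exp(-t / tau)."""

    tau: float = 1.6

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")

    def sample(self, rate: float, n_tau: float = 8.0) -> np.ndarray:
        t = np.arange(int(round(n_tau * self.tau * rate))) / rate
        return np.exp(-t / self.tau)


class RegressorMatrix:
    """T x R design matrix with per-column (group, subcategory) labels."""

    def __init__(self, df: pd.DataFrame, categories: dict, rate: float):
        if df.columns.duplicated().any():
            raise ValueError("column names must be unique")
        missing = set(df.columns) - set(categories)
        if missing:
            raise ValueError(f"columns without category: {sorted(missing)}")
        if not np.all(np.isfinite(df.to_numpy())):
            raise ValueError("design matrix must be finite")
        self.df = df
        self.categories = {k: tuple(v) for k, v in categories.items() if k in df.columns}
        self.rate = float(rate)

    @property
    def names(self) -> list[str]:
        return list(self.df.columns)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return len(self.df)

    def category_of(self, name: str) -> tuple[str, str]:
        return self.categories[name]

    def concat(self, other: "RegressorMatrix") -> "RegressorMatrix":
        if other.rate != self.rate or other.n_samples != self.n_samples:
            raise ValueError("regressor matrices must share clock and length")
        df = pd.concat([self.df, other.df], axis=1)
        cats = {**self.categories, **other.categories}
        return RegressorMatrix(df, cats, self.rate)

    def drop(self, names) -> "RegressorMatrix":
        keep = [c for c in self.df.columns if c not in set(names)]
        return RegressorMatrix(self.df[keep], self.categories, self.rate)

    def map_columns(self, fn) -> "RegressorMatrix":
        df = self.df.apply(lambda col: pd.Series(fn(col.to_numpy()), index=self.df.index))
        return RegressorMatrix(df, self.categories, self.rate)


def _impulse(times, n, rate):
    x = np.zeros(n)
    idx = np.round(np.asarray(times, dtype=float) * rate).astype(int)
    idx = idx[(idx >= 0) & (idx < n)]
    np.add.at(x, idx, 1.0)
    return x


def _boxcar(intervals, n, rate, height=None):
    x = np.zeros(n)
    for k, (a, b) in enumerate(intervals):
        i0 = max(int(round(a * rate)), 0)
        i1 = min(int(round(b * rate)), n)
        x[i0:i1] = 1.0 if height is None else height[k]
    return x


def sensory_regressors(protocol: StimulusProtocol, mode: str,
                       rate: float) -> RegressorMatrix:
    """Stimulus feature columns.

    ``ephys``: per-direction 500-ms motion-onset boxcars, per-direction
    motion-duration boxcars, graded grating speed, whole- and half-field
    rectified rotational velocities, rotation direction-change impulses,
    luminance-transition impulses and ambient luminance (17 columns).
    ``imaging``: the coarser duration/velocity/luminance set without onset
    windows (12 columns).
    """
    if mode not in ("imaging", "ephys"):
        raise ValueError(f"unknown mode: {mode!r}")
    if not len(protocol.epochs):
        raise ValueError("protocol has no epochs")
    n = int(round(protocol.duration * rate))
    t = np.arange(n) / rate
    cols: dict[str, np.ndarray] = {}
    cats: dict[str, tuple] = {}

    directions = ("forward", "right", "reverse", "left")
    if mode == "ephys":
        for d in directions:
            eps = protocol.motion_epochs(d)
            cols[f"onset_{d}"] = _boxcar(
                [(a, a + 0.5) for a in eps["t_on"]], n, rate)
            cats[f"onset_{d}"] = ("sensory", "motion_onset")
    for d in directions:
        eps = protocol.motion_epochs(d)
        cols[f"motion_{d}"] = _boxcar(list(zip(eps["t_on"], eps["t_off"])), n, rate)
        cats[f"motion_{d}"] = ("sensory", "motion_duration")

    eps = protocol.motion_epochs()
    cols["grating_speed"] = _boxcar(list(zip(eps["t_on"], eps["t_off"])), n, rate,
                                    height=eps["speed"].to_numpy())
    cats["grating_speed"] = ("sensory", "motion_velocity")

    for fld in ("whole", "half"):
        v = protocol.windmill_velocity(t, fld)
        suffix = "" if fld == "whole" else "_half"
        cols[f"rot_cw{suffix}"] = np.maximum(v, 0.0)
        cols[f"rot_ccw{suffix}"] = np.maximum(-v, 0.0)
        cats[f"rot_cw{suffix}"] = cats[f"rot_ccw{suffix}"] = ("sensory", "rotation")
    if mode == "ephys":
        # direction changes: interior zero crossings of the sinusoidal velocity
        changes = []
        for _, ep in protocol.windmill_epochs().iterrows():
            half = 0.5 / ep["freq_hz"]
            k = 1
            while ep["t_on"] + k * half < ep["t_off"]:
                changes.append(ep["t_on"] + k * half)
                k += 1
        cols["rot_dir_change"] = _impulse(changes, n, rate)
        cats["rot_dir_change"] = ("sensory", "rotation")

    # transition responses carry synaptic latency, so (like motion onsets)
    # each transition opens a 500-ms response window rather than an impulse
    trans = protocol.luminance_transitions()
    cols["lum_increase"] = _boxcar(
        [(a, a + 0.5) for a in trans[trans["sign"] > 0]["t"]], n, rate)
    cols["lum_decrease"] = _boxcar(
        [(a, a + 0.5) for a in trans[trans["sign"] < 0]["t"]], n, rate)
    cols["lum_ambient"] = protocol.ambient_level(t)
    for c in ("lum_increase", "lum_decrease", "lum_ambient"):
        cats[c] = ("sensory", "luminance")

    return RegressorMatrix(pd.DataFrame(cols), cats, rate)


def motor_regressors(bouts: BoutTable, vigor: TimeSeries | None,
                     eyes: dict[str, TimeSeries] | None, rate: float,
                     duration: float | None = None) -> RegressorMatrix:
    """Swim feature columns (onset/offset impulses, duration boxcar, graded
    vigor, three derived swim-timing variants) plus eye channels if given."""
    if duration is None:
        if vigor is not None:
            duration = vigor.duration
        elif len(bouts):
            duration = float(bouts.offsets.max())
        else:
            raise ValueError("cannot infer duration without vigor or bouts")
    n = int(round(duration * rate))
    cols: dict[str, np.ndarray] = {}
    cats: dict[str, tuple] = {}

    iv = list(zip(bouts.onsets, bouts.offsets))
    durations = bouts.offsets - bouts.onsets if len(bouts) else np.empty(0)
    cols["swim_onset"] = _impulse(bouts.onsets, n, rate)
    cols["swim_offset"] = _impulse(bouts.offsets, n, rate)
    cols["swim_duration"] = _boxcar(iv, n, rate)
    if vigor is not None:
        told = vigor.times
        tnew = np.arange(n) / rate
        v = np.interp(tnew, told, vigor.data)
        vmax = np.abs(v).max()
        cols["swim_vigor"] = v / vmax if vmax > 0 else v
    else:
        cols["swim_vigor"] = np.zeros(n)
    # derived swim-timing variants
    cols["swim_onset_window"] = _boxcar([(a, a + 0.3) for a in bouts.onsets], n, rate)
    cols["swim_offset_window"] = _boxcar([(b, b + 0.3) for b in bouts.offsets], n, rate)
    cols["swim_duration_graded"] = _boxcar(iv, n, rate, height=durations)
    for c in cols:
        cats[c] = ("motor", "swim")

    if eyes is not None:
        for name, ts in eyes.items():
            told = ts.times
            tnew = np.arange(n) / rate
            cols[name] = np.interp(tnew, told, ts.data)
            cats[name] = ("motor", "eye")
    return RegressorMatrix(pd.DataFrame(cols), cats, rate)


def convolve_kernel(X: RegressorMatrix, kernel: KernelSpec) -> RegressorMatrix:
    """Causal convolution of every column with the indicator kernel, then
    renormalization to unit maximum (zero columns stay zero)."""
    k = kernel.sample(X.rate)

    def conv(col: np.ndarray) -> np.ndarray:
        y = np.convolve(col, k)[:col.size]
        m = np.abs(y).max()
        return y / m if m > 0 else y

    return X.map_columns(conv)


def smooth_rate(X: RegressorMatrix, width: float = 0.020) -> RegressorMatrix:
    """Unit-area boxcar smoothing per column; preserves column integrals."""
    w = max(int(round(width * X.rate)), 1)
    kern = np.full(w, 1.0 / w)

    def conv(col: np.ndarray) -> np.ndarray:
        return np.convolve(col, kern)[:col.size]

    return X.map_columns(conv)


def build_design(protocol: StimulusProtocol, bouts: BoutTable,
                 vigor: TimeSeries | None, rate: float, mode: str = "ephys",
                 eyes: dict[str, TimeSeries] | None = None,
                 target: str = "ss", kernel: KernelSpec | None = None,
                 rate_filter_width: float = 0.020) -> RegressorMatrix:
    """Full design matrix for one session and measurement mode.

    ``target='cs'`` drops the two derived swim-timing variants (24 -> 22
    columns for the eyeless electrophysiology design).
    """
    X = sensory_regressors(protocol, mode, rate).concat(
        motor_regressors(bouts, vigor, eyes, rate, duration=protocol.duration))
    if mode == "ephys" and target == "cs":
        X = X.drop(CS_DROPPED_COLUMNS)
    if mode == "imaging":
        X = convolve_kernel(X, kernel or KernelSpec())
    else:
        X = smooth_rate(X, rate_filter_width)
    return X
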