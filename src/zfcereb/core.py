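"""Core containers shared across the analysis pipeline.

Time is always expressed in seconds on a single session clock, positions in
micrometres (rostral = +y, midline x = 0, dorsal = +z), rates in Hz.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TimeSeries", "SpikeTrain", "StimulusProtocol", "BoutTable"]


@dataclass
class TimeSeries:
    """A uniformly sampled signal with a start time and sampling rate."""

    data: np.ndarray
    rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.ndim != 1:
            raise ValueError("TimeSeries data must be one-dimensional")

    @property
    def n(self) -> int:
        return self.data.size

    @property
    def duration(self) -> float:
        return self.n / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.rate

    def index_of(self, t: float) -> int:
        """Nearest-sample index of time ``t`` (clipped to the valid range)."""
        i = int(round((t - self.t0) * self.rate))
        return min(max(i, 0), self.n - 1)

    def slice(self, t_start: float, t_stop: float) -> "TimeSeries":
        i0 = max(int(np.ceil((t_start - self.t0) * self.rate)), 0)
        i1 = min(int(np.floor((t_stop - self.t0) * self.rate)) + 1, self.n)
        return TimeSeries(self.data[i0:i1], self.rate, self.t0 + i0 / self.rate)


@dataclass
class SpikeTrain:
    """Sorted event times with a label (complex | simple | granule)."""

    times: np.ndarray
    label: str = "simple"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).ravel()
        if self.times.size and np.any(np.diff(self.times) < 0):
            raise ValueError("spike times must be sorted")

    @property
    def n(self) -> int:
        return self.times.size

    def count_in(self, t_on: float, t_off: float) -> int:
        return int(np.searchsorted(self.times, t_off) - np.searchsorted(self.times, t_on))

    def between(self, t_on: float, t_off: float) -> "SpikeTrain":
        i0, i1 = np.searchsorted(self.times, (t_on, t_off))
        return SpikeTrain(self.times[i0:i1], self.label)


# epoch kinds that move (used to decide whether a trial is "blank")
MOVING_KINDS = ("grating", "windmill")


@dataclass
class StimulusProtocol:
    """Ordered stimulus epochs over a session of concatenated trials.

    ``epochs`` columns: kind (grating|windmill|flash|blank), direction
    (forward|reverse|left|right|cw|ccw|none), speed (mm/s; 0 for static),
    freq_hz (sinusoid frequency, windmill only), amplitude, field
    (whole|half), luminance (ambient level in [0, 1]), t_on, t_off, trial.

    ``trials`` columns: trial, kind (stim|blank), t_start, t_end.
    """

    epochs: pd.DataFrame
    trials: pd.DataFrame
    ambient_luminance: float = 0.5

    def __post_init__(self) -> None:
        e = self.epochs
        if len(e) and np.any(e["t_off"].to_numpy() <= e["t_on"].to_numpy()):
            raise ValueError("epoch t_off must exceed t_on")

    @property
    def duration(self) -> float:
        return float(self.trials["t_end"].max())

    # -- helpers used throughout the pipeline -------------------------------
    def motion_epochs(self, direction: str | None = None) -> pd.DataFrame:
        e = self.epochs
        sel = (e["kind"] == "grating") & (e["speed"] > 0)
        if direction is not None:
            sel &= e["direction"] == direction
        return e[sel]

    def windmill_epochs(self, field_: str | None = None) -> pd.DataFrame:
        e = self.epochs
        sel = e["kind"] == "windmill"
        if field_ is not None:
            sel &= e["field"] == field_
        return e[sel]

    def flash_epochs(self) -> pd.DataFrame:
        return self.epochs[self.epochs["kind"] == "flash"]

    def luminance_transitions(self) -> pd.DataFrame:
        """Times and signs (+1 increase, -1 decrease) of whole-field steps."""
        rows = []
        level = self.ambient_luminance
        prev_off = None
        for _, ep in self.epochs.iterrows():
            if ep["kind"] != "flash":
                continue
            # step into the flash level, and back to ambient at its end
            new = ep["luminance"]
            if not np.isclose(new, level):
                rows.append({"t": ep["t_on"], "sign": 1 if new > level else -1})
            level = new
            prev_off = ep["t_off"]
            # peek: if the next epoch is not a contiguous flash, we return to ambient
        # close any trailing flash back to ambient
        flashes = self.flash_epochs()
        if len(flashes):
            ends = flashes["t_off"].to_numpy()
            starts = flashes["t_on"].to_numpy()
            for i, t_end in enumerate(ends):
                if not np.any(np.isclose(starts, t_end)):
                    lvl = flashes.iloc[i]["luminance"]
                    if not np.isclose(lvl, self.ambient_luminance):
                        rows.append({
                            "t": t_end,
                            "sign": 1 if self.ambient_luminance > lvl else -1,
                        })
        out = pd.DataFrame(rows, columns=["t", "sign"])
        return out.sort_values("t").reset_index(drop=True)

    def ambient_level(self, times: np.ndarray) -> np.ndarray:
        """Whole-field luminance level sampled at ``times``."""
        level = np.full(len(times), self.ambient_luminance)
        for _, ep in self.flash_epochs().iterrows():
            level[(times >= ep["t_on"]) & (times < ep["t_off"])] = ep["luminance"]
        return level

    def windmill_velocity(self, times: np.ndarray, field_: str = "whole") -> np.ndarray:
        """Signed rotational velocity (positive = clockwise) at ``times``."""
        v = np.zeros(len(times))
        for _, ep in self.windmill_epochs(field_).iterrows():
            m = (times >= ep["t_on"]) & (times < ep["t_off"])
            v[m] = ep["amplitude"] * np.sin(
                2 * np.pi * ep["freq_hz"] * (times[m] - ep["t_on"])
            )
        return v

    def blank_windows(self) -> list[tuple[float, float]]:
        t = self.trials
        return [
            (row["t_start"], row["t_end"])
            for _, row in t[t["kind"] == "blank"].iterrows()
        ]

    def prestimulus_windows(self, length: float = 2.0) -> list[tuple[float, float]]:
        """Per-trial windows before the first moving epoch of that trial."""
        out = []
        for _, tr in self.trials.iterrows():
            e = self.epochs
            in_trial = e[(e["trial"] == tr["trial"]) & e["kind"].isin(MOVING_KINDS) & (e["speed"] > 0)]
            first = in_trial["t_on"].min() if len(in_trial) else np.inf
            first = min(first, tr["t_end"])
            t0 = tr["t_start"]
            if first - t0 >= length:
                out.append((t0, t0 + length))
        return out


@dataclass
class BoutTable:
    """Detected (or planted) motor episodes with per-bout vigor summaries."""

    bouts: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["t_on", "t_off", "mean_vigor", "peak_vigor"]))

    def __post_init__(self) -> None:
        b = self.bouts
        if len(b):
            if np.any(b["t_off"].to_numpy() <= b["t_on"].to_numpy()):
                raise ValueError("bout t_off must exceed t_on")
            on = b["t_on"].to_numpy()
            off = b["t_off"].to_numpy()
            if np.any(on[1:] < off[:-1]):
                raise ValueError("bouts must be non-overlapping and sorted")

    def __len__(self) -> int:
        return len(self.bouts)

    @property
    def onsets(self) -> np.ndarray:
        return self.bouts["t_on"].to_numpy(dtype=float)

    @property
    def offsets(self) -> np.ndarray:
        return self.bouts["t_off"].to_numpy(dtype=float)

    @property
    def total_duration(self) -> float:
        if not len(self.bouts):
            return 0.0
        return float((self.bouts["t_off"] - self.bouts["t_on"]).sum())

    def contains(self, times: np.ndarray) -> np.ndarray:
        """Boolean mask: is each time inside some bout (t_on <= t < t_off)."""
        times = np.asarray(times, dtype=float)
        if not len(self.bouts):
            return np.zeros(times.shape, dtype=bool)
        idx = np.searchsorted(self.onsets, times, side="right") - 1
        ok = idx >= 0
        out = np.zeros(times.shape, dtype=bool)
        out[ok] = times[ok] < self.offsets[idx[ok]]
        return out

    def indicator(self, n: int, rate: float, t0: float = 0.0) -> np.ndarray:
        t = t0 + np.arange(n) / rate
        return self.contains(t)
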