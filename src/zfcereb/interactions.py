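"""Spike-level statistics: CS-triggered SS modulation by behavioral context,
bout-triggered rates, in-bout autocorrelation tests, direction selectivity,
first-spike latency, and per-event complex-spike probability.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.diagnostic import acorr_ljungbox

from .core import TimeSeries, SpikeTrain, BoutTable, StimulusProtocol
from .spikes import rate_from_train

__all__ = ["TriggeredHistogram", "ContextSplit", "cs_triggered_ss",
           "split_context", "bout_triggered_rate", "spike_autocorr_test",
           "direction_selectivity", "first_spike_latency",
           "cs_probability_per_event"]

MIN_TRIGGERS = 10  # cells with fewer triggers in a condition are excluded


@dataclass
class TriggeredHistogram:
    """Per-bin mean SS counts around a trigger, normalized to the mean count
    over the window preceding the trigger (100 ms by default)."""

    bin_edges: np.ndarray          # seconds, relative to trigger
    mean_counts: np.ndarray        # mean count per bin per trigger
    normalized: np.ndarray         # mean_counts / pre-trigger baseline
    baseline: float                # mean count per bin in the norm window
    n_triggers: int
    excluded: bool = False

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def cs_triggered_ss(cs: SpikeTrain, ss: SpikeTrain,
                    window: tuple = (-0.3, 0.3), bin_width: float = 0.010,
                    norm_window: float = 0.100,
                    triggers: np.ndarray | None = None) -> TriggeredHistogram:
    """Mean CS-triggered SS count histogram (10-ms bins), normalized to the
    mean per-bin count over the 100 ms preceding each complex spike."""
    trig = cs.times if triggers is None else np.asarray(triggers, dtype=float)
    lo, hi = window
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts = np.zeros(n_bins)
    for t in trig:
        rel = ss.times[(ss.times >= t + lo) & (ss.times < t + hi)] - t
        counts += np.histogram(rel, bins=edges)[0]
    n_trig = trig.size
    mean_counts = counts / n_trig if n_trig else counts
    pre = (edges[:-1] >= -norm_window) & (edges[1:] <= 0)
    baseline = mean_counts[pre].mean() if pre.any() else np.nan
    normalized = (mean_counts / baseline if baseline and baseline > 0
                  else np.full(n_bins, np.nan))
    return TriggeredHistogram(edges, mean_counts, normalized,
                              float(baseline), int(n_trig),
                              excluded=n_trig < MIN_TRIGGERS)


@dataclass
class ContextSplit:
    """Trigger times partitioned by behavioral and sensory context."""

    motor: np.ndarray
    non_motor: np.ndarray
    preferred_sensory: np.ndarray = field(default_factory=lambda: np.empty(0))
    other_sensory: np.ndarray = field(default_factory=lambda: np.empty(0))
    blank: np.ndarray = field(default_factory=lambda: np.empty(0))


def split_context(cs: SpikeTrain, bouts: BoutTable,
                  protocol: StimulusProtocol | None = None,
                  preferred_stimulus=None) -> ContextSplit:
    """Assign each complex spike to motor (inside a fictive bout) versus
    non-motor context, and optionally to sensory-epoch subsets.

    ``preferred_stimulus`` is a predicate over epoch rows (or a direction
    string) defining the preferred sensory context; the full epoch counts as
    preferred context.
    """
    t = cs.times
    in_bout = bouts.contains(t)
    motor, non_motor = t[in_bout], t[~in_bout]
    pref = other = blank = np.empty(0)
    if protocol is not None:
        in_pref = np.zeros(t.size, dtype=bool)
        in_any = np.zeros(t.size, dtype=bool)
        for _, ep in protocol.epochs.iterrows():
            m = (t >= ep["t_on"]) & (t < ep["t_off"])
            if ep["kind"] in ("grating", "windmill", "flash") and ep.get("speed", 0) >= 0:
                moving = ep["kind"] != "grating" or ep["speed"] > 0
                if moving:
                    in_any |= m
                    if _is_preferred(ep, preferred_stimulus):
                        in_pref |= m
        pref = t[in_pref]
        other = t[in_any & ~in_pref]
        bl = np.zeros(t.size, dtype=bool)
        for a, b in protocol.blank_windows():
            bl |= (t >= a) & (t < b)
        blank = t[bl]
    return ContextSplit(motor, non_motor, pref, other, blank)


def _is_preferred(ep, preferred) -> bool:
    if preferred is None:
        return False
    if callable(preferred):
        return bool(preferred(ep))
    return ep["direction"] == preferred


def bout_triggered_rate(train: SpikeTrain, bouts: BoutTable,
                        align: str = "onset", window: tuple = (-0.5, 1.0),
                        rate: float = 1000.0, filter_width: float = 0.020):
    """Mean 20-ms-filtered firing rate aligned to bout edges.

    Returns ``(lags, mean_rate, post_onset_mean)`` where the last value is
    the 300-ms post-onset mean rate used to sort cells.
    """
    if align not in ("onset", "offset"):
        raise ValueError("align must be 'onset' or 'offset'")
    events = bouts.onsets if align == "onset" else bouts.offsets
    if events.size == 0:
        raise ValueError("no bouts to align to")
    lo, hi = window
    n = int(round((hi - lo) * rate))
    lags = lo + np.arange(n) / rate
    acc = np.zeros(n)
    used = 0
    t_max = max(train.times.max(initial=0.0), events.max() + hi)
    full = rate_from_train(train, rate, filter_width, duration=t_max + 1.0)
    for e in events:
        i0 = int(round((e + lo) * rate))
        if i0 < 0 or i0 + n > full.n:
            continue
        acc += full.data[i0:i0 + n]
        used += 1
    if used == 0:
        raise ValueError("no aligned windows fit inside the recording")
    mean_rate = acc / used
    post = mean_rate[(lags >= 0) & (lags < 0.3)].mean()
    return lags, mean_rate, float(post)


def spike_autocorr_test(train: SpikeTrain, bouts: BoutTable,
                        max_lag: int = 20, bin_width: float = 0.005,
                        min_spikes: int = 20):
    """Ljung-Box test for in-bout spike-train autocorrelation.

    Bins in-bout spikes (5-ms bins per bout, concatenated), computes the
    autocorrelation to ``max_lag`` bins, and returns ``(acf, p_value)`` from
    the Ljung-Box Q statistic at that lag.
    """
    segs = []
    n_spikes = 0
    for a, b in zip(bouts.onsets, bouts.offsets):
        n = int(np.floor((b - a) / bin_width))
        if n < 2:
            continue
        edges = a + bin_width * np.arange(n + 1)
        seg = np.histogram(train.times, bins=edges)[0]
        n_spikes += int(seg.sum())
        segs.append(seg)
    if n_spikes < min_spikes:
        raise ValueError(f"fewer than {min_spikes} in-bout spikes")
    x = np.concatenate(segs).astype(float)
    z = x - x.mean()
    denom = np.sum(z * z)
    acf = np.array([1.0] + [np.sum(z[:-k] * z[k:]) / denom
                            for k in range(1, max_lag + 1)])
    lb = acorr_ljungbox(x, lags=[max_lag], return_df=True)
    return acf, float(lb["lb_pvalue"].iloc[0])


_OPPOSITE = {"forward": "reverse", "reverse": "forward",
             "left": "right", "right": "left"}


def direction_selectivity(rates: dict, method: str = "pref_opp") -> float:
    """Direction selectivity index from the four cardinal responses.

    Default: (R_pref - R_opp) / (R_pref + R_opp) with the preferred direction
    the argmax and the opposite its 180-degree counterpart. ``method='vector'``
    uses the normalized vector sum instead.
    """
    if set(rates) != set(_OPPOSITE) or any(v < 0 for v in rates.values()):
        raise ValueError("need non-negative responses for all four cardinals")
    total = sum(rates.values())
    if total == 0:
        raise ValueError("all-zero responses")
    if method == "vector":
        angles = {"forward": 90.0, "right": 0.0, "reverse": 270.0, "left": 180.0}
        vx = sum(r * np.cos(np.deg2rad(angles[d])) for d, r in rates.items())
        vy = sum(r * np.sin(np.deg2rad(angles[d])) for d, r in rates.items())
        return float(np.hypot(vx, vy) / total)
    pref = max(rates, key=rates.get)
    r_p, r_o = rates[pref], rates[_OPPOSITE[pref]]
    return float((r_p - r_o) / (r_p + r_o))


def first_spike_latency(cs: SpikeTrain, events, window: float = 0.5):
    """Mean latency, jitter SD, and response probability of the first complex
    spike after each event onset."""
    events = np.asarray(events, dtype=float)
    if events.size == 0:
        raise ValueError("need at least one event")
    lats = []
    for e in events:
        after = cs.times[(cs.times >= e) & (cs.times < e + window)]
        if after.size:
            lats.append(after[0] - e)
    prob = len(lats) / events.size
    if not lats:
        return float("nan"), float("nan"), 0.0
    lats = np.asarray(lats)
    return float(lats.mean()), float(lats.std(ddof=0)), float(prob)


def cs_probability_per_event(cs: SpikeTrain, events, window: float = 0.5) -> float:
    """Fraction of events followed by at least one complex spike within the
    window."""
    events = np.asarray(events, dtype=float)
    if events.size == 0:
        raise ValueError("need at least one event")
    hits = sum(cs.count_in(e, e + window) > 0 for e in events)
    return hits / events.size
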