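"""Synthetic session generator for cerebellar sensorimotor-encoding analysis.

Generates visual-stimulus protocols, fictive-swim behavior (ventral-root
traces), Purkinje complex/simple-spike and granule-cell spike trains,
GCaMP-like calcium traces, nuclear-GCaMP image volumes and dendritic
morphologies whose generative parameters equal the population statistics the
analysis pipeline is meant to recover. Every planted parameter is recorded in
``ground_truth`` so each downstream stage can be validated by parameter
recovery.

Spike trains are thinned inhomogeneous Poisson processes with a 2-ms absolute
dead time; the driving intensity is compensated pointwise
(``lam* = lam / (1 - lam * dead_time)``) so the observed rate equals the
planted rate in the long-run limit.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import signal

from .core import TimeSeries, SpikeTrain, StimulusProtocol, BoutTable

__all__ = [
    "GeneratorConfig",
    "SyntheticCell",
    "BehaviorSim",
    "Session",
    "make_protocol",
    "simulate_behavior",
    "simulate_purkinje",
    "simulate_granule",
    "simulate_calcium",
    "simulate_paired_recordings",
    "simulate_nuclei_volume",
    "simulate_morphology",
    "render_ephys_trace",
    "make_session",
    "calcium_amplitude_ratio",
]

PHENOTYPES = ("motion_onset", "rotational_velocity", "luminance", "motor", "granule")
CARDINALS = ("forward", "right", "reverse", "left")


@dataclass
class GeneratorConfig:
    """All generative defaults. The defaults ARE the study conditions.

    Rates in Hz, times in seconds, amplitudes in arbitrary recording units
    (ventral root) or dF/F (calcium).
    """

    seed: int = 0
    ephys_rate: float = 1000.0          # 8300.0 available for full-rate traces
    imaging_rate: float = 30.0
    n_trials: int = 5                   # stimulus trials per session
    n_blank_trials: int = 3             # interspersed blank (static) trials
    phenotype_mix: dict = field(default_factory=lambda: {
        "motion_onset": 31, "rotational_velocity": 12, "luminance": 10, "motor": 8,
    })

    # --- complex spikes ---------------------------------------------------
    cs_baseline: dict = field(default_factory=lambda: {
        "motion_onset": 0.20, "rotational_velocity": 0.77,
        "luminance": 0.28, "motor": 0.34,
    })
    onset_spikes_per_window: float = 1.2    # CS per preferred 500-ms onset window
    onset_window: float = 0.5
    rot_gain: float = 4.4                   # preferred-direction rate / baseline
    rot_nonpref_rate: float = 0.32          # Hz during non-preferred rotation
    rot_depress_frac: float = 0.37          # post-stimulus rate / baseline
    rot_depress_dur: float = 1.0
    lum_spikes_per_transition: float = 0.80
    lum_latency_range: tuple = (0.150, 0.400)   # fixed per cell
    lum_jitter_sd: float = 0.005                # trial-to-trial, <= 10 ms
    motor_cs_prob: float = 0.38                 # CS probability per bout
    motor_cs_latency_range: tuple = (0.0, 0.3)
    refractory: float = 0.002

    # --- simple spikes / granule cells ------------------------------------
    ss_rest: float = 7.6
    ss_bout: float = 14.5                   # time-mean in-bout rate
    gc_rest: float = 1.3
    gc_bout: float = 25.7
    # optional multiplicative post-CS gain on the SS intensity (None = off)
    cs_ss_gain: float | None = None
    cs_ss_window_nonmotor: float = 0.200
    cs_ss_window_motor: float = 0.050

    # --- fictive swimming -------------------------------------------------
    vr_cycle_hz: float = 26.7
    burst_duty: float = 0.4
    bout_duration_range: tuple = (0.2, 0.6)
    bout_min_gap: float = 1.0
    bout_max_gap: float = 5.0
    bout_rate_spont: float = 0.15           # onsets/s outside driving stimuli
    bout_rate_evoked: float = 0.45          # extra onsets/s during fwd/lat motion
    vr_noise_sd: float = 1.0
    bout_amp: float = 14.0                  # peak burst SD, x noise SD
    bout_amp_cv: float = 0.3
    bout_ramp: float = 0.020                # trapezoid attack/decay, s

    # --- eyes ---------------------------------------------------------------
    eye_gain: float = 10.0                  # deg per unit windmill velocity
    eye_gain_cv: float = 0.3
    eye_latency_range: tuple = (0.05, 0.15)
    eye_noise_sd: float = 0.1

    # --- calcium ------------------------------------------------------------
    ca_tau: float = 1.6
    ca_a_ss: float = 0.05                   # dF/F per simple spike
    ca_cs_share: float = 0.784              # target CS share of signal
    ca_noise_sd: float = 0.01
    paired_cs_rate: float = 0.5
    paired_ss_rate: float = 7.6
    paired_duration: float = 300.0

    # --- nuclei volumes -----------------------------------------------------
    n_nuclei: int = 433
    nucleus_sigma: float = 2.0              # voxels
    volume_shape: tuple = (48, 128, 128)    # z, y, x voxels
    volume_snr: float = 5.0
    nucleus_min_sep: float = 8.0            # voxels, centre-to-centre

    def __post_init__(self) -> None:
        if self.ephys_rate <= 0 or self.imaging_rate <= 0:
            raise ValueError("sampling rates must be positive")
        if any(v < 0 for v in self.phenotype_mix.values()):
            raise ValueError("phenotype counts must be non-negative")

    def rng(self, *stream) -> np.random.Generator:
        """Independent generator for a named substream of this seed."""
        tag = zlib.crc32("/".join(str(s) for s in stream).encode()) & 0x7FFFFFFF
        return np.random.default_rng([int(self.seed) & 0x7FFFFFFF, tag])

    def as_dict(self) -> dict:
        return asdict(self)


def calcium_amplitude_ratio(config: GeneratorConfig) -> float:
    """A_cs / A_ss giving the target CS variance share at the paired rates.

    By Campbell's theorem the variance contributed by a Poisson shot-noise
    source of rate r and per-event amplitude A through a common kernel k is
    A^2 * r * int(k^2), so the CS share is
    rho*sqrt(r_cs) / (rho*sqrt(r_cs) + sqrt(r_ss)) with rho = A_cs/A_ss.
    """
    s = config.ca_cs_share
    return (s / (1.0 - s)) * np.sqrt(config.paired_ss_rate / config.paired_cs_rate)


# ---------------------------------------------------------------------------
# stimulus protocol
# ---------------------------------------------------------------------------

_TRIAL_LENGTH = 100.0


def _stim_trial_epochs(t0: float, trial: int, ambient: float) -> list[dict]:
    """One stimulus trial: forward gratings at 3/10/30 mm/s, reverse/left/right
    at 10 mm/s (5 s each, 5 s static pauses), whole- and half-field windmill at
    0.2 Hz sinusoidal velocity, and whole-field luminance flashes."""
    eps = []

    def grating(t_on, direction, speed, dur=5.0):
        eps.append(dict(kind="grating", direction=direction, speed=speed,
                        freq_hz=0.0, amplitude=0.0, field="whole",
                        luminance=ambient, t_on=t0 + t_on, t_off=t0 + t_on + dur,
                        trial=trial))

    t = 2.0  # 2-s pre-stimulus static period
    for speed in (3.0, 10.0, 30.0):
        grating(t, "forward", speed)
        t += 10.0
    for direction in ("reverse", "left", "right"):
        grating(t, direction, 10.0)
        t += 10.0
    for fld in ("whole", "half"):
        eps.append(dict(kind="windmill", direction="none", speed=0.0,
                        freq_hz=0.2, amplitude=1.0, field=fld,
                        luminance=ambient, t_on=t0 + t, t_off=t0 + t + 10.0,
                        trial=trial))
        t += 15.0
    # flashes: alternate max luminance and darkness, 1 s each
    for i in range(6):
        lvl = 1.0 if i % 2 == 0 else 0.0
        eps.append(dict(kind="flash", direction="none", speed=0.0,
                        freq_hz=0.0, amplitude=0.0, field="whole",
                        luminance=lvl, t_on=t0 + t, t_off=t0 + t + 1.0,
                        trial=trial))
        t += 1.0
    return eps


def make_protocol(config: GeneratorConfig) -> StimulusProtocol:
    """Session protocol: ``n_trials`` stimulus trials followed by
    ``n_blank_trials`` blank trials (static gratings only)."""
    ambient = 0.5
    epochs: list[dict] = []
    trials: list[dict] = []
    t0 = 0.0
    trial = 0
    for _ in range(config.n_trials):
        epochs.extend(_stim_trial_epochs(t0, trial, ambient))
        trials.append(dict(trial=trial, kind="stim", t_start=t0, t_end=t0 + _TRIAL_LENGTH))
        t0 += _TRIAL_LENGTH
        trial += 1
    for _ in range(config.n_blank_trials):
        epochs.append(dict(kind="blank", direction="none", speed=0.0,
                           freq_hz=0.0, amplitude=0.0, field="whole",
                           luminance=ambient, t_on=t0, t_off=t0 + _TRIAL_LENGTH,
                           trial=trial))
        trials.append(dict(trial=trial, kind="blank", t_start=t0, t_end=t0 + _TRIAL_LENGTH))
        t0 += _TRIAL_LENGTH
        trial += 1
    cols = ["kind", "direction", "speed", "freq_hz", "amplitude", "field",
            "luminance", "t_on", "t_off", "trial"]
    return StimulusProtocol(
        epochs=pd.DataFrame(epochs, columns=cols),
        trials=pd.DataFrame(trials, columns=["trial", "kind", "t_start", "t_end"]),
        ambient_luminance=ambient,
    )


# ---------------------------------------------------------------------------
# point-process machinery
# ---------------------------------------------------------------------------

def _dead_time_filter(times: np.ndarray, refractory: float) -> np.ndarray:
    if times.size == 0 or refractory <= 0:
        return times
    keep = [times[0]]
    for t in times[1:]:
        if t - keep[-1] >= refractory:
            keep.append(t)
    return np.asarray(keep)


def sample_poisson_train(
    rate: np.ndarray | float,
    duration: float,
    rng: np.random.Generator,
    sample_rate: float = 1000.0,
    refractory: float = 0.002,
    t0: float = 0.0,
) -> np.ndarray:
    """Thinned (inhomogeneous) Poisson spike times with dead-time compensation."""
    if np.isscalar(rate):
        lam = np.full(max(int(round(duration * sample_rate)), 1), float(rate))
    else:
        lam = np.asarray(rate, dtype=float)
        duration = lam.size / sample_rate
    lam = np.clip(lam, 0.0, 0.5 / max(refractory, 1e-9))
    lam_star = lam / (1.0 - lam * refractory)
    lam_max = float(lam_star.max(initial=0.0))
    if lam_max <= 0:
        return np.empty(0)
    n = rng.poisson(lam_max * duration)
    cand = np.sort(rng.uniform(0.0, duration, size=n))
    idx = np.minimum((cand * sample_rate).astype(int), lam.size - 1)
    keep = rng.uniform(0.0, lam_max, size=n) < lam_star[idx]
    times = _dead_time_filter(cand[keep], refractory)
    return times + t0


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

@dataclass
class BehaviorSim:
    """Planted fictive-swim behavior for one session."""

    vr: TimeSeries
    vigor: TimeSeries            # planted smooth vigor (burst cycle removed)
    bouts: BoutTable             # planted bout table
    eyes: tuple                  # (left, right) TimeSeries
    cycle_hz: float
    ground_truth: dict = field(default_factory=dict)


def _draw_bouts(protocol: StimulusProtocol, config: GeneratorConfig,
                rng: np.random.Generator) -> pd.DataFrame:
    """Bout onsets as an inhomogeneous renewal process: elevated probability
    during forward/lateral motion, no elevation for reverse motion."""
    T = protocol.duration
    drive = protocol.motion_epochs()
    drive = drive[drive["direction"].isin(["forward", "left", "right"])]
    lam_max = config.bout_rate_spont + config.bout_rate_evoked
    n = rng.poisson(lam_max * T)
    cand = np.sort(rng.uniform(0.0, T, size=n))
    in_drive = np.zeros(cand.size, dtype=bool)
    for _, ep in drive.iterrows():
        in_drive |= (cand >= ep["t_on"]) & (cand < ep["t_off"])
    lam = np.where(in_drive, lam_max, config.bout_rate_spont)
    cand = cand[rng.uniform(0.0, lam_max, size=cand.size) < lam]

    rows = []
    last_off = -np.inf
    lo, hi = config.bout_duration_range
    fc, duty = config.vr_cycle_hz, config.burst_duty
    for t_on in cand:
        if t_on < last_off + config.bout_min_gap:
            continue
        dur = rng.uniform(lo, hi)
        # quantize to whole burst cycles plus one burst so ventral-root
        # activity starts and ends exactly at the bout edges
        k = max(int(round(dur * fc - duty)), 3)
        dur = (k + duty) / fc
        if t_on + dur > T:
            break
        amp = max(rng.normal(1.0, config.bout_amp_cv), 0.4)
        rows.append(dict(t_on=t_on, t_off=t_on + dur, amplitude=amp))
        last_off = t_on + dur
    return pd.DataFrame(rows, columns=["t_on", "t_off", "amplitude"])


def simulate_behavior(protocol: StimulusProtocol, config: GeneratorConfig,
                      rng: np.random.Generator | None = None) -> BehaviorSim:
    """Ventral-root trace with bursty bouts, planted vigor, and eye traces.

    Within a bout the burst-cycle structure runs at ``vr_cycle_hz``: the noise
    standard deviation is modulated by a trapezoidal bout profile (fast
    ``bout_ramp`` attack/decay, as in real bout envelopes) times a
    burst/inter-burst duty cycle. The planted vigor is the smooth (cycle-free)
    profile used to scale simple-spike and granule-cell intensities.
    """
    if rng is None:
        rng = config.rng("behavior")
    rate = config.ephys_rate
    T = protocol.duration
    n = int(round(T * rate))
    t = np.arange(n) / rate

    bouts = _draw_bouts(protocol, config, rng)
    sigma = np.full(n, config.vr_noise_sd)
    vigor = np.zeros(n)
    fc = config.vr_cycle_hz
    for _, b in bouts.iterrows():
        i0, i1 = int(round(b["t_on"] * rate)), int(round(b["t_off"] * rate))
        i1 = min(i1, n)
        tt = t[i0:i1] - b["t_on"]
        dur = b["t_off"] - b["t_on"]
        ramp = min(config.bout_ramp, dur / 2)
        profile = np.clip(np.minimum(tt, dur - tt) / ramp, 0.0, 1.0)
        phase = (tt * fc) % 1.0
        burst = np.where(phase < config.burst_duty, 1.0, 0.1)
        amp = b["amplitude"] * config.bout_amp * config.vr_noise_sd
        sigma[i0:i1] += amp * profile * burst
        vigor[i0:i1] = amp * profile
    vr = TimeSeries(rng.normal(0.0, 1.0, size=n) * sigma, rate)

    # per-bout vigor summaries on the planted (smooth) vigor
    out_rows = []
    for _, b in bouts.iterrows():
        i0, i1 = int(round(b["t_on"] * rate)), min(int(round(b["t_off"] * rate)), n)
        seg = vigor[i0:i1]
        out_rows.append(dict(t_on=b["t_on"], t_off=b["t_off"],
                             mean_vigor=float(seg.mean()) if seg.size else 0.0,
                             peak_vigor=float(seg.max()) if seg.size else 0.0))
    table = BoutTable(pd.DataFrame(out_rows, columns=["t_on", "t_off", "mean_vigor", "peak_vigor"]))

    eyes = _simulate_eyes(protocol, config, rng, t)
    gt = dict(cycle_hz=fc, n_bouts=len(table),
              bout_rate_spont=config.bout_rate_spont,
              bout_rate_evoked=config.bout_rate_evoked)
    return BehaviorSim(vr=vr, vigor=TimeSeries(vigor, rate), bouts=table,
                       eyes=eyes, cycle_hz=fc, ground_truth=gt)


def _simulate_eyes(protocol, config, rng, t):
    """Eyes follow the windmill velocity with per-epoch gain/latency jitter
    plus slow drift; saccade-free by construction."""
    rate = config.ephys_rate
    pos = {side: np.zeros(t.size) for side in ("left", "right")}
    for _, ep in protocol.windmill_epochs().iterrows():
        lat = rng.uniform(*config.eye_latency_range)
        for side in ("left", "right"):
            g = config.eye_gain * max(rng.normal(1.0, config.eye_gain_cv), 0.1)
            m = (t >= ep["t_on"] + lat) & (t < ep["t_off"] + lat)
            pos[side][m] = g * np.sin(
                2 * np.pi * ep["freq_hz"] * (t[m] - ep["t_on"] - lat))
    # slow drift: heavily smoothed white noise
    b, a = signal.butter(2, min(0.5 / (rate / 2.0), 0.99))
    for side in ("left", "right"):
        drift = signal.lfilter(b, a, rng.normal(0, config.eye_noise_sd, t.size))
        pos[side] = pos[side] + drift
    return (TimeSeries(pos["left"], rate), TimeSeries(pos["right"], rate))


# ---------------------------------------------------------------------------
# cells
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCell:
    cell_id: str
    phenotype: str
    position: tuple                 # (x, y, z) micrometres
    hemisphere: str                 # L | R from sign(x)
    preferred_direction: str | None
    cs: SpikeTrain
    ss: SpikeTrain
    ground_truth: dict = field(default_factory=dict)


# phenotype region centres (x, y, z) in micrometres; rostral = +y
_REGION = {
    "motion_onset": (15.0, 60.0, 0.0),        # rostromedial
    "rotational_velocity": (45.0, -60.0, 0.0),  # caudolateral
    "luminance": (30.0, 0.0, 0.0),            # central
    "motor": (30.0, 0.0, 0.0),                # scattered (wide sd below)
    "granule": (20.0, 0.0, -20.0),
}
_REGION_SD = {"motion_onset": 12.0, "rotational_velocity": 12.0,
              "luminance": 15.0, "motor": 40.0, "granule": 25.0}


def _draw_position(phenotype: str, rng: np.random.Generator) -> tuple:
    cx, cy, cz = _REGION[phenotype]
    sd = _REGION_SD[phenotype]
    hemi = 1.0 if rng.uniform() < 0.5 else -1.0
    x = hemi * abs(rng.normal(cx, sd))
    y = rng.normal(cy, sd)
    z = rng.normal(cz, sd / 2)
    return (float(x), float(y), float(z))


def _cs_intensity_motion_onset(protocol, config, pref_dirs, rate):
    n = int(round(protocol.duration * rate))
    lam = np.full(n, config.cs_baseline["motion_onset"])
    w_rate = config.onset_spikes_per_window / config.onset_window
    for d in pref_dirs:
        for _, ep in protocol.motion_epochs(d).iterrows():
            i0 = int(round(ep["t_on"] * rate))
            i1 = min(int(round((ep["t_on"] + config.onset_window) * rate)), n)
            lam[i0:i1] = w_rate
    return lam


def _cs_intensity_rotational(protocol, config, pref_sign, rate):
    n = int(round(protocol.duration * rate))
    base = config.cs_baseline["rotational_velocity"]
    lam = np.full(n, base)
    t = np.arange(n) / rate
    for _, ep in protocol.windmill_epochs().iterrows():
        m = (t >= ep["t_on"]) & (t < ep["t_off"])
        v = np.sin(2 * np.pi * ep["freq_hz"] * (t[m] - ep["t_on"]))
        lam[m] = np.where(np.sign(v) == pref_sign, base * config.rot_gain,
                          config.rot_nonpref_rate)
        i0 = int(round(ep["t_off"] * rate))
        i1 = min(int(round((ep["t_off"] + config.rot_depress_dur) * rate)), n)
        lam[i0:i1] = base * config.rot_depress_frac
    return lam


def _event_spikes(events, prob, latency, jitter_sd, rng):
    """Bernoulli per event: one spike at a fixed latency with small jitter."""
    hits = rng.uniform(size=len(events)) < prob
    times = np.asarray(events)[hits] + latency + rng.normal(0, jitter_sd, hits.sum())
    return np.sort(times)


def _ss_intensity(behavior: BehaviorSim, config: GeneratorConfig,
                  rest: float, bout_rate: float) -> np.ndarray:
    """Rest rate outside bouts; inside bouts scaled linearly with planted
    vigor, normalized so the time-mean in-bout rate equals ``bout_rate``."""
    v = behavior.vigor.data
    inbout = behavior.bouts.indicator(v.size, behavior.vigor.rate)
    lam = np.full(v.size, rest)
    if inbout.any():
        vbar = v[inbout].mean()
        if vbar > 0:
            lam[inbout] = bout_rate * v[inbout] / vbar
    return lam


def _apply_cs_gain_windows(lam, cs_times, behavior, config, rate):
    """Optional multiplicative post-CS gain window on the SS intensity; the
    window is shorter when the CS falls inside a fictive bout."""
    if config.cs_ss_gain is None:
        return lam
    lam = lam.copy()
    in_bout = behavior.bouts.contains(cs_times)
    for t_cs, motor in zip(cs_times, in_bout):
        w = config.cs_ss_window_motor if motor else config.cs_ss_window_nonmotor
        i0 = int(round(t_cs * rate))
        i1 = min(int(round((t_cs + w) * rate)), lam.size)
        lam[i0:i1] *= config.cs_ss_gain
    return lam


def simulate_purkinje(protocol: StimulusProtocol, behavior: BehaviorSim,
                      phenotype: str, config: GeneratorConfig,
                      cell_id: str = "pc0",
                      rng: np.random.Generator | None = None) -> SyntheticCell:
    """One Purkinje cell: phenotype-tuned complex spikes plus vigor-graded
    simple spikes, both as dead-time-compensated Poisson processes."""
    if phenotype not in PHENOTYPES[:4]:
        raise ValueError(f"unknown Purkinje phenotype: {phenotype!r}")
    if rng is None:
        rng = config.rng("purkinje", cell_id)
    rate = config.ephys_rate
    pos = _draw_position(phenotype, rng)
    hemi = "L" if pos[0] < 0 else "R"
    gt: dict = {"phenotype": phenotype,
                "cs_baseline": config.cs_baseline[phenotype],
                "ss_rest": config.ss_rest, "ss_bout": config.ss_bout}
    pref: str | None = None
    extra = np.empty(0)

    if phenotype == "motion_onset":
        i = int(rng.integers(len(CARDINALS)))
        pref_dirs = (CARDINALS[i], CARDINALS[(i + 1) % 4])  # two adjacent dirs
        pref = pref_dirs[0]
        lam = _cs_intensity_motion_onset(protocol, config, pref_dirs, rate)
        gt.update(preferred_directions=pref_dirs,
                  onset_spikes_per_window=config.onset_spikes_per_window)
    elif phenotype == "rotational_velocity":
        # clockwise-preferring cells sit in the left hemisphere and vice versa
        pref_sign = 1.0 if hemi == "L" else -1.0
        pref = "cw" if pref_sign > 0 else "ccw"
        lam = _cs_intensity_rotational(protocol, config, pref_sign, rate)
        gt.update(preferred_rotation=pref, rot_gain=config.rot_gain,
                  rot_nonpref_rate=config.rot_nonpref_rate,
                  rot_depress_frac=config.rot_depress_frac)
    elif phenotype == "luminance":
        lam = np.full(int(round(protocol.duration * rate)),
                      config.cs_baseline["luminance"])
        u = rng.uniform()
        pref_sign = 1 if u < 0.36 else (-1 if u < 0.80 else 0)  # 0 = both
        latency = rng.uniform(*config.lum_latency_range)
        trans = protocol.luminance_transitions()
        sel = trans if pref_sign == 0 else trans[trans["sign"] == pref_sign]
        extra = _event_spikes(sel["t"].to_numpy(), config.lum_spikes_per_transition,
                              latency, config.lum_jitter_sd, rng)
        pref = {1: "increase", -1: "decrease", 0: "both"}[pref_sign]
        gt.update(preferred_transition=pref, latency=latency,
                  lum_spikes_per_transition=config.lum_spikes_per_transition)
    else:  # motor
        lam = np.full(int(round(protocol.duration * rate)),
                      config.cs_baseline["motor"])
        onsets = behavior.bouts.onsets
        lat = rng.uniform(*config.motor_cs_latency_range, size=onsets.size)
        hits = rng.uniform(size=onsets.size) < config.motor_cs_prob
        extra = np.sort(onsets[hits] + lat[hits])
        gt.update(motor_cs_prob=config.motor_cs_prob)

    cs_times = sample_poisson_train(lam, protocol.duration, rng, rate,
                                    config.refractory)
    if extra.size:
        cs_times = _dead_time_filter(np.sort(np.concatenate([cs_times, extra])),
                                     config.refractory)
    cs_times = cs_times[cs_times < protocol.duration]

    lam_ss = _ss_intensity(behavior, config, config.ss_rest, config.ss_bout)
    lam_ss = _apply_cs_gain_windows(lam_ss, cs_times, behavior, config, rate)
    ss_times = sample_poisson_train(lam_ss, protocol.duration, rng, rate,
                                    config.refractory)
    if config.cs_ss_gain is not None:
        gt.update(cs_ss_gain=config.cs_ss_gain,
                  cs_ss_window_nonmotor=config.cs_ss_window_nonmotor,
                  cs_ss_window_motor=config.cs_ss_window_motor)
    return SyntheticCell(cell_id, phenotype, pos, hemi, pref,
                         SpikeTrain(cs_times, "complex"),
                         SpikeTrain(ss_times, "simple"), gt)


def simulate_granule(protocol: StimulusProtocol, behavior: BehaviorSim,
                     config: GeneratorConfig, cell_id: str = "gc0",
                     phase_locked: bool = False, phase: float = 0.0,
                     lock_depth: float = 0.8,
                     rng: np.random.Generator | None = None) -> SyntheticCell:
    """One granule cell: near-silent at rest, strongly motor-driven during
    bouts, optionally phase-locked to the ventral-root burst cycle."""
    if rng is None:
        rng = config.rng("granule", cell_id)
    rate = config.ephys_rate
    lam = _ss_intensity(behavior, config, config.gc_rest, config.gc_bout)
    if phase_locked:
        n = lam.size
        t = np.arange(n) / rate
        mod = np.ones(n)
        for t_on, t_off in zip(behavior.bouts.onsets, behavior.bouts.offsets):
            m = (t >= t_on) & (t < t_off)
            mod[m] = 1.0 + lock_depth * np.cos(
                2 * np.pi * behavior.cycle_hz * (t[m] - t_on) - phase)
        lam = lam * mod
    times = sample_poisson_train(lam, protocol.duration, rng, rate,
                                 config.refractory)
    pos = _draw_position("granule", rng)
    gt = dict(phenotype="granule", gc_rest=config.gc_rest,
              gc_bout=config.gc_bout, phase_locked=phase_locked,
              phase=phase, lock_depth=lock_depth if phase_locked else 0.0)
    return SyntheticCell(cell_id, "granule", pos, "L" if pos[0] < 0 else "R",
                         None, SpikeTrain(np.empty(0), "complex"),
                         SpikeTrain(times, "granule"), gt)


# ---------------------------------------------------------------------------
# calcium
# ---------------------------------------------------------------------------

def _exp_convolve_deltas(times: np.ndarray, amp: float, n: int, rate: float,
                         tau: float) -> np.ndarray:
    """amp * sum_i exp(-(t - t_i)/tau), sampled at ``rate`` (causal)."""
    deltas = np.zeros(n)
    idx = np.round(times * rate).astype(int)
    idx = idx[(idx >= 0) & (idx < n)]
    np.add.at(deltas, idx, amp)
    decay = np.exp(-1.0 / (rate * tau))
    return signal.lfilter([1.0], [1.0, -decay], deltas)


def simulate_calcium(cs: SpikeTrain, ss: SpikeTrain, config: GeneratorConfig,
                     duration: float | None = None, noise: bool = True,
                     rng: np.random.Generator | None = None) -> TimeSeries:
    """dF/F = A_cs*(delta_cs (x) k_tau) + A_ss*(delta_ss (x) k_tau) + noise.

    A_cs exceeds A_ss by the Campbell-calibrated ratio so that, at the default
    paired-recording spike statistics, complex spikes carry the default share
    of the signal variance.
    """
    if rng is None:
        rng = config.rng("calcium")
    if duration is None:
        duration = max(cs.times.max(initial=0.0), ss.times.max(initial=0.0)) + 5 * config.ca_tau
    rate = config.imaging_rate
    n = int(round(duration * rate))
    a_ss = config.ca_a_ss
    a_cs = a_ss * calcium_amplitude_ratio(config)
    if a_cs < 0 or a_ss < 0:
        raise ValueError("calcium amplitudes must be non-negative")
    dff = (_exp_convolve_deltas(cs.times, a_cs, n, rate, config.ca_tau)
           + _exp_convolve_deltas(ss.times, a_ss, n, rate, config.ca_tau))
    if noise:
        dff = dff + rng.normal(0.0, config.ca_noise_sd, n)
    return TimeSeries(dff, rate)


def simulate_paired_recordings(config: GeneratorConfig, n_cells: int = 8):
    """Paired ephys+calcium recordings at the default stationary rates.

    Returns a list of (dff, cs, ss) triples used for the CS/SS calcium-source
    decomposition study.
    """
    out = []
    for i in range(n_cells):
        rng = config.rng("paired", i)
        cs = SpikeTrain(sample_poisson_train(
            config.paired_cs_rate, config.paired_duration, rng,
            config.ephys_rate, config.refractory), "complex")
        ss = SpikeTrain(sample_poisson_train(
            config.paired_ss_rate, config.paired_duration, rng,
            config.ephys_rate, config.refractory), "simple")
        dff = simulate_calcium(cs, ss, config, duration=config.paired_duration,
                               noise=True, rng=rng)
        out.append((dff, cs, ss))
    return out


# ---------------------------------------------------------------------------
# volumes and morphologies
# ---------------------------------------------------------------------------

def simulate_nuclei_volume(n_nuclei: int | None = None, shape: tuple | None = None,
                           config: GeneratorConfig | None = None,
                           centers: np.ndarray | None = None,
                           rng: np.random.Generator | None = None):
    """Volume of non-overlapping spherical-Gaussian nuclei plus noise.

    Returns ``(volume, centers)`` with centers in (z, y, x) voxel coordinates
    as the planted ground truth. Raises if a feasible non-overlapping packing
    cannot be found within bounded retries, or if explicit ``centers`` violate
    the 2-sigma overlap precondition.
    """
    config = config or GeneratorConfig()
    n_nuclei = config.n_nuclei if n_nuclei is None else int(n_nuclei)
    shape = tuple(config.volume_shape if shape is None else shape)
    if rng is None:
        rng = config.rng("volume")
    sig = config.nucleus_sigma
    margin = 3.0 * sig

    if centers is not None:
        centers = np.asarray(centers, dtype=float)
        if len(centers) >= 2:
            from scipy.spatial.distance import pdist
            if pdist(centers).min() < 2.0 * sig:
                raise ValueError("nucleus centers closer than 2 sigma overlap")
    else:
        centers_list: list[np.ndarray] = []
        max_tries = 200 * max(n_nuclei, 1)
        tries = 0
        while len(centers_list) < n_nuclei:
            tries += 1
            if tries > max_tries:
                raise RuntimeError("could not place nuclei without overlap")
            c = np.array([rng.uniform(margin, s - margin) for s in shape])
            if centers_list:
                d = np.linalg.norm(np.asarray(centers_list) - c, axis=1)
                if d.min() < config.nucleus_min_sep:
                    continue
            centers_list.append(c)
        centers = (np.asarray(centers_list) if centers_list
                   else np.empty((0, 3)))

    vol = np.zeros(shape, dtype=float)
    r = int(np.ceil(3.5 * sig))
    for c in centers:
        lo = np.maximum(np.round(c).astype(int) - r, 0)
        hi = np.minimum(np.round(c).astype(int) + r + 1, shape)
        zz, yy, xx = np.meshgrid(*[np.arange(a, b) for a, b in zip(lo, hi)],
                                 indexing="ij")
        d2 = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
        vol[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += np.exp(-d2 / (2 * sig ** 2))
    vol += rng.normal(0.0, 1.0 / config.volume_snr, shape)
    return vol, centers


def simulate_morphology(planarity_target: float, n_points: int = 500,
                        config: GeneratorConfig | None = None,
                        rng: np.random.Generator | None = None) -> np.ndarray:
    """Anisotropic Gaussian point cloud with planted PC3/PC2 variance ratio."""
    if not 0.0 <= planarity_target <= 1.0:
        raise ValueError("planarity target must be in [0, 1]")
    config = config or GeneratorConfig()
    if rng is None:
        rng = config.rng("morphology")
    variances = np.array([1.0, 0.4, 0.4 * planarity_target])
    pts = rng.normal(size=(n_points, 3)) * np.sqrt(variances)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    return pts @ q.T


# ---------------------------------------------------------------------------
# raw ephys rendering (for spike-sorting round trips)
# ---------------------------------------------------------------------------

def render_ephys_trace(cs: SpikeTrain, ss: SpikeTrain, rate: float,
                       duration: float, cs_amp: float = 10.0,
                       ss_amp: float = 2.0, noise_sd: float = 0.1,
                       rng: np.random.Generator | None = None) -> TimeSeries:
    """Cell-attached-like voltage trace: large multiphasic complex-spike
    waveforms, small brief simple-spike waveforms, Gaussian noise."""
    if rng is None:
        rng = np.random.default_rng(0)
    n = int(round(duration * rate))
    trace = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)

    def waveform(width_s, amp, wobble=0.0):
        w = max(int(round(width_s * rate)), 3)
        x = np.linspace(0, np.pi, w)
        shape = np.sin(x)
        if wobble:
            shape = shape * (1 + wobble * np.sin(3 * x))
        return amp * shape / shape.max()

    for train, amp, width, wob in ((ss, ss_amp, 0.001, 0.0),
                                   (cs, cs_amp, 0.003, 0.3)):
        wf = waveform(width, amp, wob)
        half = wf.argmax()
        for t in train.times:
            i = int(round(t * rate)) - half
            j0, j1 = max(i, 0), min(i + wf.size, n)
            if j1 > j0:
                trace[j0:j1] += wf[j0 - i:j1 - i]
    return TimeSeries(trace, rate)


# ---------------------------------------------------------------------------
# session assembly
# ---------------------------------------------------------------------------

@dataclass
class Session:
    config: GeneratorConfig
    protocol: StimulusProtocol
    behavior: BehaviorSim
    cells: list

    @property
    def ground_truth(self) -> dict:
        gt = {"behavior": self.behavior.ground_truth}
        gt.update({c.cell_id: c.ground_truth for c in self.cells})
        return gt


def make_session(config: GeneratorConfig, n_granule: int = 0) -> Session:
    """Full synthetic session: protocol, behavior, and a population of cells
    drawn from ``config.phenotype_mix`` (plus optional granule cells)."""
    protocol = make_protocol(config)
    behavior = simulate_behavior(protocol, config)
    cells = []
    k = 0
    for phen, count in config.phenotype_mix.items():
        for _ in range(count):
            cells.append(simulate_purkinje(protocol, behavior, phen, config,
                                           cell_id=f"pc{k:03d}"))
            k += 1
    for g in range(n_granule):
        cells.append(simulate_granule(protocol, behavior, config,
                                      cell_id=f"gc{g:03d}"))
    return Session(config, protocol, behavior, cells)
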