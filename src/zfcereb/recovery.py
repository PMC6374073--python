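"""End-to-end parameter-recovery measurements on defaults-generated data.

Each routine generates synthetic sessions at the generator defaults, runs the
full analysis pipeline (envelope -> bout detection -> spike statistics ->
regression) on them, and returns the recovered population statistic. These
are the quantities the synthetic defaults plant, so agreement validates the
whole chain from raw traces to summary numbers.
"""
from __future__ import annotations

import numpy as np

from .core import SpikeTrain
from .synth import (GeneratorConfig, make_protocol, simulate_behavior,
                    simulate_purkinje, simulate_granule, simulate_calcium,
                    simulate_paired_recordings, simulate_nuclei_volume)
from .behavior import envelope, detect_bouts, rest_threshold, swim_frequency
from .spikes import baseline_rate
from .encoding import decompose_calcium
from .anatomy import count_nuclei

__all__ = ["recover_nucleus_count", "recover_swim_frequency",
           "recover_population_rates", "recover_granule_rates",
           "recover_calcium_tau", "recover_calcium_decomposition"]


def _session_bouts(vr, threshold_k: float = 3.0, min_duration: float = 0.05):
    env = envelope(vr, 0.010)
    thr = rest_threshold(env, threshold_k)
    return env, thr, detect_bouts(env, thr, merge_gap=0.100,
                                  min_duration=min_duration)


def recover_nucleus_count(seed: int) -> dict:
    """Template-matching count on one default nuclear-GCaMP volume."""
    config = GeneratorConfig(seed=seed)
    vol, centers = simulate_nuclei_volume(config=config)
    det = count_nuclei(vol, sigma=config.nucleus_sigma)
    return {"count": det.count, "n_planted": len(centers)}


def recover_swim_frequency(seed: int, n_fish: int = 30) -> dict:
    """Mean first-peak VR autocorrelation frequency over synthetic fish."""
    freqs = []
    for i in range(n_fish):
        config = GeneratorConfig(seed=seed + i, n_trials=2, n_blank_trials=2)
        protocol = make_protocol(config)
        behavior = simulate_behavior(protocol, config)
        env, thr, bouts = _session_bouts(behavior.vr)
        f, _ = swim_frequency(env, thr, bouts=bouts, seed=seed + i)
        if np.isfinite(f):
            freqs.append(f)
    return {"mean_hz": float(np.mean(freqs)), "n_fish": len(freqs),
            "planted_hz": GeneratorConfig().vr_cycle_hz}


def recover_population_rates(seed: int, phenotype_mix: dict | None = None) -> dict:
    """Full-pipeline recovery over a default 61-cell Purkinje population.

    One synthetic fish (behavior session) per cell, as in the recordings this
    emulates. Returns population means of: simple-spike rate inside/outside
    detected bouts, blank-trial complex-spike baseline per phenotype,
    complex spikes per preferred motion-onset window, and the percent
    complex-spike rate increase during preferred rotation.
    """
    base = GeneratorConfig(seed=seed)
    mix = phenotype_mix or base.phenotype_mix
    ss_in, ss_out = [], []
    cs_base = {p: [] for p in mix}
    onset_counts = []
    rot_increase = []
    cell_idx = 0
    for phen, count in mix.items():
        for _ in range(count):
            config = GeneratorConfig(seed=seed + 1000 + cell_idx)
            protocol = make_protocol(config)
            behavior = simulate_behavior(protocol, config)
            cell = simulate_purkinje(protocol, behavior, phen, config,
                                     cell_id=f"pc{cell_idx:03d}")
            _, _, bouts = _session_bouts(behavior.vr)

            # simple-spike rates in and out of detected bouts
            t_total = protocol.duration
            t_in = bouts.total_duration
            n_in = sum(cell.ss.count_in(a, b)
                       for a, b in zip(bouts.onsets, bouts.offsets))
            if t_in > 0:
                ss_in.append(n_in / t_in)
            ss_out.append((cell.ss.n - n_in) / (t_total - t_in))

            cs_base[phen].append(baseline_rate(cell.cs, protocol))

            if phen == "motion_onset":
                prefs = cell.ground_truth["preferred_directions"]
                counts = [cell.cs.count_in(a, a + config.onset_window)
                          for d in prefs
                          for a in protocol.motion_epochs(d)["t_on"]]
                if counts:
                    onset_counts.append(float(np.mean(counts)))
            elif phen == "rotational_velocity":
                sign = 1.0 if cell.ground_truth["preferred_rotation"] == "cw" else -1.0
                n_cs, t_pref = _preferred_rotation_rate(cell.cs, protocol, sign)
                base_rate = cs_base[phen][-1]
                if t_pref > 0 and base_rate > 0:
                    rate_pref = n_cs / t_pref
                    rot_increase.append(100.0 * (rate_pref - base_rate) / base_rate)
            cell_idx += 1
    return {
        "ss_inbout_hz": float(np.mean(ss_in)),
        "ss_rest_hz": float(np.mean(ss_out)),
        "cs_baseline_hz": {p: float(np.mean(v)) for p, v in cs_base.items() if v},
        "onset_spikes_per_window": float(np.mean(onset_counts)) if onset_counts else float("nan"),
        "rot_increase_percent": float(np.mean(rot_increase)) if rot_increase else float("nan"),
        "n_cells": cell_idx,
    }


def _preferred_rotation_rate(cs: SpikeTrain, protocol, pref_sign: float):
    """Spike count and total time within preferred-sign half-cycles of all
    windmill epochs (half-cycles are analytic for a sinusoidal velocity)."""
    n_cs = 0
    t_pref = 0.0
    for _, ep in protocol.windmill_epochs().iterrows():
        half = 0.5 / ep["freq_hz"]
        k = 0
        while ep["t_on"] + k * half < ep["t_off"]:
            a = ep["t_on"] + k * half
            b = min(a + half, ep["t_off"])
            sign = 1.0 if k % 2 == 0 else -1.0  # sin positive on first half
            if sign == pref_sign:
                n_cs += cs.count_in(a, b)
                t_pref += b - a
            k += 1
    return n_cs, t_pref


def recover_granule_rates(seed: int, n_cells: int = 6) -> dict:
    """In-bout and rest firing rates of motor-excited granule cells after
    pipeline bout detection, averaged over cells (one fish per cell)."""
    in_rates, rest_rates = [], []
    for i in range(n_cells):
        config = GeneratorConfig(seed=seed + 5000 + i)
        protocol = make_protocol(config)
        behavior = simulate_behavior(protocol, config)
        cell = simulate_granule(protocol, behavior, config, cell_id=f"gc{i}")
        _, _, bouts = _session_bouts(behavior.vr)
        t_in = bouts.total_duration
        n_in = sum(cell.ss.count_in(a, b)
                   for a, b in zip(bouts.onsets, bouts.offsets))
        if t_in > 0:
            in_rates.append(n_in / t_in)
        rest_rates.append((cell.ss.n - n_in) / (protocol.duration - t_in))
    return {"inbout_hz": float(np.mean(in_rates)),
            "rest_hz": float(np.mean(rest_rates)), "n_cells": n_cells}


def recover_calcium_tau(seed: int, n_spikes: int = 10) -> dict:
    """Decay constant of the noise-free CS-triggered calcium transient.

    Widely spaced complex spikes, noise off; spike-triggered transients are
    averaged and a single exponential is fitted to the decay phase by
    log-linear regression.
    """
    config = GeneratorConfig(seed=seed)
    spacing = 15.0  # s, >> tau so transients never overlap
    cs = SpikeTrain(spacing * np.arange(1, n_spikes + 1), "complex")
    dff = simulate_calcium(cs, SpikeTrain(np.empty(0)), config,
                           duration=spacing * (n_spikes + 1), noise=False)
    rate = dff.rate
    n_seg = int(round(6 * config.ca_tau * rate))
    segs = []
    for t in cs.times:
        i0 = dff.index_of(t)
        segs.append(dff.data[i0:i0 + n_seg])
    mean = np.mean(segs, axis=0)
    peak = int(np.argmax(mean))
    decay = mean[peak:]
    decay = decay[decay > 1e-12 * decay[0]]
    t_rel = np.arange(decay.size) / rate
    slope = np.polyfit(t_rel, np.log(decay), 1)[0]
    tau_ms = -1000.0 / slope
    return {"tau_ms": float(tau_ms), "n_spikes": n_spikes}


def recover_calcium_decomposition(seed: int, n_cells: int = 8) -> dict:
    """Mean CS percentage from the CS/SS regression decomposition over
    synthetic paired ephys+calcium recordings."""
    config = GeneratorConfig(seed=seed)
    shares = [decompose_calcium(dff, cs, ss)["cs_percent"]
              for dff, cs, ss in simulate_paired_recordings(config, n_cells)]
    return {"cs_percent_mean": float(np.mean(shares)), "n_cells": n_cells,
            "planted_percent": 100.0 * config.ca_cs_share}
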