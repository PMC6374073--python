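"""Generator contracts: protocol structure, determinism, planted rates,
calcium kernel analytics, volumes, and morphologies."""
import numpy as np
import pytest

from zfcereb.core import SpikeTrain
from zfcereb.synth import (GeneratorConfig, make_protocol, simulate_behavior,
                           simulate_purkinje, simulate_granule,
                           simulate_calcium, simulate_nuclei_volume,
                           simulate_morphology, sample_poisson_train,
                           calcium_amplitude_ratio, render_ephys_trace)


class TestProtocol:
    def test_forward_grating_speeds(self, protocol):
        speeds = sorted(protocol.motion_epochs("forward")["speed"].unique())
        assert speeds == [3.0, 10.0, 30.0]

    def test_lateral_and_reverse_at_medium_speed(self, protocol):
        for d in ("reverse", "left", "right"):
            assert set(protocol.motion_epochs(d)["speed"]) == {10.0}

    def test_windmill_velocity_zero_at_half_period(self, protocol):
        ep = protocol.windmill_epochs("whole").iloc[0]
        t = np.array([ep["t_on"], ep["t_on"] + 2.5])  # 0.2 Hz -> half period 2.5 s
        v = protocol.windmill_velocity(t)
        assert np.allclose(v, 0.0, atol=1e-9)

    def test_windmill_velocity_integrates_to_zero_per_cycle(self, protocol):
        ep = protocol.windmill_epochs("whole").iloc[0]
        t = ep["t_on"] + np.linspace(0, 5.0, 50001)  # one full cycle
        v = protocol.windmill_velocity(t)
        assert abs(np.trapezoid(v, t)) < 1e-6

    def test_blank_trials_have_no_moving_epochs(self, protocol):
        blanks = protocol.epochs[protocol.epochs["kind"] == "blank"]
        assert len(blanks) > 0
        assert (blanks["speed"] == 0).all()
        for a, b in protocol.blank_windows():
            moving = protocol.motion_epochs()
            assert not ((moving["t_on"] < b) & (moving["t_off"] > a)).any()

    def test_epochs_non_overlapping(self, protocol):
        e = protocol.epochs.sort_values("t_on")
        assert (e["t_on"].to_numpy()[1:] >= e["t_off"].to_numpy()[:-1] - 1e-9).all()


class TestDeterminism:
    def test_same_seed_identical_output(self):
        cfgs = [GeneratorConfig(seed=7, n_trials=1, n_blank_trials=1) for _ in range(2)]
        out = []
        for cfg in cfgs:
            prot = make_protocol(cfg)
            beh = simulate_behavior(prot, cfg)
            cell = simulate_purkinje(prot, beh, "rotational_velocity", cfg)
            out.append((beh.vr.data, cell.cs.times, cell.ss.times))
        assert np.array_equal(out[0][0], out[1][0])
        assert np.array_equal(out[0][1], out[1][1])
        assert np.array_equal(out[0][2], out[1][2])

    def test_different_seed_differs(self):
        a = simulate_behavior(make_protocol(GeneratorConfig(seed=1, n_trials=1)),
                              GeneratorConfig(seed=1, n_trials=1))
        b = simulate_behavior(make_protocol(GeneratorConfig(seed=2, n_trials=1)),
                              GeneratorConfig(seed=2, n_trials=1))
        assert not np.array_equal(a.vr.data, b.vr.data)


class TestPointProcess:
    def test_rate_contract_constant_intensity(self, rng):
        """Empirical rate converges to the planted rate (binomial tolerance)."""
        for r in (0.5, 5.0, 20.0):
            t = sample_poisson_train(r, 800.0, rng, 1000.0, 0.002)
            n = t.size
            assert abs(n - r * 800) < 4 * np.sqrt(r * 800)

    def test_refractory_floor(self, rng):
        t = sample_poisson_train(50.0, 100.0, rng, 1000.0, 0.002)
        assert np.diff(t).min() >= 0.002

    def test_zero_rate_empty(self, rng):
        assert sample_poisson_train(0.0, 100.0, rng).size == 0


class TestBehavior:
    def test_zero_bout_probability_pure_noise(self, protocol):
        cfg = GeneratorConfig(seed=3, n_trials=2, n_blank_trials=1,
                              bout_rate_spont=0.0, bout_rate_evoked=0.0)
        beh = simulate_behavior(protocol, cfg)
        assert len(beh.bouts) == 0
        assert abs(beh.vr.data.std() - cfg.vr_noise_sd) < 0.02

    def test_intra_bout_cycle_frequency(self, behavior_sim, config):
        """Spectral peak of the in-bout VR power lies at the planted cycle
        frequency within 5%."""
        vr, bouts = behavior_sim.vr, behavior_sim.bouts
        seg = np.concatenate([
            np.abs(vr.data[int(a * vr.rate):int(b * vr.rate)])
            for a, b in zip(bouts.onsets, bouts.offsets)])
        seg = seg - seg.mean()
        f = np.fft.rfftfreq(seg.size, 1 / vr.rate)
        p = np.abs(np.fft.rfft(seg)) ** 2
        band = (f > 10) & (f < 60)
        peak = f[band][np.argmax(p[band])]
        assert abs(peak - config.vr_cycle_hz) / config.vr_cycle_hz < 0.05

    def test_reverse_motion_does_not_drive_bouts(self):
        """Planted bout counts during reverse epochs match blank epochs."""
        rev_rate, blank_rate = [], []
        for s in range(25):
            cfg = GeneratorConfig(seed=100 + s, n_trials=2, n_blank_trials=1)
            prot = make_protocol(cfg)
            beh = simulate_behavior(prot, cfg)
            on = beh.bouts.onsets
            t_rev = n_rev = 0.0
            for _, ep in prot.motion_epochs("reverse").iterrows():
                t_rev += ep["t_off"] - ep["t_on"]
                n_rev += ((on >= ep["t_on"]) & (on < ep["t_off"])).sum()
            t_bl = n_bl = 0.0
            for a, b in prot.blank_windows():
                t_bl += b - a
                n_bl += ((on >= a) & (on < b)).sum()
            rev_rate.append(n_rev / t_rev)
            blank_rate.append(n_bl / t_bl)
        # same spontaneous rate in both conditions, far below the evoked rate
        assert abs(np.mean(rev_rate) - np.mean(blank_rate)) < 0.08
        assert np.mean(rev_rate) < 0.35

    def test_forward_motion_drives_bouts(self, behavior_sim, protocol, config):
        on = behavior_sim.bouts.onsets
        t_f = n_f = 0.0
        for _, ep in protocol.motion_epochs("forward").iterrows():
            t_f += ep["t_off"] - ep["t_on"]
            n_f += ((on >= ep["t_on"]) & (on < ep["t_off"])).sum()
        assert n_f / t_f > 2 * config.bout_rate_spont


class TestPurkinje:
    def test_unknown_phenotype_rejected(self, protocol, behavior_sim, config):
        with pytest.raises(ValueError, match="phenotype"):
            simulate_purkinje(protocol, behavior_sim, "nonsense", config)

    def test_baseline_poisson_without_stimuli(self):
        """Motion-onset CS over blank-only sessions is Poisson at the planted
        baseline rate."""
        cfg = GeneratorConfig(seed=5, n_trials=0, n_blank_trials=6,
                              bout_rate_spont=0.0)
        prot = make_protocol(cfg)
        beh = simulate_behavior(prot, cfg)
        counts = []
        for k in range(10):
            cell = simulate_purkinje(prot, beh, "motion_onset", cfg,
                                     cell_id=f"c{k}")
            counts.append(cell.cs.n)
        rate = np.sum(counts) / (10 * prot.duration)
        expect = cfg.cs_baseline["motion_onset"]
        assert abs(rate - expect) < 4 * np.sqrt(expect / (10 * prot.duration))

    def test_rotational_nonpreferred_suppression(self):
        """CS rate during non-preferred rotation falls below baseline."""
        cfg = GeneratorConfig(seed=11, n_trials=3, n_blank_trials=1)
        prot = make_protocol(cfg)
        beh = simulate_behavior(prot, cfg)
        n_np = t_np = 0.0
        cells = [simulate_purkinje(prot, beh, "rotational_velocity", cfg,
                                   cell_id=f"r{k}") for k in range(12)]
        for cell in cells:
            sign = 1.0 if cell.ground_truth["preferred_rotation"] == "cw" else -1.0
            for _, ep in prot.windmill_epochs().iterrows():
                half = 0.5 / ep["freq_hz"]
                k = 0
                while ep["t_on"] + k * half < ep["t_off"]:
                    a = ep["t_on"] + k * half
                    b = min(a + half, ep["t_off"])
                    s = 1.0 if k % 2 == 0 else -1.0
                    if s != sign:
                        n_np += cell.cs.count_in(a, b)
                        t_np += b - a
                    k += 1
        rate_np = n_np / t_np
        assert rate_np < cfg.cs_baseline["rotational_velocity"]
        assert abs(rate_np - cfg.rot_nonpref_rate) < 0.12

    def test_ss_rest_rate_without_bouts(self):
        cfg = GeneratorConfig(seed=2, n_trials=0, n_blank_trials=4,
                              bout_rate_spont=0.0)
        prot = make_protocol(cfg)
        beh = simulate_behavior(prot, cfg)
        cell = simulate_purkinje(prot, beh, "luminance", cfg)
        rate = cell.ss.n / prot.duration
        assert abs(rate - cfg.ss_rest) < 4 * np.sqrt(cfg.ss_rest / prot.duration)

    def test_granule_rest_rate_without_bouts(self):
        cfg = GeneratorConfig(seed=2, n_trials=0, n_blank_trials=4,
                              bout_rate_spont=0.0)
        prot = make_protocol(cfg)
        beh = simulate_behavior(prot, cfg)
        cell = simulate_granule(prot, beh, cfg)
        rate = cell.ss.n / prot.duration
        assert abs(rate - cfg.gc_rest) < 4 * np.sqrt(cfg.gc_rest / prot.duration)

    def test_ground_truth_records_planted_parameters(self, motion_onset_cell, config):
        gt = motion_onset_cell.ground_truth
        assert gt["cs_baseline"] == config.cs_baseline["motion_onset"]
        assert gt["onset_spikes_per_window"] == config.onset_spikes_per_window
        assert len(gt["preferred_directions"]) == 2


class TestGranulePhaseLocking:
    def test_phase_locked_autocorr_peak_at_cycle_period(self):
        """In-bout spike ACF of a phase-locked granule cell peaks at the VR
        cycle period."""
        from zfcereb.interactions import spike_autocorr_test
        cfg = GeneratorConfig(seed=8, n_trials=4, n_blank_trials=2)
        prot = make_protocol(cfg)
        beh = simulate_behavior(prot, cfg)
        cell = simulate_granule(prot, beh, cfg, phase_locked=True)
        acf, p = spike_autocorr_test(cell.ss, beh.bouts, max_lag=16)
        assert p < 0.001
        period_bins = (1.0 / cfg.vr_cycle_hz) / 0.005  # ~7.5 bins
        from scipy.signal import find_peaks
        peaks, _ = find_peaks(acf[1:])
        first = peaks[0] + 1
        assert abs(first - period_bins) <= 1.5


class TestCalcium:
    def test_single_cs_analytic_decay(self):
        cfg = GeneratorConfig(seed=0)
        cs = SpikeTrain([2.0], "complex")
        dff = simulate_calcium(cs, SpikeTrain([], "simple"), cfg,
                               duration=20.0, noise=False)
        a_cs = cfg.ca_a_ss * calcium_amplitude_ratio(cfg)
        i0 = dff.index_of(2.0)
        assert np.isclose(dff.data[i0], a_cs, rtol=1e-6)
        i_tau = dff.index_of(2.0 + cfg.ca_tau)
        assert np.isclose(dff.data[i_tau], a_cs * np.exp(-1), rtol=0.02)

    def test_no_spikes_no_noise_identically_zero(self):
        cfg = GeneratorConfig(seed=0)
        dff = simulate_calcium(SpikeTrain([], "complex"), SpikeTrain([], "simple"),
                               cfg, duration=10.0, noise=False)
        assert np.all(dff.data == 0)

    def test_spike_triggered_average_recovers_kernel(self, rng):
        """STA of a noisy Poisson-driven trace matches the exponential."""
        cfg = GeneratorConfig(seed=0, ca_noise_sd=0.02)
        times = np.sort(rng.uniform(5, 595, 120))
        ss = SpikeTrain(times, "simple")
        dff = simulate_calcium(SpikeTrain([], "complex"), ss, cfg,
                               duration=600.0, noise=True,
                               rng=np.random.default_rng(4))
        pre = int(1.0 * dff.rate)
        post = int(2 * cfg.ca_tau * dff.rate)
        segs = [dff.data[dff.index_of(t) - pre:dff.index_of(t) + post]
                for t in times
                if dff.index_of(t) >= pre and dff.index_of(t) + post <= dff.n]
        sta = np.mean(segs, axis=0)
        # overlap from neighbouring spikes contributes a near-constant floor;
        # subtract the pre-spike baseline and fit the early decay
        y = sta - sta[:pre].mean()
        t_rel = (np.arange(sta.size) - pre) / dff.rate
        sel = (t_rel > 0.05) & (t_rel < cfg.ca_tau) & (y > 0)
        sl = np.polyfit(t_rel[sel], np.log(y[sel]), 1)[0]
        assert abs(-1 / sl - cfg.ca_tau) / cfg.ca_tau < 0.2

    def test_negative_amplitude_rejected(self):
        cfg = GeneratorConfig(seed=0, ca_a_ss=-1.0)
        with pytest.raises(ValueError):
            simulate_calcium(SpikeTrain([1.0]), SpikeTrain([]), cfg, duration=5.0)


class TestVolume:
    def test_zero_nuclei_pure_noise(self):
        cfg = GeneratorConfig(seed=0)
        vol, centers = simulate_nuclei_volume(0, (24, 32, 32), cfg)
        assert len(centers) == 0
        assert abs(vol.std() - 1 / cfg.volume_snr) < 0.01

    def test_explicit_centers_too_close_rejected(self):
        cfg = GeneratorConfig(seed=0)
        centers = np.array([[10.0, 10.0, 10.0], [10.0, 10.0, 12.0]])
        with pytest.raises(ValueError, match="2 sigma"):
            simulate_nuclei_volume(2, (24, 32, 32), cfg, centers=centers)

    def test_infeasible_packing_raises(self):
        cfg = GeneratorConfig(seed=0)
        with pytest.raises(RuntimeError):
            simulate_nuclei_volume(500, (20, 20, 20), cfg)

    def test_centers_respect_min_separation(self):
        from scipy.spatial.distance import pdist
        cfg = GeneratorConfig(seed=1)
        _, centers = simulate_nuclei_volume(40, (32, 64, 64), cfg)
        assert pdist(centers).min() >= cfg.nucleus_min_sep


class TestMorphology:
    def test_target_zero_coplanar(self):
        pts = simulate_morphology(0.0, 200)
        from zfcereb.anatomy import planarity
        assert planarity(pts) < 1e-12

    def test_target_recovered_at_large_n(self):
        from zfcereb.anatomy import planarity
        for target in (0.3, 1.0):
            pts = simulate_morphology(target, 200_000)
            assert abs(planarity(pts) - target) < 0.05

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            simulate_morphology(1.5)


class TestRenderedTrace:
    def test_planted_amplitudes_at_spike_times(self):
        cs = SpikeTrain([0.5, 1.0], "complex")
        ss = SpikeTrain([0.2, 0.7], "simple")
        tr = render_ephys_trace(cs, ss, 1000.0, 2.0, noise_sd=0.0)
        for t in cs.times:
            assert tr.data[tr.index_of(t)] == pytest.approx(10.0, abs=0.3)
        for t in ss.times:
            assert tr.data[tr.index_of(t)] == pytest.approx(2.0, abs=0.1)
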