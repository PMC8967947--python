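"""Synthetic-signal generator: codebooks, determinism, signal model, SNR
and latency contracts, continuous-recording layout."""

import math

import numpy as np
import pytest

import zpfdcnn as z
from zpfdcnn.signal_gen import END_MARKER


class TestCodebook:
    def test_beta_preset(self):
        cb = z.make_codebook("beta")
        assert cb.n_targets == 40
        assert cb.frequencies[0] == pytest.approx(8.0)
        assert cb.frequencies[-1] == pytest.approx(15.8)
        assert np.allclose(np.diff(cb.frequencies), 0.2)
        assert cb.delta_f_stim == pytest.approx(0.2)
        # phases advance by 0.5*pi mod 2*pi, starting at 0
        expected = [(0.5 * math.pi * i) % (2 * math.pi) for i in range(40)]
        assert np.allclose(cb.phases, expected)

    def test_ssmvep_preset(self):
        cb = z.make_codebook("ssmvep")
        assert cb.n_targets == 35
        assert cb.frequencies[0] == pytest.approx(3.0)
        assert cb.frequencies[-1] == pytest.approx(20.0)
        assert cb.delta_f_stim == pytest.approx(0.5)
        assert np.allclose(cb.phases, 0.5 * math.pi)

    @pytest.mark.parametrize("kwargs", [
        dict(f_min=10, f_max=10, step=1),   # degenerate range
        dict(f_min=10, f_max=12, step=0),   # nonpositive step
        dict(f_min=12, f_max=10, step=1),   # reversed range
    ])
    def test_invalid_custom_grids(self, kwargs):
        with pytest.raises(ValueError):
            z.make_codebook(**kwargs)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            z.StimulusCodebook(frequencies=(10.0, 9.0), phases=(0.0, 0.0),
                               delta_f_stim=1.0)
        with pytest.raises(ValueError):
            z.StimulusCodebook(frequencies=(9.0, 10.0), phases=(0.0, 7.0),
                               delta_f_stim=1.0)


class TestSimulateEpochs:
    def test_noiseless_single_harmonic_is_exact_sinusoid(self, codebook8):
        cfg = z.SimulationConfig(noise_snr_db=math.inf, harmonic_amps=(1.0,),
                                 n_blocks=1, seed=3, latency_sd_s=0.0)
        ep = z.simulate_epochs(codebook8, cfg)
        t = np.arange(ep.n_samples) / cfg.fs
        k = 5
        f, ph = codebook8.frequencies[k], codebook8.phases[k]
        on = cfg.pre_stim_s + cfg.latency_mean_s
        active = (t >= on) & (t < on + cfg.stim_s)
        ref = np.zeros_like(t)
        ref[active] = np.sin(2 * np.pi * f * (t[active] - on) + ph)
        x = ep.values[0, :, 0, k]
        gain = x[active][3] / ref[active][3]
        assert 0.5 <= gain <= 1.0
        assert np.abs(x - gain * ref).max() < 1e-9
        # pre/post segments are silent without noise
        assert np.all(x[~active] == 0.0)

    def test_determinism(self, codebook8):
        cfg = z.SimulationConfig(noise_snr_db=-5.0, n_blocks=2, seed=1)
        a = z.simulate_epochs(codebook8, cfg)
        b = z.simulate_epochs(codebook8, cfg)
        assert np.array_equal(a.values, b.values)
        c = z.simulate_epochs(codebook8,
                              z.SimulationConfig(noise_snr_db=-5.0,
                                                 n_blocks=2, seed=2))
        assert not np.array_equal(a.values, c.values)

    def test_psd_peaks_at_fundamental_and_second_harmonic(self, codebook8):
        cfg = z.SimulationConfig(noise_snr_db=math.inf,
                                 harmonic_amps=(1.0, 0.5), n_blocks=1,
                                 seed=0, latency_sd_s=0.0)
        ep = z.simulate_epochs(codebook8, cfg)
        k = 2
        f = codebook8.frequencies[k]
        seg = z.sliding_segments(ep, 2.0, cfg.latency_mean_s, 0.1,
                                 block=0, stimulus=k)[0]
        scfg = z.SpectralConfig.for_segment(cfg.fs, codebook8.delta_f_stim,
                                            seg.values.shape[1])
        pv = z.psd(z.zero_pad(seg.values[0], scfg.n_total), cfg.fs)
        half = pv.values[: scfg.n_total // 2]
        # the two tallest spectral peaks (local maxima — neighbouring bins
        # ride the same sinc mainlobe) sit at f_k and 2 f_k
        from scipy.signal import find_peaks
        peaks, props = find_peaks(half, height=0.0)
        top2 = peaks[np.argsort(props["peak_heights"])[::-1][:2]]
        top2_hz = sorted(pv.bin_hz[top2])
        assert top2_hz[0] == pytest.approx(f, abs=scfg.bin_spacing_hz)
        assert top2_hz[1] == pytest.approx(2 * f, abs=scfg.bin_spacing_hz)

    def test_nyquist_guard(self, codebook8):
        cfg = z.SimulationConfig(fs=30.0, harmonic_amps=(1.0, 0.5))
        with pytest.raises(ValueError, match="Nyquist"):
            z.simulate_epochs(codebook8, cfg)

    def test_realized_snr_within_1db(self, codebook8):
        """Signal/noise power ratio over >=100 trials matches the config."""
        target_db = -8.0
        cfg = z.SimulationConfig(noise_snr_db=target_db, n_blocks=13, seed=5,
                                 latency_sd_s=0.0)
        noisy = z.simulate_epochs(codebook8, cfg)
        clean = z.simulate_epochs(
            codebook8,
            z.SimulationConfig(noise_snr_db=math.inf, n_blocks=13, seed=5,
                               latency_sd_s=0.0),
        )
        on = int(round((cfg.pre_stim_s + cfg.latency_mean_s) * cfg.fs))
        off = on + int(round(cfg.stim_s * cfg.fs))
        sig = clean.values[:, on:off]
        noise = noisy.values[:, on:off] - sig
        # 13 blocks x 8 stimuli = 104 trials
        ratio_db = 10 * np.log10(np.mean(sig ** 2) / np.mean(noise ** 2))
        assert abs(ratio_db - target_db) < 1.0

    def test_latency_recovered_by_cross_correlation(self, codebook8):
        cfg = z.SimulationConfig(noise_snr_db=20.0, n_blocks=3, seed=9,
                                 latency_mean_s=0.12, latency_sd_s=0.02)
        ep = z.simulate_epochs(codebook8, cfg)
        tmpl_cfg = z.SimulationConfig(noise_snr_db=math.inf, n_blocks=3,
                                      seed=9, latency_mean_s=0.0,
                                      latency_sd_s=0.0)
        tmpl = z.simulate_epochs(codebook8, tmpl_cfg)
        # the same seed draws the same per-block latencies
        rng = np.random.default_rng(cfg.seed)
        rng.uniform(0.5, 1.0, size=cfg.n_channels)  # skip channel gains
        drawn = np.clip(rng.normal(cfg.latency_mean_s, cfg.latency_sd_s,
                                   cfg.n_blocks), 0.0, None)
        k = 0
        for b in range(cfg.n_blocks):
            x = ep.values[8, :, b, k]
            ref = tmpl.values[8, :, b, k]
            lags = np.arange(-100, 101)
            corr = [np.dot(x, np.roll(ref, L)) for L in lags]
            lag = lags[int(np.argmax(corr))]
            expected = int(round(drawn[b] * cfg.fs))
            assert abs(lag - expected) <= 1


class TestSimulateContinuous:
    @pytest.fixture(scope="class")
    def recording(self):
        cb = z.make_codebook("ssmvep")
        cfg = z.make_sim_config("ssmvep", n_blocks=1, seed=4,
                                noise_snr_db=0.0)
        rec = z.simulate_continuous(cb, cfg, trial_s=5.0, rest_s=2.0)
        return cb, cfg, rec

    def test_one_onset_marker_per_stimulus(self, recording):
        cb, cfg, rec = recording
        track = rec.label_track
        onsets = track[(track > 0) & (track != END_MARKER)]
        assert len(onsets) == 35
        assert sorted(onsets.astype(int)) == list(range(1, 36))

    def test_marker_spacing_is_trial_length(self, recording):
        cb, cfg, rec = recording
        track = rec.label_track
        pos = np.flatnonzero((track > 0) & (track != END_MARKER))
        assert np.all(np.diff(pos) == int(round(5.0 * cfg.fs)))

    def test_round_trip_through_parse_continuous(self, recording):
        cb, cfg, rec = recording
        ep = z.parse_continuous(rec, pre_s=1.0, stim_s=3.0, post_s=1.0,
                                codebook=cb)
        assert ep.n_stimuli == 35
        track = rec.label_track
        pos = np.flatnonzero((track > 0) & (track != END_MARKER))
        n_pre = int(round(1.0 * cfg.fs))
        n_epoch = ep.n_samples
        for p in pos[:5]:
            k = int(track[p])
            direct = rec.data[:, p - n_pre:p - n_pre + n_epoch]
            assert np.array_equal(ep.values[:, :, 0, k - 1], direct)

    def test_trial_duration_mismatch_rejected(self):
        cb = z.make_codebook("ssmvep")
        cfg = z.make_sim_config("ssmvep")
        with pytest.raises(ValueError, match="stim_s"):
            z.simulate_continuous(cb, cfg, trial_s=4.0, rest_s=2.0)
        with pytest.raises(ValueError, match="rest_s"):
            z.simulate_continuous(cb, cfg, trial_s=2.0, rest_s=-1.0)
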