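"""Zero-padded DFT/PSD: padding arithmetic, transform oracle, leakage,
band extraction and feature-matrix assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import zpfdcnn as z
from zpfdcnn.preprocess import Segment


def dft_direct(x):
    """O(N^2) evaluation of X(m) = sum_n x(n) exp(-i 2 pi n m / N)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    m = np.arange(n)
    return np.exp(-2j * np.pi * np.outer(m, m % n) / n) @ x


class TestPaddedLength:
    @pytest.mark.parametrize("fs,df,expected", [
        (250.0, 0.2, 1250),
        (1000.0, 0.5, 2000),
        (250.0, 250.0, 1),
    ])
    def test_examples(self, fs, df, expected):
        assert z.padded_length(fs, df) == expected

    def test_misaligned_ratio_rejected(self):
        with pytest.raises(ValueError, match="align"):
            z.padded_length(250.0, 0.3)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            z.padded_length(0.0, 0.2)


class TestZeroPad:
    def test_definition(self):
        assert np.array_equal(z.zero_pad([1.0, 2.0], 5), [1, 2, 0, 0, 0])
        x = np.arange(4.0)
        assert np.array_equal(z.zero_pad(x, 4), x)

    def test_energy_preserved(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(100)
        assert np.sum(z.zero_pad(x, 1000) ** 2) == pytest.approx(
            np.sum(x ** 2))

    def test_truncation_rejected(self):
        with pytest.raises(ValueError):
            z.zero_pad(np.zeros(10), 5)


class TestDft:
    def test_dc_signal(self):
        s = z.dft([1.0, 1.0, 1.0, 1.0])
        assert s.values[0] == pytest.approx(4.0)
        assert np.abs(s.values[1:]).max() < 1e-12

    def test_on_bin_cosine_magnitude(self):
        n, k = 64, 5
        x = np.cos(2 * np.pi * k * np.arange(n) / n)
        s = z.dft(x)
        assert abs(s.values[k]) == pytest.approx(n / 2)

    def test_fast_transform_equals_direct_evaluation(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            x = rng.standard_normal(16)
            assert np.allclose(z.dft(x).values, dft_direct(x),
                               rtol=1e-9, atol=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            z.dft([])


class TestPsd:
    def test_zero_signal(self):
        assert np.all(z.psd(np.zeros(32), 250.0).values == 0.0)

    def test_on_bin_cosine_closed_form(self):
        # P(k) = (A*N/2)^2 / (fs*N)
        n, k, A, fs = 128, 7, 1.7, 250.0
        x = A * np.cos(2 * np.pi * k * np.arange(n) / n)
        pv = z.psd(x, fs)
        assert pv.values[k] == pytest.approx((A * n / 2) ** 2 / (fs * n))

    def test_padded_psd_scales_with_transform_length(self):
        # |X| is invariant at coincident bins, so P scales as 1/N_len
        rng = np.random.default_rng(1)
        x = rng.standard_normal(50)
        fs = 250.0
        p1 = z.psd(x, fs)
        p4 = z.psd(z.zero_pad(x, 200), fs)
        assert p4.values[4 * 7] == pytest.approx(p1.values[7] / 4)

    def test_invalid_fs(self):
        with pytest.raises(ValueError):
            z.psd(np.ones(8), 0.0)


class TestLeakage:
    def test_sinc_limit_and_zeros(self):
        assert z.leakage_amplitude(12, 12, 100) == pytest.approx(50.0)
        assert z.leakage_amplitude(12, 9, 100) == pytest.approx(0.0, abs=1e-12)

    def test_half_bin_offset(self):
        assert z.leakage_amplitude(12.5, 12, 100) == pytest.approx(
            100 / np.pi, rel=1e-9)


class TestSpectralIdentity:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 10 ** 9))
    def test_padded_spectrum_interpolates_unpadded(self, seed):
        """X_padded(m*(M+N)/N) == X_unpadded(m) wherever the index is integer."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 64))
        mult = int(rng.integers(2, 6))
        x = rng.standard_normal(n)
        xu = z.dft(x).values
        xp = z.dft(z.zero_pad(x, mult * n)).values
        assert np.allclose(xp[::mult], xu, rtol=1e-9, atol=1e-9)


class TestBandBins:
    def test_beta_grid(self):
        cb = z.make_codebook("beta")
        cfg = z.SpectralConfig.for_segment(250.0, 0.2, 250)
        b1 = z.band_bins(cb, 1, cfg)
        assert list(b1) == list(range(40, 80))
        b2 = z.band_bins(cb, 2, cfg)
        assert cfg.bin_spacing_hz * b2[0] == pytest.approx(16.0)
        assert cfg.bin_spacing_hz * b2[-1] == pytest.approx(31.6)

    def test_ssmvep_grid(self):
        cb = z.make_codebook("ssmvep")
        cfg = z.SpectralConfig.for_segment(1000.0, 0.5, 1000)
        b1 = z.band_bins(cb, 1, cfg)
        assert len(b1) == 35
        assert cfg.bin_spacing_hz * b1[0] == pytest.approx(3.0)
        assert cfg.bin_spacing_hz * b1[-1] == pytest.approx(20.0)

    def test_harmonic_beyond_nyquist_rejected(self):
        cb = z.make_codebook("beta")
        cfg = z.SpectralConfig.for_segment(250.0, 0.2, 250)
        with pytest.raises(ValueError, match="Nyquist"):
            z.band_bins(cb, 8, cfg)


class TestFeatureMatrix:
    def test_beta_preset_is_80_by_9(self):
        cb = z.make_codebook("beta")
        rng = np.random.default_rng(0)
        seg = Segment(values=rng.standard_normal((9, 250)), fs=250.0,
                      label=1, window_s=1.0)
        fm = z.build_feature_matrix(seg, cb, n_bands=2)
        assert fm.values.shape == (80, 9)
        assert fm.values.min() == pytest.approx(0.0)
        assert fm.values.max() == pytest.approx(1.0)

    def test_noiseless_class_argmax_on_own_row(self, codebook8,
                                               noiseless_epochs):
        for k in range(8):
            seg = z.sliding_segments(noiseless_epochs, 1.0, 0.13, 0.1,
                                     block=0, stimulus=k)[0]
            fm = z.build_feature_matrix(seg, codebook8, n_bands=1)
            assert list(fm.values.argmax(axis=0)) == [k] * 9
            assert fm.label == k + 1

    def test_constant_segment_maps_to_zeros(self, codebook8):
        seg = Segment(values=np.full((9, 250), 3.3), fs=250.0, label=2,
                      window_s=1.0)
        fm = z.build_feature_matrix(seg, codebook8, n_bands=2)
        assert np.all(fm.values == 0.0)

    def test_rescale_is_gain_invariant(self, codebook8, noiseless_epochs):
        seg = z.sliding_segments(noiseless_epochs, 1.0, 0.13, 0.1,
                                 block=0, stimulus=4)[0]
        fm1 = z.build_feature_matrix(seg, codebook8, n_bands=2)
        scaled = Segment(values=seg.values * 7.5, fs=seg.fs, label=seg.label,
                         window_s=seg.window_s)
        fm2 = z.build_feature_matrix(scaled, codebook8, n_bands=2)
        assert np.allclose(fm1.values, fm2.values, atol=1e-9)

    def test_band_layout_records_bin_frequencies(self, codebook8,
                                                 noiseless_epochs):
        seg = z.sliding_segments(noiseless_epochs, 1.0, 0.13, 0.1,
                                 block=0, stimulus=0)[0]
        fm = z.build_feature_matrix(seg, codebook8, n_bands=2)
        (h1, f1), (h2, f2) = fm.band_layout
        assert (h1, h2) == (1, 2)
        assert np.allclose(f1, codebook8.frequencies)
        assert np.allclose(f2, np.asarray(codebook8.frequencies) * 2)

    def test_zero_padding_separates_adjacent_classes_better(self, codebook8):
        """Padded features spread adjacent classes further apart than
        non-padded features (mean between-class distance, noisy segments)."""
        cb = z.make_codebook("beta")
        cfg = z.SimulationConfig(noise_snr_db=-8.0, n_blocks=19, seed=22)
        ep = z.simulate_epochs(cb, cfg)
        # adjacent stimulation frequencies 11.6/11.8/12.0 Hz: at a 1 s
        # window the non-padded 1 Hz grid reads all three from the same
        # coarse bin; 19 blocks x 11 windows > 200 segments per class
        classes = [18, 19, 20]
        feats = {True: {}, False: {}}
        for padded in (True, False):
            for k in classes:
                rows = []
                for b in range(ep.n_blocks):
                    for seg in z.sliding_segments(ep, 1.0, 0.13, 0.1,
                                                  block=b, stimulus=k):
                        fm = z.build_feature_matrix(seg, cb,
                                                    n_bands=2, padded=padded)
                        rows.append(fm.values.ravel())
                feats[padded][k] = np.asarray(rows)
                assert len(rows) >= 200

        def mean_between(d):
            dists = []
            for i, a in enumerate(classes):
                for bcls in classes[i + 1:]:
                    ma = d[a].mean(axis=0)
                    mb = d[bcls].mean(axis=0)
                    dists.append(np.linalg.norm(ma - mb))
            return np.mean(dists)

        assert mean_between(feats[True]) > mean_between(feats[False])
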