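"""Zero-padded DFT/PSD features with stimulus-aligned bins.

An N-point DFT only exposes the spectrum on the grid fs/N — the picket
fence effect.  When the stimulation frequencies sit 0.2 Hz apart and the
analysis window is one second, that grid (1 Hz) cannot separate them.
Appending M zeros before the transform evaluates the *same* underlying
spectrum on the finer grid fs/(N+M) without adding information; choosing
N+M = fs/delta_f puts a bin exactly on every stimulation frequency and on
every harmonic h*f_k.  The feature for a windowed segment is the PSD
P(m) = |X(m)|^2 / (fs*N_len) sampled at those aligned bins, one column per
channel, min-max rescaled to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_gen import StimulusCodebook

__all__ = [
    "SpectralConfig",
    "Spectrum",
    "PsdVector",
    "FeatureMatrix",
    "padded_length",
    "zero_pad",
    "dft",
    "psd",
    "leakage_amplitude",
    "band_bins",
    "build_feature_matrix",
]


@dataclass(frozen=True)
class SpectralConfig:
    """Transform geometry: sampling rate, target bin spacing, lengths.

    ``n_total`` is the post-padding transform length; it equals
    ``round(fs / delta_f_target)`` raised to the next multiple when the
    signal is longer (padding never truncates and alignment is preserved,
    since every multiple keeps the stimulus frequencies on-bin).
    """

    fs: float
    delta_f_target: float
    n_signal: int
    n_total: int

    def __post_init__(self):
        if self.n_total < self.n_signal:
            raise ValueError("n_total must be >= n_signal (padding never "
                             "truncates)")
        base = padded_length(self.fs, self.delta_f_target)
        if self.n_total % base != 0:
            raise ValueError(
                f"n_total={self.n_total} is not a multiple of "
                f"round(fs/delta_f)={base}; bins would miss the stimulus grid"
            )

    @property
    def bin_spacing_hz(self) -> float:
        return self.fs / self.n_total

    @classmethod
    def for_segment(
        cls, fs: float, delta_f_target: float, n_signal: int
    ) -> "SpectralConfig":
        base = padded_length(fs, delta_f_target)
        n_total = base * max(1, -(-n_signal // base))  # ceil division
        return cls(fs=fs, delta_f_target=delta_f_target,
                   n_signal=n_signal, n_total=n_total)


@dataclass(frozen=True)
class Spectrum:
    """Complex DFT values with their bin frequencies."""

    values: np.ndarray
    bin_hz: np.ndarray
    fs: float


@dataclass(frozen=True)
class PsdVector:
    """Real nonnegative power spectral density per bin."""

    values: np.ndarray
    bin_hz: np.ndarray
    fs: float


@dataclass(frozen=True)
class FeatureMatrix:
    """bins x channels PSD amplitudes rescaled to [0, 1].

    ``band_layout`` lists, per harmonic band h, the bin frequencies its rows
    sample (h*f_k for every stimulation frequency f_k).  ``label`` is the
    1-based stimulus index, or 0 when unknown.
    """

    values: np.ndarray
    band_layout: tuple
    label: int

    def __post_init__(self):
        v = self.values
        if v.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if v.size and (v.min() < -1e-9 or v.max() > 1.0 + 1e-9):
            raise ValueError("feature matrix must be rescaled to [0, 1]")


def padded_length(fs: float, delta_f_target: float) -> int:
    """Transform length whose bin spacing equals ``delta_f_target``.

    The padded length N+M must satisfy delta_f = fs/(N+M), so fs/delta_f has
    to be (numerically) an integer or the bins cannot land on the stimulus
    grid.
    """
    if fs <= 0 or delta_f_target <= 0:
        raise ValueError("fs and delta_f_target must be positive")
    ratio = fs / delta_f_target
    n = round(ratio)
    if n < 1 or abs(ratio - n) > 1e-6 * max(1.0, ratio):
        raise ValueError(
            f"fs/delta_f_target = {ratio} is not an integer; DFT bins "
            "cannot align with the stimulation-frequency grid"
        )
    return int(n)


def zero_pad(x: np.ndarray, n_total: int) -> np.ndarray:
    """Append zeros up to length ``n_total`` (last axis untouched elsewhere)."""
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if n_total < n:
        raise ValueError(f"n_total={n_total} < signal length {n}")
    if n_total == n:
        return x.copy()
    pad = [(0, 0)] * (x.ndim - 1) + [(0, n_total - n)]
    return np.pad(x, pad)


def dft(x: np.ndarray) -> Spectrum:
    """Full (two-sided) DFT X(m) = sum_n x(n) exp(-i 2 pi n m / N)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    if not np.all(np.isfinite(x)):
        raise ValueError("input must be finite")
    n = x.shape[-1]
    values = np.fft.fft(x, axis=-1)
    # fs unknown here; bin_hz in cycles-per-window units is m/N * fs — the
    # caller supplies fs via psd(); expose normalized bins when standalone.
    bin_hz = np.arange(n) / n
    return Spectrum(values=values, bin_hz=bin_hz, fs=float("nan"))


def psd(x: np.ndarray, fs: float) -> PsdVector:
    """Discrete PSD P(m) = |X(m)|^2 / (fs * N_len), N_len the transform length."""
    if fs <= 0:
        raise ValueError("fs must be positive")
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    n = x.shape[-1]
    spec = np.fft.fft(x, axis=-1)
    values = (spec.real ** 2 + spec.imag ** 2) / (fs * n)
    bin_hz = np.arange(n) * (fs / n)
    return PsdVector(values=values, bin_hz=bin_hz, fs=fs)


def leakage_amplitude(k: float, m: float, n: int) -> float:
    """Rectangular-window leakage of a k-cycle cosine onto bin m.

    The N-point DFT of a cosine completing k (possibly fractional) cycles in
    the window responds on bin m with magnitude approximately
    N/2 * sinc(k - m); at k = m the limit is N/2.  Integer nonzero offsets
    fall on sinc zeros, which is why an aligned (on-bin) grid suppresses
    cross-talk between stimulation frequencies.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    return 0.5 * n * float(np.sinc(k - m))


def band_bins(
    codebook: StimulusCodebook, harmonic: int, cfg: SpectralConfig
) -> np.ndarray:
    """Bin indices of harmonic h of every stimulation frequency.

    index_k = round(h * f_k / bin_spacing); every h*f_k must land exactly on
    the padded grid and stay below Nyquist.
    """
    if harmonic < 1:
        raise ValueError("harmonic must be >= 1")
    freqs = np.asarray(codebook.frequencies, dtype=float) * harmonic
    spacing = cfg.bin_spacing_hz
    ratio = freqs / spacing
    idx = np.round(ratio).astype(int)
    if np.any(np.abs(ratio - idx) > 1e-6 * np.maximum(1.0, ratio)):
        bad = freqs[np.abs(ratio - idx) > 1e-6 * np.maximum(1.0, ratio)]
        raise ValueError(
            f"harmonic {harmonic} frequencies {bad.tolist()} do not align "
            f"with the {spacing} Hz bin grid"
        )
    if freqs.max() >= cfg.fs / 2:
        raise ValueError(
            f"harmonic {harmonic} band reaches {freqs.max()} Hz, beyond "
            f"Nyquist {cfg.fs / 2} Hz"
        )
    return idx


def _rescale_zero_one(m: np.ndarray) -> np.ndarray:
    lo, hi = float(m.min()), float(m.max())
    if hi - lo <= 0:
        return np.zeros_like(m)
    return (m - lo) / (hi - lo)


def build_feature_matrix(
    segment,
    codebook: StimulusCodebook,
    cfg: SpectralConfig | None = None,
    n_bands: int = 2,
    *,
    padded: bool = True,
) -> FeatureMatrix:
    """Assemble the (n_bands*K) x channels zero-padded-PSD feature matrix.

    For each channel the segment is zero-padded to the aligned transform
    length and its PSD evaluated; row k of band h is the bin at h*f_k.  The
    whole matrix is min-max rescaled to [0, 1] (a constant matrix maps to
    all zeros).  With ``padded=False`` the PSD is taken on the raw N-point
    grid and each h*f_k is read from the nearest coarse bin — the
    non-padded baseline the padded features are compared against.
    """
    if n_bands < 1:
        raise ValueError("n_bands must be >= 1")
    x = np.asarray(segment.values, dtype=float)
    if x.ndim != 2:
        raise ValueError("segment values must be [channel][sample]")
    fs = segment.fs
    n = x.shape[1]
    if cfg is None:
        cfg = SpectralConfig.for_segment(fs, codebook.delta_f_stim, n)
    if cfg.fs != fs:
        raise ValueError(f"segment fs {fs} != spectral config fs {cfg.fs}")

    # remove per-channel DC: the pipeline assumes bandpassed input, and a
    # residual offset would otherwise leak through the padded rectangular
    # window into every off-integer bin
    x = x - x.mean(axis=1, keepdims=True)

    if padded:
        xp = zero_pad(x, cfg.n_total)
        pv = psd(xp, fs)
        bins = [band_bins(codebook, h, cfg) for h in range(1, n_bands + 1)]
    else:
        pv = psd(x, fs)
        spacing = fs / n
        bins = []
        for h in range(1, n_bands + 1):
            freqs = np.asarray(codebook.frequencies) * h
            if freqs.max() >= fs / 2:
                raise ValueError(
                    f"harmonic {h} band beyond Nyquist {fs / 2} Hz")
            bins.append(np.round(freqs / spacing).astype(int))

    rows = np.concatenate(bins)
    feat = pv.values[:, rows].T  # (n_bands*K, channels)
    layout = tuple(
        (h, tuple(pv.bin_hz[b] for b in bins[h - 1]))
        for h in range(1, n_bands + 1)
    )
    label = int(getattr(segment, "label", 0) or 0)
    return FeatureMatrix(
        values=_rescale_zero_one(feat), band_layout=layout, label=label
    )
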