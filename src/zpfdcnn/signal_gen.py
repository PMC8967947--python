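"""Synthetic SSVEP/SSMVEP recordings with the statistical structure the
frequency-recognition method assumes.

Steady-state visual evoked potentials (SSVEP) are narrowband oscillatory EEG
responses locked to the frequency (and harmonics) of a flickering stimulus;
steady-state *motion* VEPs (SSMVEP) are the analogue for periodic radial
motion and carry almost no harmonic energy.  The generator emits per-class
sinusoids with configurable harmonic amplitudes, a subject visual latency
drawn once per block, and a pink-plus-white background, in the two container
layouts used by public benchmark recordings: a 4-D epoched array
(channel x sample x block x stimulus) and a raw 2-D continuous array whose
last row is an event/label track.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace

import h5py
import numpy as np
from numpy.random import Generator, default_rng
from scipy.io import loadmat, savemat

__all__ = [
    "StimulusCodebook",
    "SimulationConfig",
    "EpochArray",
    "ContinuousRecording",
    "make_codebook",
    "make_sim_config",
    "simulate_epochs",
    "simulate_continuous",
    "write_epochs_mat",
    "read_epochs_mat",
    "write_epochs_hdf5",
    "read_epochs_hdf5",
    "write_continuous_mat",
    "read_continuous_mat",
    "write_continuous_hdf5",
    "read_continuous_hdf5",
    "write_epochs_raw",
    "read_epochs_raw",
    "OCCIPITAL_9",
]

#: The nine occipito-parietal electrodes used for SSVEP decoding.
OCCIPITAL_9 = ("Pz", "PO5", "PO3", "POz", "PO4", "PO6", "O1", "Oz", "O2")

#: Event code marking the end of a stimulation segment in the label track.
END_MARKER = 251

TWO_PI = 2.0 * math.pi


# ---------------------------------------------------------------------------
# codebooks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StimulusCodebook:
    """The K stimulation frequencies/phases that define classes and feature bins.

    ``delta_f_stim`` is the minimum gap between stimulation frequencies; the
    spectral stage aligns its bin grid to it.
    """

    frequencies: tuple
    phases: tuple
    delta_f_stim: float
    name: str = "custom"

    def __post_init__(self):
        f = np.asarray(self.frequencies, dtype=float)
        p = np.asarray(self.phases, dtype=float)
        if f.size == 0:
            raise ValueError("codebook needs at least one frequency")
        if f.size != p.size:
            raise ValueError("frequencies and phases must have equal length")
        if f.size > 1:
            gaps = np.diff(f)
            if np.any(gaps <= 0):
                raise ValueError("frequencies must be strictly increasing")
            min_gap = float(gaps.min())
            if not math.isclose(self.delta_f_stim, min_gap, rel_tol=1e-9):
                raise ValueError(
                    f"delta_f_stim={self.delta_f_stim} != minimum pairwise "
                    f"gap {min_gap}"
                )
        if self.delta_f_stim <= 0:
            raise ValueError("delta_f_stim must be > 0")
        if np.any(p < 0) or np.any(p >= TWO_PI):
            raise ValueError("phases must lie in [0, 2*pi)")

    @property
    def n_targets(self) -> int:
        return len(self.frequencies)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.frequencies)


def make_codebook(
    preset: str | None = None,
    *,
    f_min: float | None = None,
    f_max: float | None = None,
    step: float | None = None,
    phase_start: float = 0.0,
    phase_step: float = 0.0,
    name: str | None = None,
) -> StimulusCodebook:
    """Build a stimulus codebook from a preset or a custom frequency grid.

    Presets
    -------
    ``"beta"``
        40 targets, 8.0-15.8 Hz in 0.2 Hz steps, phases 0, 0.5*pi, pi, ...
        (mod 2*pi) — the joint frequency/phase code of the BETA speller.
    ``"ssmvep"``
        35 targets, 3.0-20.0 Hz in 0.5 Hz steps, all phases 0.5*pi.

    Custom grids take ``f_min``, ``f_max``, ``step`` and a linear phase rule
    ``phase_start + k * phase_step`` (mod 2*pi).
    """
    if preset is not None:
        key = preset.lower()
        if key == "beta":
            return make_codebook(
                f_min=8.0, f_max=15.8, step=0.2,
                phase_start=0.0, phase_step=0.5 * math.pi, name="beta",
            )
        if key == "ssmvep":
            return make_codebook(
                f_min=3.0, f_max=20.0, step=0.5,
                phase_start=0.5 * math.pi, phase_step=0.0, name="ssmvep",
            )
        raise ValueError(f"unknown preset {preset!r}")
    if f_min is None or f_max is None or step is None:
        raise ValueError("custom codebook requires f_min, f_max and step")
    if step <= 0:
        raise ValueError("step must be positive")
    if f_max <= f_min:
        raise ValueError("f_max must exceed f_min")
    n = int(round((f_max - f_min) / step)) + 1
    freqs = tuple(round(f_min + i * step, 9) for i in range(n))
    phases = tuple((phase_start + i * phase_step) % TWO_PI for i in range(n))
    return StimulusCodebook(
        frequencies=freqs, phases=phases, delta_f_stim=float(step),
        name=name or "custom",
    )


# ---------------------------------------------------------------------------
# simulation configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic recording.

    ``harmonic_amps[h-1]`` is the relative amplitude of harmonic h (h=1 is
    the fundamental).  ``noise_snr_db`` is the ratio, in dB, of oscillation
    power to total background-noise power over the stimulation segment;
    ``math.inf`` disables the noise.  The background is pink (1/f^exponent)
    plus white noise mixed 50/50 in power.  The visual latency — the delay
    between stimulus onset and the evoked response — is drawn once per block
    from Normal(latency_mean_s, latency_sd_s), truncated at zero.
    """

    fs: float = 250.0
    n_channels: int = 9
    harmonic_amps: tuple = (1.0, 0.5)
    noise_snr_db: float = -10.0
    pink_exponent: float = 1.0
    latency_mean_s: float = 0.13
    latency_sd_s: float = 0.01
    pre_stim_s: float = 0.5
    stim_s: float = 2.0
    post_stim_s: float = 0.5
    n_blocks: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.n_channels < 1:
            raise ValueError("need at least one channel")
        if any(a < 0 for a in self.harmonic_amps):
            raise ValueError("harmonic amplitudes must be nonnegative")
        if self.latency_mean_s < 0:
            raise ValueError("latency_mean_s must be >= 0")
        if min(self.pre_stim_s, self.stim_s, self.post_stim_s) < 0:
            raise ValueError("segment durations must be >= 0")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")

    @property
    def n_harmonics(self) -> int:
        return len(self.harmonic_amps)

    def validate_against(self, codebook: StimulusCodebook) -> None:
        """All generated harmonics must lie strictly below Nyquist."""
        top = max(codebook.frequencies) * self.n_harmonics
        if self.fs <= 2.0 * top:
            raise ValueError(
                f"fs={self.fs} too low: harmonic {self.n_harmonics} of "
                f"{max(codebook.frequencies)} Hz reaches {top} Hz "
                f">= Nyquist {self.fs / 2}"
            )


def make_sim_config(preset: str, **overrides) -> SimulationConfig:
    """Simulation defaults matched to a codebook preset.

    The BETA-style preset runs at 250 Hz with a strong second harmonic and a
    130 ms mean latency; the SSMVEP-style preset runs at 1000 Hz with a
    near-absent second harmonic and the 107.61 +/- 16.63 ms latency estimated
    for motion stimuli.
    """
    key = preset.lower()
    if key == "beta":
        base = SimulationConfig(
            fs=250.0, harmonic_amps=(1.0, 0.5),
            latency_mean_s=0.13, latency_sd_s=0.01,
            pre_stim_s=0.5, stim_s=2.0, post_stim_s=0.5, n_blocks=4,
        )
    elif key == "ssmvep":
        base = SimulationConfig(
            fs=1000.0, harmonic_amps=(1.0, 0.05),
            latency_mean_s=0.10761, latency_sd_s=0.01663,
            pre_stim_s=1.0, stim_s=3.0, post_stim_s=1.0, n_blocks=2,
        )
    else:
        raise ValueError(f"unknown preset {preset!r}")
    return replace(base, **overrides) if overrides else base


def _default_labels(n_channels: int) -> tuple:
    if n_channels <= 9:
        return OCCIPITAL_9[:n_channels]
    return OCCIPITAL_9 + tuple(f"Ch{i + 1}" for i in range(9, n_channels))


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class EpochArray:
    """4-D epoched EEG: values[channel, sample, block, stimulus].

    ``stim_onset_s`` is the offset of stimulation start within each epoch and
    ``stim_s`` the stimulation duration (needed to place sliding windows).
    """

    values: np.ndarray
    fs: float
    channel_labels: tuple
    codebook: StimulusCodebook
    stim_onset_s: float
    stim_s: float

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 4:
            raise ValueError("EpochArray values must be 4-D")
        if not np.all(np.isfinite(v)):
            raise ValueError("EpochArray values must be finite")
        if v.shape[0] != len(self.channel_labels):
            raise ValueError("channel dimension does not match labels")
        if v.shape[3] != self.codebook.n_targets:
            raise ValueError("stimulus dimension does not match codebook")
        self.values = v
        self.channel_labels = tuple(self.channel_labels)

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_blocks(self) -> int:
        return self.values.shape[2]

    @property
    def n_stimuli(self) -> int:
        return self.values.shape[3]


@dataclass
class ContinuousRecording:
    """Raw 2-D recording: values[channel, sample]; last row is the label track.

    The label track is zero except at trial boundaries: stimulation onset is
    marked with the 1-based stimulus index, stimulation end with code 251.
    """

    values: np.ndarray
    fs: float
    channel_labels: tuple

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] < 2:
            raise ValueError("ContinuousRecording needs >= 1 data channel "
                             "plus the label track")
        if v.shape[0] != len(self.channel_labels):
            raise ValueError("channel dimension does not match labels")
        self.values = v
        self.channel_labels = tuple(self.channel_labels)

    @property
    def label_track(self) -> np.ndarray:
        return self.values[-1]

    @property
    def data(self) -> np.ndarray:
        return self.values[:-1]


# ---------------------------------------------------------------------------
# signal synthesis
# ---------------------------------------------------------------------------


def _pink_noise(rng: Generator, n: int, exponent: float) -> np.ndarray:
    """Unit-variance noise with power spectrum proportional to 1/f^exponent."""
    white = rng.standard_normal(n)
    if exponent == 0.0:
        return white
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = 1.0  # DC removed below
    spec /= f ** (exponent / 2.0)
    spec[0] = 0.0
    pink = np.fft.irfft(spec, n=n)
    sd = pink.std()
    return pink / sd if sd > 0 else pink


def _background(rng: Generator, n: int, exponent: float) -> np.ndarray:
    """Pink + white background, mixed 50/50 in power, unit total variance."""
    pink = _pink_noise(rng, n, exponent)
    white = rng.standard_normal(n)
    return math.sqrt(0.5) * pink + math.sqrt(0.5) * white


def _oscillation(
    t: np.ndarray,
    f: float,
    phase: float,
    amps,
    t_start: float,
    t_stop: float,
) -> np.ndarray:
    """Harmonic stack active on [t_start, t_stop), zero elsewhere.

    Harmonic h runs at h*f with phase h*phase, mirroring how a periodic
    nonlinear response locks every harmonic to the stimulus phase.
    """
    out = np.zeros_like(t)
    active = (t >= t_start) & (t < t_stop)
    tau = t[active] - t_start
    for h, amp in enumerate(amps, start=1):
        if amp != 0.0:
            out[active] += amp * np.sin(TWO_PI * h * f * tau + h * phase)
    return out


def _draw_latencies(rng: Generator, cfg: SimulationConfig) -> np.ndarray:
    lat = rng.normal(cfg.latency_mean_s, cfg.latency_sd_s, size=cfg.n_blocks)
    return np.clip(lat, 0.0, None)


def simulate_epochs(
    codebook: StimulusCodebook, cfg: SimulationConfig
) -> EpochArray:
    """Generate a 4-D epoched synthetic recording.

    Each epoch holds ``pre_stim_s`` of background, the stimulation segment
    (oscillation delayed by the block's visual latency, plus background), and
    ``post_stim_s`` of background.  Noise is scaled per channel so that
    oscillation power over the stimulation segment exceeds background power
    by ``noise_snr_db``.  Deterministic given ``cfg.seed``.
    """
    cfg.validate_against(codebook)
    rng = default_rng(cfg.seed)
    fs = cfg.fs
    n_samples = int(round((cfg.pre_stim_s + cfg.stim_s + cfg.post_stim_s) * fs))
    t = np.arange(n_samples) / fs
    K = codebook.n_targets
    C, B = cfg.n_channels, cfg.n_blocks

    gains = rng.uniform(0.5, 1.0, size=C)
    latencies = _draw_latencies(rng, cfg)
    noisy = math.isfinite(cfg.noise_snr_db)
    snr_lin = 10.0 ** (cfg.noise_snr_db / 10.0) if noisy else math.inf

    values = np.zeros((C, n_samples, B, K))
    for b in range(B):
        t_start = cfg.pre_stim_s + latencies[b]
        t_stop = t_start + cfg.stim_s
        for k in range(K):
            osc = _oscillation(
                t, codebook.frequencies[k], codebook.phases[k],
                cfg.harmonic_amps, t_start, t_stop,
            )
            stim_mask = (t >= t_start) & (t < t_stop)
            osc_power = float(np.mean(osc[stim_mask] ** 2)) if stim_mask.any() else 0.0
            for c in range(C):
                x = gains[c] * osc
                if noisy:
                    sigma = math.sqrt(gains[c] ** 2 * osc_power / snr_lin)
                    x = x + sigma * _background(rng, n_samples, cfg.pink_exponent)
                values[c, :, b, k] = x

    return EpochArray(
        values=values, fs=fs, channel_labels=_default_labels(C),
        codebook=codebook, stim_onset_s=cfg.pre_stim_s, stim_s=cfg.stim_s,
    )


def simulate_continuous(
    codebook: StimulusCodebook,
    cfg: SimulationConfig,
    trial_s: float,
    rest_s: float,
) -> ContinuousRecording:
    """Generate a raw continuous recording with an event/label track.

    Each block presents every stimulus once in random order; a trial is
    ``stim_s`` of stimulation followed by ``rest_s`` of rest, and
    ``trial_s`` must equal their sum.  A lead-in and lead-out rest of
    ``rest_s`` pad the recording so epochs with pre/post context can be cut.
    """
    if rest_s < 0:
        raise ValueError("rest_s must be >= 0")
    if not math.isclose(trial_s, cfg.stim_s + rest_s, rel_tol=1e-9, abs_tol=1e-9):
        raise ValueError(
            f"trial_s={trial_s} must equal stim_s + rest_s = "
            f"{cfg.stim_s + rest_s}"
        )
    cfg.validate_against(codebook)
    rng = default_rng(cfg.seed)
    fs = cfg.fs
    K = codebook.n_targets
    C, B = cfg.n_channels, cfg.n_blocks
    n_trial = int(round(trial_s * fs))
    n_stim = int(round(cfg.stim_s * fs))
    n_rest = int(round(rest_s * fs))
    n_total = 2 * n_rest + B * K * n_trial
    t_all = np.arange(n_total) / fs

    gains = rng.uniform(0.5, 1.0, size=C)
    latencies = _draw_latencies(rng, cfg)
    orders = [rng.permutation(K) for _ in range(B)]
    noisy = math.isfinite(cfg.noise_snr_db)
    snr_lin = 10.0 ** (cfg.noise_snr_db / 10.0) if noisy else math.inf

    values = np.zeros((C + 1, n_total))
    labels = values[-1]

    osc_sum = np.zeros(n_total)
    power_scale = 0.0
    n_trials = 0
    for b in range(B):
        for j, k in enumerate(orders[b]):
            start = n_rest + (b * K + j) * n_trial
            t_on = start / fs + latencies[b]
            osc = _oscillation(
                t_all, codebook.frequencies[k], codebook.phases[k],
                cfg.harmonic_amps, t_on, t_on + cfg.stim_s,
            )
            osc_sum += osc
            mask = (t_all >= t_on) & (t_all < t_on + cfg.stim_s)
            if mask.any():
                power_scale += float(np.mean(osc[mask] ** 2))
                n_trials += 1
            labels[start] = k + 1
            labels[start + n_stim] = END_MARKER
    mean_power = power_scale / max(n_trials, 1)

    for c in range(C):
        x = gains[c] * osc_sum
        if noisy:
            sigma = math.sqrt(gains[c] ** 2 * mean_power / snr_lin)
            x = x + sigma * _background(rng, n_total, cfg.pink_exponent)
        values[c] = x

    return ContinuousRecording(
        values=values, fs=fs,
        channel_labels=_default_labels(C) + ("EVENT",),
    )


# ---------------------------------------------------------------------------
# writers / readers
# ---------------------------------------------------------------------------


def _epoch_meta(ep: EpochArray) -> dict:
    return {
        "fs": ep.fs,
        "channel_labels": list(ep.channel_labels),
        "frequencies": list(ep.codebook.frequencies),
        "phases": list(ep.codebook.phases),
        "delta_f_stim": ep.codebook.delta_f_stim,
        "codebook_name": ep.codebook.name,
        "stim_onset_s": ep.stim_onset_s,
        "stim_s": ep.stim_s,
    }


def _strip_labels(labels) -> tuple:
    # MAT v5 stores cell-of-char as space-padded char matrices
    return tuple(str(c).strip() for c in labels)


def _epoch_from_meta(values: np.ndarray, meta: dict) -> EpochArray:
    cb = StimulusCodebook(
        frequencies=tuple(float(f) for f in meta["frequencies"]),
        phases=tuple(float(p) for p in meta["phases"]),
        delta_f_stim=float(meta["delta_f_stim"]),
        name=str(meta["codebook_name"]),
    )
    return EpochArray(
        values=values, fs=float(meta["fs"]),
        channel_labels=_strip_labels(meta["channel_labels"]),
        codebook=cb, stim_onset_s=float(meta["stim_onset_s"]),
        stim_s=float(meta["stim_s"]),
    )


def write_epochs_mat(path, ep: EpochArray) -> None:
    """MAT v5 file with the benchmark layout: 4-D ``EEG`` + ``suppl_info``."""
    savemat(str(path), {"EEG": ep.values, "suppl_info": _epoch_meta(ep)})


def read_epochs_mat(path) -> EpochArray:
    raw = loadmat(str(path), simplify_cells=True)
    if "EEG" not in raw or "suppl_info" not in raw:
        raise ValueError(f"{path}: expected variables 'EEG' and 'suppl_info'")
    return _epoch_from_meta(np.asarray(raw["EEG"], dtype=float),
                            raw["suppl_info"])


def write_epochs_hdf5(path, ep: EpochArray) -> None:
    with h5py.File(str(path), "w") as f:
        f.create_dataset("EEG", data=ep.values)
        f.attrs["meta"] = json.dumps(_epoch_meta(ep))


def read_epochs_hdf5(path) -> EpochArray:
    with h5py.File(str(path), "r") as f:
        values = f["EEG"][()]
        meta = json.loads(f.attrs["meta"])
    return _epoch_from_meta(values, meta)


def write_epochs_raw(path, ep: EpochArray) -> None:
    """Plain float64 binary + JSON sidecar (``<path>.json``)."""
    v = np.ascontiguousarray(ep.values, dtype="<f8")
    v.tofile(str(path))
    meta = _epoch_meta(ep)
    meta["shape"] = list(ep.values.shape)
    meta["dtype"] = "<f8"
    with open(str(path) + ".json", "w") as fh:
        json.dump(meta, fh, indent=1)


def read_epochs_raw(path) -> EpochArray:
    with open(str(path) + ".json") as fh:
        meta = json.load(fh)
    values = np.fromfile(str(path), dtype=meta["dtype"])
    values = values.reshape(meta["shape"])
    return _epoch_from_meta(values, meta)


def write_continuous_mat(path, rec: ContinuousRecording) -> None:
    savemat(str(path), {
        "data": rec.values,
        "fs": rec.fs,
        "channel_labels": list(rec.channel_labels),
    })


def read_continuous_mat(path) -> ContinuousRecording:
    raw = loadmat(str(path), simplify_cells=True)
    return ContinuousRecording(
        values=np.asarray(raw["data"], dtype=float),
        fs=float(raw["fs"]),
        channel_labels=_strip_labels(raw["channel_labels"]),
    )


def write_continuous_hdf5(path, rec: ContinuousRecording) -> None:
    with h5py.File(str(path), "w") as f:
        f.create_dataset("data", data=rec.values)
        f.attrs["fs"] = rec.fs
        f.attrs["channel_labels"] = json.dumps(list(rec.channel_labels))


def read_continuous_hdf5(path) -> ContinuousRecording:
    with h5py.File(str(path), "r") as f:
        values = f["data"][()]
        fs = float(f.attrs["fs"])
        labels = tuple(json.loads(f.attrs["channel_labels"]))
    return ContinuousRecording(values=values, fs=fs, channel_labels=labels)
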