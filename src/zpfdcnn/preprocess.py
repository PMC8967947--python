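"""Filtering, channel selection, latency handling and sliding-window epoching.

Conventions used throughout: 0-based sample indexing, half-open windows
[start, start + len), and time-to-index conversion by rounding half away
from zero.  Bandpass filtering is causal single-pass IIR (Butterworth,
order 4 by default), matching the single-direction `filter` semantics of
common EEG toolchains; zero-phase filtering is available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .signal_gen import ContinuousRecording, EpochArray, END_MARKER

__all__ = [
    "FilterSpec",
    "Segment",
    "MissingChannelError",
    "round_to_sample",
    "apply_bandpass",
    "select_channels",
    "parse_continuous",
    "sliding_segments",
    "segment_count",
    "downsample",
]


class MissingChannelError(KeyError):
    """Raised when requested channel labels are absent; lists the missing ones."""

    def __init__(self, missing):
        self.missing = tuple(missing)
        super().__init__(f"channels not present: {', '.join(self.missing)}")


@dataclass(frozen=True)
class FilterSpec:
    """IIR bandpass specification (Butterworth)."""

    low_hz: float
    high_hz: float
    order: int = 4

    def __post_init__(self):
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError("need 0 < low_hz < high_hz")
        if self.order < 1:
            raise ValueError("order must be >= 1")

    def sos(self, fs: float) -> np.ndarray:
        if self.high_hz >= fs / 2:
            raise ValueError(
                f"high edge {self.high_hz} Hz >= Nyquist {fs / 2} Hz")
        return sps.butter(
            self.order, [self.low_hz, self.high_hz],
            btype="bandpass", fs=fs, output="sos",
        )


@dataclass(frozen=True)
class Segment:
    """One windowed multichannel training sample."""

    values: np.ndarray
    fs: float
    label: int
    window_s: float

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("segment values must be [channel][sample]")
        if v.shape[1] != round_to_sample(self.window_s * self.fs):
            raise ValueError("sample count does not match window_s * fs")
        object.__setattr__(self, "values", v)


def round_to_sample(x: float) -> int:
    """Round half away from zero — the package's time-to-index convention."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def apply_bandpass(x: np.ndarray, spec: FilterSpec, fs: float,
                   zero_phase: bool = False) -> np.ndarray:
    """Bandpass filter each channel (last axis is time).

    Causal single-pass by default; ``zero_phase=True`` switches to
    forward-backward filtering (no group delay, doubled order).
    """
    sos = spec.sos(fs)
    x = np.asarray(x, dtype=float)
    if zero_phase:
        return sps.sosfiltfilt(sos, x, axis=-1)
    return sps.sosfilt(sos, x, axis=-1)


def select_channels(x: np.ndarray, labels, wanted) -> np.ndarray:
    """Select rows by channel label, order-preserving; duplicates allowed."""
    labels = list(labels)
    missing = [w for w in wanted if w not in labels]
    if missing:
        raise MissingChannelError(missing)
    idx = [labels.index(w) for w in wanted]
    return np.asarray(x)[idx]


def parse_continuous(
    rec: ContinuousRecording,
    pre_s: float,
    stim_s: float,
    post_s: float,
    codebook=None,
) -> EpochArray:
    """Cut a labelled continuous recording into the 4-D epoch container.

    Onset markers (codes 1..K) in the trailing label track anchor each
    epoch: ``pre_s`` of context before onset, the stimulation segment, and
    ``post_s`` after its end.  Every stimulus must appear exactly once per
    block; a missing or surplus marker raises.
    """
    fs = rec.fs
    track = rec.label_track
    onset_idx = np.flatnonzero((track > 0) & (track != END_MARKER))
    codes = track[onset_idx].astype(int)
    if codes.size == 0:
        raise ValueError("label track contains no onset markers")
    K = codebook.n_targets if codebook is not None else int(codes.max())
    if codes.size % K != 0:
        raise ValueError(
            f"{codes.size} onset markers is not a whole number of blocks "
            f"of {K} stimuli"
        )
    n_blocks = codes.size // K
    for b in range(n_blocks):
        block_codes = np.sort(codes[b * K:(b + 1) * K])
        if not np.array_equal(block_codes, np.arange(1, K + 1)):
            raise ValueError(
                f"block {b}: stimulus codes {block_codes.tolist()} are not "
                f"a permutation of 1..{K}"
            )

    n_pre = round_to_sample(pre_s * fs)
    n_stim = round_to_sample(stim_s * fs)
    n_post = round_to_sample(post_s * fs)
    n_epoch = n_pre + n_stim + n_post
    data = rec.data
    C = data.shape[0]
    values = np.zeros((C, n_epoch, n_blocks, K))
    for i, (pos, code) in enumerate(zip(onset_idx, codes)):
        b = i // K
        start = pos - n_pre
        stop = pos + n_stim + n_post
        if start < 0 or stop > data.shape[1]:
            raise ValueError(
                f"epoch for marker at sample {pos} exceeds the recording")
        values[:, :, b, code - 1] = data[:, start:stop]

    from .signal_gen import StimulusCodebook  # local to avoid cycle at import

    if codebook is None:
        codebook = StimulusCodebook(
            frequencies=tuple(float(i) for i in range(1, K + 1)),
            phases=(0.0,) * K, delta_f_stim=1.0, name="unknown",
        )
    return EpochArray(
        values=values, fs=fs, channel_labels=rec.channel_labels[:-1],
        codebook=codebook, stim_onset_s=pre_s, stim_s=stim_s,
    )


def segment_count(stim_s: float, window_s: float, step_s: float) -> int:
    """floor((stim_s - window_s)/step_s) + 1, guarded against fp jitter."""
    return int(math.floor((stim_s - window_s) / step_s + 1e-9)) + 1


def sliding_segments(
    epoch: EpochArray,
    window_s: float,
    latency_s: float,
    step_s: float = 0.1,
    *,
    block: int | None = None,
    stimulus: int | None = None,
) -> list:
    """Cut sliding windows from the latency-shifted stimulation span.

    The first window starts at round((stim_onset_s + latency_s) * fs);
    successive windows advance round(step_s * fs) samples; the last window
    ends at or before round((stim_onset_s + latency_s + stim_s) * fs), so
    windows may run into the latency-shifted tail of the stimulation.
    Returns one ``Segment`` per (block, stimulus, window), labelled with the
    1-based stimulus index.
    """
    if latency_s < 0:
        raise ValueError("latency_s must be >= 0")
    if window_s > epoch.stim_s:
        raise ValueError(
            f"window_s={window_s} exceeds stimulation span {epoch.stim_s}")
    fs = epoch.fs
    first = round_to_sample((epoch.stim_onset_s + latency_s) * fs)
    n_win = round_to_sample(window_s * fs)
    hop = round_to_sample(step_s * fs)
    if hop < 1:
        raise ValueError("step_s is below one sample")
    n_seg = segment_count(epoch.stim_s, window_s, step_s)
    last_allowed = round_to_sample(
        (epoch.stim_onset_s + latency_s + epoch.stim_s) * fs)

    blocks = range(epoch.n_blocks) if block is None else [block]
    stimuli = range(epoch.n_stimuli) if stimulus is None else [stimulus]
    out = []
    for b in blocks:
        for k in stimuli:
            trial = epoch.values[:, :, b, k]
            for j in range(n_seg):
                start = first + j * hop
                stop = start + n_win
                if stop > last_allowed or stop > trial.shape[1]:
                    break
                out.append(Segment(
                    values=trial[:, start:stop], fs=fs,
                    label=k + 1, window_s=window_s,
                ))
    return out


def downsample(x: np.ndarray, factor: int, fs: float | None = None):
    """Anti-alias filter then decimate the last axis by an integer factor.

    Returns the decimated array, or ``(array, new_fs)`` when ``fs`` is
    given.  ``factor`` must be a positive integer (1 is the identity).
    """
    if not float(factor).is_integer() or factor < 1:
        raise ValueError(f"decimation factor must be a positive integer, "
                         f"got {factor}")
    factor = int(factor)
    x = np.asarray(x, dtype=float)
    y = x.copy() if factor == 1 else sps.decimate(x, factor, ftype="fir",
                                                 axis=-1, zero_phase=True)
    if fs is None:
        return y
    return y, fs / factor
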