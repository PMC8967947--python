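# Methods

## Signal model and feature extraction

An attended flickering target at frequency f with phase φ evokes an
occipito-parietal EEG component Σ_h a_h sin(2π h f t + h φ): the
fundamental plus phase-locked harmonics.  Classic flicker stimuli produce a
strong second harmonic; radial-motion (SSMVEP) stimuli produce almost none.
The decoder sees a windowed multichannel segment and must decide which of K
frequencies, spaced Δf apart, is present.

The N-point DFT of a T-second window exposes the spectrum only on the grid
F_s/N = 1/T.  With T = 1 s and Δf = 0.2 Hz, five stimulation frequencies
share a coarse bin, and an off-bin component leaks across the whole band
(rectangular-window response ≈ N/2 · sinc(k−m) for a k-cycle cosine at bin
m).  Zero-padding to length N+M = F_s/Δf evaluates the same discrete-time
Fourier transform on a grid that contains every f_k and every harmonic
h·f_k exactly; it adds no information, but the classifier then reads a
consistent, stimulus-aligned sample of the leakage pattern instead of an
arbitrary rounding of it.  Because any multiple of F_s/Δf keeps the grid
aligned, segments longer than F_s/Δf are padded up to the next multiple
rather than truncated.

Features per segment: for each channel, remove the channel mean (the
pipeline assumes bandpassed input; a residual offset would leak through the
padded rectangular window into every off-integer bin), zero-pad, take
P(m) = |X(m)|²/(F_s·N_len), and read the bins at h·f_k for h = 1..n_bands.
Rows are stacked band-by-band — K rows per band, giving 2K×9 = 80×9 for the
40-target preset — and the whole matrix is min-max rescaled to [0, 1]
(a constant matrix maps to all zeros).  Rescaling the matrix as a unit
keeps the fundamental/harmonic power ratio visible to the classifier and
makes features invariant to per-segment gain.  The single-bin-per-harmonic
layout is chosen over "all grid bins in the harmonic span" because it is
the only reading that reproduces the 80-row input geometry; under the same
rule the 35-target preset yields 70×9, not 80×9.

Only the rectangular window is offered: of the common tapers it has the
narrowest main lobe, and the aligned grid already places nulls of an
on-grid component on every other integer-offset bin.

## Classifier

Fixed layer sequence: conv 3×3×32 → BN → LeakyReLU(0.01) → conv 3×3×64 →
BN → LeakyReLU → FC 2048 → BN → LeakyReLU → FC K → BN → LeakyReLU →
softmax; convolutions are stride-1 "same", there is no pooling, and the
first FC layer attaches to the full flattened conv output (80×9×64 ≈ 46k
inputs for the 40-target preset).  Batch normalization after the *final*
FC layer is unusual — it bounds the logit scale so confidence grows only
through the BN gain — but it is part of the recipe and is kept.  Training:
Adam (β₁ 0.9, β₂ 0.999), cross-entropy over mutually exclusive classes,
defaults lr 1e-4, 30 epochs, batch 512 (clamped to the dataset size).
Weights are He-uniform with a seeded generator; everything runs in float32
and is bit-reproducible for a fixed seed and BLAS configuration.

Variants, sharing the architecture:

* `zpfd` — zero-padded PSD features (the method);
* `fd`   — PSD on the raw N-point grid, harmonics read from the nearest
  coarse bin (the no-padding ablation);
* `raw`  — the min-max-rescaled time-domain segment (channels × samples)
  as input;
* `separable` — each 3×3 convolution replaced by a 3×1 convolution
  followed by a *depthwise* 1×3 convolution.  This is a rank-1
  factorisation of each kernel (3+3 parameters per kernel position instead
  of 9) and is the only common separable scheme whose conv stack is
  strictly smaller than the dense one at these channel counts; the
  alternative (second stage mixing channels) is larger for a 1-channel
  input layer.

The implementation is pure NumPy — im2col convolutions, explicit batch-norm
backward, Adam — so the package has no deep-learning-framework dependency.

## Evaluation

Stratified 10-fold cross-validation, split at the *trial* level before
sliding windows are cut, so overlapping windows from one trial never
straddle the train/test boundary (a deliberately conservative reading of
pooled 10-fold CV; splitting at the window level would leak).  Accuracy is
the fraction of correctly classified windows; TPR/FPR are one-vs-rest per
class, macro-averaged.  ITR uses Wolpaw's formula with T = window + 0.55 s
gaze shift; below-chance accuracy reports 0 bits/min with a warning rather
than a negative rate.  Fold means carry standard errors.

## Synthetic data

The generator emulates what the method needs and nothing more:

* per-class sinusoids with configurable harmonic amplitudes — defaults
  (1.0, 0.5) for flicker-like and (1.0, 0.05) for motion-like signals
  (amplitude models are plausibility choices; the response-magnitude
  structure, strong vs. negligible second harmonic, is what matters);
* a visual latency drawn once per block from N(μ, σ) truncated at zero
  (μ = 130 ms for the 250 Hz flicker preset, μ = 107.61 ms / σ = 16.63 ms
  for the 1 kHz motion preset), applied as a delay of the oscillation
  onset;
* pink (1/f) + white background noise, mixed 50/50 in power and scaled per
  channel so that oscillation power over the stimulation segment exceeds
  noise power by `noise_snr_db` (realized SNR is within 1 dB of nominal;
  latency is recoverable to one sample by cross-correlation — both are
  tested);
* per-channel gains in [0.5, 1] on a shared oscillation, independent noise
  per channel; no volume-conduction mixing, artifacts, or inter-subject
  variability.

Both container layouts are produced: the 4-D epoched array and a raw
continuous recording whose last row carries event codes (stimulation onset
= 1-based stimulus index, stimulation end = 251), with MAT v5, HDF5 and
binary+JSON writers/readers.

Consequently, passing tests show that the *pipeline* behaves as designed on
signals with the assumed structure; they say nothing about cortical
nonlinearities, non-stationarity, eye/muscle artifacts, or real
inter-subject spread, and synthetic accuracies are not comparable to
accuracies on benchmark recordings.

## Numerical conventions

* Time→index conversion rounds half away from zero; windows are half-open
  [start, start+len) with 0-based samples.
* Bandpass filtering is a causal single-pass 4th-order Butterworth (the
  filter family/order is a convention choice; the sources specify only
  "IIR bandpass"), zero-phase filtering behind a flag.
* `padded_length` requires F_s/Δf to be an integer to 1e-6 relative
  tolerance — otherwise no transform length can align bins with the
  stimulus grid.
* Sliding windows start at round((onset+latency)·F_s) and may run into the
  latency-shifted stimulation tail; the count is floor((stim−window)/step)+1.
* Argmax ties in prediction resolve to the lower class index.
* k-fold splitting uses scikit-learn's StratifiedKFold with a fixed seed.

## Fixture-scale study conditions

The published recipe (conv 32/64, FC 2048, lr 1e-4, 30 epochs, batch 512)
is sized for tens of thousands of training windows.  Adam moves each
parameter by roughly the learning rate per step, so at desk scale — tens of
samples per class, a handful of steps per epoch — that recipe is hundreds
of times short of convergence.  The package therefore distinguishes:

* **defaults** = the published recipe (`ModelConfig`, `TrainConfig`);
* **fixture scale**, used by the test suite and the worked example:
  8 targets (8.0–9.4 Hz, 0.2 Hz spacing), 10 blocks, one 1.0 s window per
  trial, −8 dB broadband SNR, reduced widths conv (8, 16) / FC 128, lr
  1e-2, batch 32, 40–120 epochs.  The SNR was fixed once at the level
  where fundamental-band-only decoding sits well off both chance and
  ceiling (≈ 0.8), so that band/variant comparisons have headroom in both
  directions.  The raw time-domain variant is decimated ×4 (to 62.5 Hz,
  keeping the second harmonic alias-free) to bound its input size.

The directional conclusions exercised at fixture scale — padded features ≥
non-padded ≥ raw input; dense kernels ≥ separable; the second-harmonic band
helps iff the signal carries a second harmonic — are properties of the
feature representations and survive the reduced widths; absolute
accuracies at this scale are not meaningful beyond those comparisons.

## Known limitations

* The NumPy CNN is CPU-bound and intended for method study, not
  full-benchmark training runs.
* At desk scale the CNN pays a systematic penalty of a few accuracy points
  for noise-only input rows: with a near-absent second harmonic, adding the
  h=2 band (which then carries only noise) costs ~3–7 points at tens of
  training windows per class, even though a linear readout of the identical
  features loses under one point.  The band-irrelevance property therefore
  holds at the representation level but is not recovered by the CNN at this
  data scale; with the sample counts of full benchmark recordings the
  effect disappears into the noise floor.
* The 35-target preset's feature matrix is 70×9 under the consistent
  single-bin-per-harmonic reading, although the published input geometry
  states 80×9 for both presets; the discrepancy is noted rather than
  padded over.
* Continuous-recording simulation places stimulation at trial start; rest
  precedes and follows, and a lead-in/lead-out rest pads the recording so
  pre/post-context epochs can always be cut.
* ITR assumes the Wolpaw channel model (uniform error distribution over
  the Q−1 wrong targets), as is conventional for offline speller analysis.
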