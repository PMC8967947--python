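"""Cross-validated evaluation: stratified 10-fold CV, confusion-matrix
metrics, and the Wolpaw information transfer rate.

The CV splits at the *trial* level (block x stimulus), before sliding
windows are cut, so overlapping windows from one trial never straddle the
train/test boundary.  TPR/FPR are one-vs-rest per class and macro-averaged;
accuracy is the fraction of correctly classified samples.  ITR uses
Wolpaw's formula with the trial duration T = window length + gaze-shift
time (0.55 s by convention for offline analysis).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .classifier import ModelConfig, TrainConfig, build_model, predict, train
from .preprocess import downsample, sliding_segments
from .signal_gen import EpochArray
from .spectral import build_feature_matrix

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "kfold_split",
    "metrics",
    "itr",
    "evaluate_pipeline",
    "compare_variants",
    "GAZE_SHIFT_S",
]

#: Conventional gaze-shift time added to the window length for offline ITR.
GAZE_SHIFT_S = 0.55


@dataclass(frozen=True)
class ConfusionMatrix:
    """counts[true class, predicted class] with 1-based class ids."""

    counts: np.ndarray
    class_ids: tuple

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=int)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (c < 0).any():
            raise ValueError("confusion counts must be nonnegative")
        if c.shape[0] != len(self.class_ids):
            raise ValueError("class_ids length must match matrix size")
        object.__setattr__(self, "counts", c)

    @classmethod
    def from_predictions(cls, y_true, y_pred, n_classes: int
                         ) -> "ConfusionMatrix":
        counts = np.zeros((n_classes, n_classes), dtype=int)
        for t, p in zip(np.asarray(y_true), np.asarray(y_pred)):
            counts[int(t) - 1, int(p) - 1] += 1
        return cls(counts=counts, class_ids=tuple(range(1, n_classes + 1)))

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class EvalReport:
    """Cross-validation outcome at one window length."""

    fold_accuracies: list
    mean_accuracy: float
    se_accuracy: float
    tpr: float
    fpr: float
    confusion: ConfusionMatrix
    itr_bpm: float
    window_s: float
    gaze_shift_s: float
    n_classes: int
    variant: str = "zpfd"
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "mean_accuracy": float(self.mean_accuracy),
            "se_accuracy": float(self.se_accuracy),
            "tpr": float(self.tpr),
            "fpr": float(self.fpr),
            "confusion": self.confusion.counts.tolist(),
            "itr_bpm": float(self.itr_bpm),
            "window_s": float(self.window_s),
            "gaze_shift_s": float(self.gaze_shift_s),
            "n_classes": int(self.n_classes),
            "variant": self.variant,
            "extra": self.extra,
        }


def kfold_split(n_samples: int, labels, k: int = 10, seed: int = 0) -> list:
    """Stratified k-fold: disjoint test-index sets covering 0..n-1.

    Fold sizes differ by at most one and per-class counts across folds
    differ by at most one; there is no overlap between the complementary
    training subset and each test subset.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if n_samples < k:
        raise ValueError(f"cannot split {n_samples} samples into {k} folds")
    labels = np.asarray(labels)
    if labels.shape[0] != n_samples:
        raise ValueError("labels length must equal n_samples")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(n_samples), labels)]


def metrics(cm: ConfusionMatrix):
    """(ACC, TPR, FPR) from a confusion matrix.

    ACC is the fraction of correctly classified samples (diagonal mass).
    TPR and FPR are computed one-vs-rest per class and macro-averaged:
    TPR_c = TP_c/(TP_c+FN_c), FPR_c = FP_c/(FP_c+TN_c).
    """
    counts = cm.counts
    total = counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    diag = np.diag(counts).astype(float)
    acc = diag.sum() / total
    row = counts.sum(axis=1).astype(float)  # true-class totals
    col = counts.sum(axis=0).astype(float)  # predicted totals
    tp = diag
    fn = row - diag
    fp = col - diag
    tn = total - tp - fn - fp
    with np.errstate(invalid="ignore", divide="ignore"):
        tpr_c = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        fpr_c = np.where(fp + tn > 0, fp / (fp + tn), 0.0)
    return float(acc), float(tpr_c.mean()), float(fpr_c.mean())


def itr(P: float, Q: int, T_trial_s: float) -> float:
    """Wolpaw information transfer rate in bits per minute.

    ITR = (60/T) [log2 Q + P log2 P + (1-P) log2((1-P)/(Q-1))], with
    0*log2(0) taken as 0.  Below-chance accuracy (P < 1/Q) is reported as
    0 with a warning rather than as a negative rate.
    """
    if not (0.0 < P <= 1.0):
        raise ValueError(f"accuracy P={P} must lie in (0, 1]")
    if Q < 2:
        raise ValueError("Q must be >= 2")
    if T_trial_s <= 0:
        raise ValueError("trial duration must be positive")
    if P < 1.0 / Q:
        warnings.warn(
            f"accuracy {P} below chance 1/{Q}; reporting ITR = 0",
            stacklevel=2,
        )
        return 0.0
    bits = math.log2(Q)
    if P < 1.0:
        bits += P * math.log2(P) + (1.0 - P) * math.log2((1.0 - P) / (Q - 1))
    return (60.0 / T_trial_s) * bits


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------


def _featurize_trials(epochs, window_s, step_s, latency_s, n_bands, variant,
                      raw_decim):
    """Per-trial segment stacks and their feature tensors.

    Returns (X, y, trial_index) where trial_index maps each sample to its
    (block, stimulus) trial so CV can split by trial.
    """
    X, y, trial_idx = [], [], []
    tid = 0
    for b in range(epochs.n_blocks):
        for k in range(epochs.n_stimuli):
            segs = sliding_segments(
                epochs, window_s, latency_s, step_s, block=b, stimulus=k)
            for seg in segs:
                if variant == "raw":
                    v = seg.values
                    if raw_decim > 1:
                        v = downsample(v, raw_decim)
                    lo, hi = v.min(), v.max()
                    v = (v - lo) / (hi - lo) if hi > lo else np.zeros_like(v)
                    X.append(v)
                else:
                    fm = build_feature_matrix(
                        seg, epochs.codebook, n_bands=n_bands,
                        padded=(variant != "fd"),
                    )
                    X.append(fm.values)
                y.append(seg.label)
                trial_idx.append(tid)
            tid += 1
    return np.asarray(X), np.asarray(y), np.asarray(trial_idx)


def evaluate_pipeline(
    epochs: EpochArray,
    window_s: float,
    *,
    variant: str = "zpfd",
    n_bands: int = 2,
    latency_s: float = 0.0,
    step_s: float = 0.1,
    k_folds: int = 10,
    seed: int = 0,
    train_cfg: TrainConfig | None = None,
    conv_channels: tuple = (32, 64),
    fc_width: int = 2048,
    gaze_shift_s: float = GAZE_SHIFT_S,
    raw_decim: int = 1,
) -> EvalReport:
    """featurize -> train -> predict per fold; aggregate ACC, TPR/FPR, ITR.

    Samples are sliding-window segments; folds are stratified over *trials*
    so no window of a test trial was seen in training.  Fully seeded: the
    split, every fold's weight init and every shuffle derive from ``seed``.
    """
    train_cfg = train_cfg or TrainConfig()
    X, y, trial_idx = _featurize_trials(
        epochs, window_s, step_s, latency_s, n_bands, variant, raw_decim)
    if X.shape[0] == 0:
        raise ValueError("no segments produced; check window/step/latency")
    K = epochs.n_stimuli

    trials = np.unique(trial_idx)
    trial_labels = np.array([y[trial_idx == t][0] for t in trials])
    folds = kfold_split(len(trials), trial_labels, k=k_folds, seed=seed)

    cfg = ModelConfig(
        input_rows=X.shape[1], input_cols=X.shape[2], n_classes=K,
        variant=variant, conv_channels=tuple(conv_channels),
        fc_width=fc_width,
    )
    fold_acc = []
    y_true_all, y_pred_all = [], []
    for f, test_trials in enumerate(folds):
        test_mask = np.isin(trial_idx, trials[test_trials])
        fold_seed = (seed * 1000 + f) % (2 ** 31)
        model = build_model(cfg, seed=fold_seed)
        tc = TrainConfig(
            learning_rate=train_cfg.learning_rate, epochs=train_cfg.epochs,
            batch_size=train_cfg.batch_size, seed=fold_seed,
        )
        train(model, X[~test_mask], y[~test_mask], tc)
        pred, _ = predict(model, X[test_mask])
        fold_acc.append(float(np.mean(pred == y[test_mask])))
        y_true_all.append(y[test_mask])
        y_pred_all.append(pred)

    cm = ConfusionMatrix.from_predictions(
        np.concatenate(y_true_all), np.concatenate(y_pred_all), K)
    acc, tpr, fpr = metrics(cm)
    mean_acc = float(np.mean(fold_acc))
    se_acc = float(np.std(fold_acc, ddof=1) / math.sqrt(len(fold_acc))) \
        if len(fold_acc) > 1 else 0.0
    T = window_s + gaze_shift_s
    rate = itr(mean_acc, K, T) if mean_acc > 0 else 0.0
    return EvalReport(
        fold_accuracies=fold_acc, mean_accuracy=mean_acc, se_accuracy=se_acc,
        tpr=tpr, fpr=fpr, confusion=cm, itr_bpm=rate, window_s=window_s,
        gaze_shift_s=gaze_shift_s, n_classes=K, variant=variant,
        extra={"pooled_accuracy": acc, "n_samples": int(X.shape[0]),
               "k_folds": k_folds, "seed": seed},
    )


def compare_variants(
    epochs: EpochArray,
    window_s: float,
    variants=("zpfd", "fd", "raw", "separable"),
    seeds=(0, 1, 2, 3, 4),
    **kwargs,
) -> dict:
    """Mean CV accuracy per variant, averaged over seeds.

    Returns {variant: {"mean": float, "per_seed": [...]}}; used for the
    directional ablation comparison (padded vs non-padded features vs raw
    time-domain input vs separable kernels).
    """
    out = {}
    for variant in variants:
        per_seed = [
            evaluate_pipeline(
                epochs, window_s, variant=variant, seed=s, **kwargs
            ).mean_accuracy
            for s in seeds
        ]
        out[variant] = {"mean": float(np.mean(per_seed)),
                        "per_seed": per_seed}
    return out
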