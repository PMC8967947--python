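"""Run configuration and stage orchestration.

A run is declared by a :class:`RunConfig` — preset, window geometry,
feature/variant choices, training parameters and a seed — loadable from a
YAML file with CLI overrides (precedence: CLI > file > preset defaults).
``run()`` executes simulate -> featurize -> train -> evaluate and writes
features (HDF5), a model checkpoint (npz) and a JSON report + CSV confusion
matrix, each embedding the resolved configuration, package version and seed
so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

from . import __version__
from .classifier import ModelConfig, TrainConfig, build_model, save_model, train
from .evaluation import evaluate_pipeline
from .preprocess import sliding_segments
from .signal_gen import (
    EpochArray,
    make_codebook,
    make_sim_config,
    read_epochs_hdf5,
    read_epochs_mat,
    simulate_epochs,
    write_epochs_hdf5,
    write_epochs_mat,
)
from .spectral import build_feature_matrix

__all__ = ["RunConfig", "ConfigError", "load_run_config", "run",
           "read_epochs_any", "write_features_hdf5", "read_features_hdf5"]

log = logging.getLogger("zpfdcnn")

_PRESETS = ("beta", "ssmvep", "custom")


class ConfigError(ValueError):
    """Invalid run configuration; the message names the offending keys."""


@dataclass(frozen=True)
class RunConfig:
    """Declarative description of one end-to-end run."""

    preset: str = "beta"
    out_dir: str = "runs/out"
    # custom codebooks only:
    f_min: float | None = None
    f_max: float | None = None
    f_step: float | None = None
    # simulation
    snr_db: float = -10.0
    n_blocks: int = 4
    harmonic_amps: tuple = (1.0, 0.5)
    # windows / features
    window_s: float = 1.0
    step_s: float = 0.1
    latency_s: float | None = None
    n_bands: int = 2
    # model / training
    variant: str = "zpfd"
    epochs: int = 30
    batch_size: int = 512
    learning_rate: float = 1e-4
    conv_channels: tuple = (32, 64)
    fc_width: int = 2048
    k_folds: int = 10
    seed: int = 0

    def validate(self) -> None:
        bad = []
        if self.preset not in _PRESETS:
            bad.append(f"preset={self.preset!r} (must be one of {_PRESETS})")
        if self.preset == "custom" and None in (self.f_min, self.f_max,
                                                self.f_step):
            bad.append("custom preset requires f_min, f_max, f_step")
        if self.window_s <= 0:
            bad.append(f"window_s={self.window_s} (must be > 0)")
        if self.step_s <= 0:
            bad.append(f"step_s={self.step_s} (must be > 0)")
        if self.latency_s is not None and self.latency_s < 0:
            bad.append(f"latency_s={self.latency_s} (must be >= 0)")
        if self.n_bands < 1:
            bad.append(f"n_bands={self.n_bands} (must be >= 1)")
        if self.variant not in ("zpfd", "fd", "raw", "separable"):
            bad.append(f"variant={self.variant!r}")
        if self.epochs < 1:
            bad.append(f"epochs={self.epochs} (must be >= 1)")
        if self.learning_rate <= 0:
            bad.append(f"learning_rate={self.learning_rate} (must be > 0)")
        if self.k_folds < 2:
            bad.append(f"k_folds={self.k_folds} (must be >= 2)")
        if bad:
            raise ConfigError("invalid configuration: " + "; ".join(bad))

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        d["package_version"] = __version__
        return d


_VALID_KEYS = {f.name for f in dataclasses.fields(RunConfig)}


def load_run_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Merge preset defaults < YAML file < overrides; validate."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: expected a mapping at top level")
        data.update(loaded)
    for k, v in (overrides or {}).items():
        if v is not None:
            data[k] = v
    unknown = set(data) - _VALID_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    for key in ("harmonic_amps", "conv_channels"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    cfg = RunConfig(**data)
    cfg.validate()
    return cfg


def _codebook_for(cfg: RunConfig):
    if cfg.preset in ("beta", "ssmvep"):
        return make_codebook(cfg.preset)
    return make_codebook(f_min=cfg.f_min, f_max=cfg.f_max, step=cfg.f_step)


def _sim_config_for(cfg: RunConfig):
    base_preset = cfg.preset if cfg.preset in ("beta", "ssmvep") else "beta"
    return make_sim_config(
        base_preset,
        noise_snr_db=cfg.snr_db,
        n_blocks=cfg.n_blocks,
        harmonic_amps=tuple(cfg.harmonic_amps),
        seed=cfg.seed,
    )


def _latency_for(cfg: RunConfig) -> float:
    if cfg.latency_s is not None:
        return cfg.latency_s
    return _sim_config_for(cfg).latency_mean_s


# ---------------------------------------------------------------------------
# file helpers shared by CLI stages
# ---------------------------------------------------------------------------


def read_epochs_any(path) -> EpochArray:
    """Read an epoch container, dispatching on extension (.mat / .h5)."""
    p = str(path)
    if p.endswith(".mat"):
        return read_epochs_mat(p)
    if p.endswith((".h5", ".hdf5")):
        return read_epochs_hdf5(p)
    raise ValueError(f"unrecognised epoch container extension: {p}")


def write_epochs_any(path, epochs: EpochArray) -> None:
    p = str(path)
    if p.endswith(".mat"):
        write_epochs_mat(p, epochs)
    elif p.endswith((".h5", ".hdf5")):
        write_epochs_hdf5(p, epochs)
    else:
        raise ValueError(f"unrecognised epoch container extension: {p}")


def write_features_hdf5(path, X, y, meta: dict) -> None:
    with h5py.File(str(path), "w") as f:
        f.create_dataset("X", data=np.asarray(X))
        f.create_dataset("y", data=np.asarray(y, dtype=int))
        f.attrs["meta"] = json.dumps(meta, sort_keys=True)


def read_features_hdf5(path):
    with h5py.File(str(path), "r") as f:
        X = f["X"][()]
        y = f["y"][()]
        meta = json.loads(f.attrs["meta"])
    return X, y, meta


def featurize_epochs(epochs: EpochArray, window_s: float, step_s: float,
                     latency_s: float, n_bands: int, padded: bool = True):
    """All sliding-window feature matrices + labels from an epoch container."""
    X, y = [], []
    for b in range(epochs.n_blocks):
        for k in range(epochs.n_stimuli):
            for seg in sliding_segments(epochs, window_s, latency_s, step_s,
                                        block=b, stimulus=k):
                fm = build_feature_matrix(seg, epochs.codebook,
                                          n_bands=n_bands, padded=padded)
                X.append(fm.values)
                y.append(fm.label)
    return np.asarray(X), np.asarray(y)


# ---------------------------------------------------------------------------
# the end-to-end run
# ---------------------------------------------------------------------------


def run(cfg: RunConfig) -> dict:
    """Execute simulate -> featurize -> train -> evaluate; return artifact paths."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    resolved = cfg.resolved()

    codebook = _codebook_for(cfg)
    sim = _sim_config_for(cfg)
    latency = _latency_for(cfg)
    log.info("simulate: preset=%s K=%d blocks=%d snr=%s dB seed=%d",
             cfg.preset, codebook.n_targets, sim.n_blocks, cfg.snr_db,
             cfg.seed)
    epochs = simulate_epochs(codebook, sim)

    padded = cfg.variant != "fd"
    X, y = featurize_epochs(epochs, cfg.window_s, cfg.step_s, latency,
                            cfg.n_bands, padded=padded)
    features_path = out / "features.h5"
    write_features_hdf5(features_path, X, y,
                        {"config": resolved, "latency_s": latency})
    log.info("featurize: %d samples of %dx%d", X.shape[0], X.shape[1],
             X.shape[2])

    tcfg = TrainConfig(learning_rate=cfg.learning_rate, epochs=cfg.epochs,
                       batch_size=cfg.batch_size, seed=cfg.seed)
    report = evaluate_pipeline(
        epochs, cfg.window_s, variant=cfg.variant, n_bands=cfg.n_bands,
        latency_s=latency, step_s=cfg.step_s, k_folds=cfg.k_folds,
        seed=cfg.seed, train_cfg=tcfg, conv_channels=cfg.conv_channels,
        fc_width=cfg.fc_width,
    )
    log.info("evaluate: mean acc %.4f, ITR %.2f bpm",
             report.mean_accuracy, report.itr_bpm)

    mcfg = ModelConfig(
        input_rows=X.shape[1], input_cols=X.shape[2],
        n_classes=codebook.n_targets, variant=cfg.variant,
        conv_channels=tuple(cfg.conv_channels), fc_width=cfg.fc_width,
    )
    model = build_model(mcfg, seed=cfg.seed)
    train(model, X, y, tcfg)
    model_path = out / "model.npz"
    save_model(model, model_path)

    report_path = out / "report.json"
    payload = {"config": resolved, "report": report.to_dict()}
    with open(report_path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    confusion_path = out / "confusion.csv"
    np.savetxt(confusion_path, report.confusion.counts, fmt="%d",
               delimiter=",")
    return {
        "features": str(features_path),
        "model": str(model_path),
        "report": str(report_path),
        "confusion": str(confusion_path),
    }
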