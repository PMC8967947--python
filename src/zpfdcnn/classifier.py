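"""The spectral-feature CNN and its ablation variants, in pure NumPy.

Layer recipe (fixed): conv 3x3 x32 -> BN -> LeakyReLU(0.01) -> conv 3x3 x64
-> BN -> LeakyReLU -> FC 2048 -> BN -> LeakyReLU -> FC n_classes -> BN ->
LeakyReLU -> softmax, trained with Adam on mutually-exclusive cross-entropy.
Convolutions are stride 1 with "same" padding and there is no pooling: the
first FC layer attaches to the full flattened conv output.  Batch
normalization sits after the final FC as well — unusual, but that is the
recipe implemented here.

Variants
--------
``zpfd``      zero-padded-PSD feature input (bins x channels)
``fd``        same architecture on non-padded PSD features
``raw``       same architecture on the time-domain segment (channels x samples)
``separable`` each 3x3 conv replaced by a 3x1 conv followed by a depthwise
              1x3 conv (a rank-1 factorisation of the kernel, fewer
              parameters per kernel position: 3+3 < 9)

Everything runs in float32 and is deterministic for a fixed seed and thread
configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "CNNModel",
    "build_model",
    "train",
    "predict",
    "save_model",
    "load_model",
    "n_parameters",
    "conv_parameters",
]

_DTYPE = np.float32
_VARIANTS = ("zpfd", "fd", "raw", "separable")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture parameters; defaults follow the published recipe."""

    input_rows: int
    input_cols: int
    n_classes: int
    variant: str = "zpfd"
    conv_channels: tuple = (32, 64)
    fc_width: int = 2048
    leaky_slope: float = 0.01

    def __post_init__(self):
        if self.input_rows < 1 or self.input_cols < 1:
            raise ValueError("input dimensions must be positive")
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.variant not in _VARIANTS:
            raise ValueError(f"variant must be one of {_VARIANTS}")
        if len(self.conv_channels) != 2:
            raise ValueError("conv_channels must list two layer widths")
        if self.variant == "raw" and self.input_cols <= self.input_rows:
            raise ValueError(
                "raw variant requires time-domain input shape "
                "(channels x samples, with more samples than channels); got "
                f"{self.input_rows}x{self.input_cols}"
            )


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation recipe: Adam, lr 1e-4, 30 epochs, batch 512."""

    learning_rate: float = 1e-4
    epochs: int = 30
    batch_size: int = 512
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class _Layer:
    params: dict
    grads: dict

    def __init__(self):
        self.params = {}
        self.grads = {}

    def forward(self, x, training):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError


def _he_uniform(rng, shape, fan_in):
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(_DTYPE)


class _Conv2DSame(_Layer):
    """kh x kw convolution, stride 1, zero 'same' padding, via im2col."""

    def __init__(self, rng, kh, kw, c_in, c_out):
        super().__init__()
        self.kh, self.kw, self.c_in, self.c_out = kh, kw, c_in, c_out
        fan_in = kh * kw * c_in
        self.params["W"] = _he_uniform(rng, (fan_in, c_out), fan_in)
        self.params["b"] = np.zeros(c_out, dtype=_DTYPE)

    def _pad(self, x):
        ph, pw = self.kh // 2, self.kw // 2
        return np.pad(x, ((0, 0), (ph, self.kh - 1 - ph),
                          (pw, self.kw - 1 - pw), (0, 0)))

    def _im2col(self, xp, H, W):
        B = xp.shape[0]
        C = self.c_in
        cols = np.empty((B, H, W, self.kh * self.kw * C), dtype=_DTYPE)
        idx = 0
        for i in range(self.kh):
            for j in range(self.kw):
                cols[..., idx * C:(idx + 1) * C] = xp[:, i:i + H, j:j + W, :]
                idx += 1
        return cols

    def forward(self, x, training):
        B, H, W, _ = x.shape
        xp = self._pad(x)
        cols = self._im2col(xp, H, W)
        y = cols.reshape(-1, cols.shape[-1]) @ self.params["W"]
        y += self.params["b"]
        self._cache = (cols, (B, H, W), xp.shape)
        return y.reshape(B, H, W, self.c_out)

    def backward(self, dy):
        cols, (B, H, W), xp_shape = self._cache
        dy2 = dy.reshape(-1, self.c_out)
        self.grads["W"] = cols.reshape(-1, cols.shape[-1]).T @ dy2
        self.grads["b"] = dy2.sum(axis=0)
        dcols = (dy2 @ self.params["W"].T).reshape(cols.shape)
        dxp = np.zeros(xp_shape, dtype=_DTYPE)
        C = self.c_in
        idx = 0
        for i in range(self.kh):
            for j in range(self.kw):
                dxp[:, i:i + H, j:j + W, :] += dcols[..., idx * C:(idx + 1) * C]
                idx += 1
        ph, pw = self.kh // 2, self.kw // 2
        return dxp[:, ph:ph + H, pw:pw + W, :]


class _DepthwiseConv1x3(_Layer):
    """Per-channel 1x3 convolution along the column axis ('same' padding)."""

    def __init__(self, rng, channels):
        super().__init__()
        self.channels = channels
        self.params["W"] = _he_uniform(rng, (3, channels), 3)
        self.params["b"] = np.zeros(channels, dtype=_DTYPE)

    def forward(self, x, training):
        B, H, W, C = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (0, 0)))
        y = np.zeros_like(x)
        for j in range(3):
            y += xp[:, :, j:j + W, :] * self.params["W"][j]
        y += self.params["b"]
        self._cache = (xp, x.shape)
        return y

    def backward(self, dy):
        xp, x_shape = self._cache
        B, H, W, C = x_shape
        dW = np.empty((3, C), dtype=_DTYPE)
        dxp = np.zeros_like(xp)
        for j in range(3):
            dW[j] = (dy * xp[:, :, j:j + W, :]).sum(axis=(0, 1, 2))
            dxp[:, :, j:j + W, :] += dy * self.params["W"][j]
        self.grads["W"] = dW
        self.grads["b"] = dy.sum(axis=(0, 1, 2))
        return dxp[:, :, 1:1 + W, :]


class _BatchNorm(_Layer):
    """Batch normalization over all axes but the last; eps 1e-5."""

    def __init__(self, width, momentum=0.1):
        super().__init__()
        self.eps = 1e-5
        self.momentum = momentum
        self.params["gamma"] = np.ones(width, dtype=_DTYPE)
        self.params["beta"] = np.zeros(width, dtype=_DTYPE)
        self.running_mean = np.zeros(width, dtype=_DTYPE)
        self.running_var = np.ones(width, dtype=_DTYPE)

    def forward(self, x, training):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mean).astype(_DTYPE)
            self.running_var = ((1 - m) * self.running_var
                                + m * var).astype(_DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * invstd
        self._cache = (xhat, invstd.astype(_DTYPE), axes,
                       int(np.prod([x.shape[a] for a in axes])))
        return (self.params["gamma"] * xhat + self.params["beta"]).astype(_DTYPE)

    def backward(self, dy):
        xhat, invstd, axes, n = self._cache
        self.grads["gamma"] = (dy * xhat).sum(axis=axes)
        self.grads["beta"] = dy.sum(axis=axes)
        g = self.params["gamma"]
        dxhat = dy * g
        dx = (invstd / n) * (
            n * dxhat
            - dxhat.sum(axis=axes)
            - xhat * (dxhat * xhat).sum(axis=axes)
        )
        return dx.astype(_DTYPE)


class _LeakyReLU(_Layer):
    def __init__(self, slope):
        super().__init__()
        self.slope = slope

    def forward(self, x, training):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy):
        return np.where(self._mask, dy, self.slope * dy)


class _Flatten(_Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class _Dense(_Layer):
    def __init__(self, rng, n_in, n_out):
        super().__init__()
        self.params["W"] = _he_uniform(rng, (n_in, n_out), n_in)
        self.params["b"] = np.zeros(n_out, dtype=_DTYPE)

    def forward(self, x, training):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


class CNNModel:
    """Trainable network with the fixed layer sequence of one variant."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        self.seed = seed
        rng = np.random.default_rng(seed)
        c1, c2 = cfg.conv_channels
        layers = []
        for c_in, c_out in ((1, c1), (c1, c2)):
            if cfg.variant == "separable":
                layers.append(_Conv2DSame(rng, 3, 1, c_in, c_out))
                layers.append(_DepthwiseConv1x3(rng, c_out))
            else:
                layers.append(_Conv2DSame(rng, 3, 3, c_in, c_out))
            layers.append(_BatchNorm(c_out))
            layers.append(_LeakyReLU(cfg.leaky_slope))
        layers.append(_Flatten())
        flat = cfg.input_rows * cfg.input_cols * c2
        layers.append(_Dense(rng, flat, cfg.fc_width))
        layers.append(_BatchNorm(cfg.fc_width))
        layers.append(_LeakyReLU(cfg.leaky_slope))
        layers.append(_Dense(rng, cfg.fc_width, cfg.n_classes))
        layers.append(_BatchNorm(cfg.n_classes))
        layers.append(_LeakyReLU(cfg.leaky_slope))
        self.layers = layers

    # -- plumbing -----------------------------------------------------------

    def _check_input(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=_DTYPE)
        if X.ndim == 3:
            X = X[..., None]
        if X.ndim != 4 or X.shape[1] != self.cfg.input_rows \
                or X.shape[2] != self.cfg.input_cols or X.shape[3] != 1:
            raise ValueError(
                f"input shape {X.shape} does not match model input "
                f"{self.cfg.input_rows}x{self.cfg.input_cols}x1"
            )
        return X

    def forward(self, X, training: bool) -> np.ndarray:
        h = self._check_input(X)
        for layer in self.layers:
            h = layer.forward(h, training)
        return h  # logits (post-BN/LeakyReLU)

    def backward(self, dlogits) -> None:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def predict_proba(self, X, batch_size: int = 512) -> np.ndarray:
        X = self._check_input(X)
        out = []
        for i in range(0, X.shape[0], batch_size):
            logits = self.forward(X[i:i + batch_size], training=False)
            out.append(_softmax(logits))
        return np.concatenate(out, axis=0)

    def parameters(self):
        for layer in self.layers:
            for name in layer.params:
                yield layer, name


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z.astype(np.float64))
    return e / e.sum(axis=1, keepdims=True)


def build_model(cfg: ModelConfig, seed: int = 0) -> CNNModel:
    """Construct a freshly initialised (He-uniform, seeded) model."""
    return CNNModel(cfg, seed=seed)


def n_parameters(model: CNNModel) -> int:
    return sum(layer.params[name].size for layer, name in model.parameters())


def conv_parameters(model: CNNModel) -> int:
    """Weight count of the convolutional stack only."""
    return sum(
        layer.params[name].size
        for layer, name in model.parameters()
        if isinstance(layer, (_Conv2DSame, _DepthwiseConv1x3))
    )


# ---------------------------------------------------------------------------
# training / inference
# ---------------------------------------------------------------------------


class _Adam:
    def __init__(self, model, lr):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.state = {
            (id(layer), name): (np.zeros_like(layer.params[name]),
                                np.zeros_like(layer.params[name]))
            for layer, name in model.parameters()
        }

    def step(self, model):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1 ** self.t
        bias2 = 1 - b2 ** self.t
        for layer, name in model.parameters():
            g = layer.grads[name].astype(_DTYPE)
            m, v = self.state[(id(layer), name)]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            layer.params[name] -= (
                self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
            ).astype(_DTYPE)


def train(model: CNNModel, X, y, tcfg: TrainConfig | None = None):
    """Train in place; returns ``(model, per-epoch mean loss trace)``.

    ``y`` holds 1-based class labels.  The batch size is clamped to the
    dataset size; shuffling and all arithmetic are deterministic for a
    fixed seed (and BLAS thread configuration).
    """
    tcfg = tcfg or TrainConfig()
    X = np.asarray(X, dtype=_DTYPE)
    y = np.asarray(y)
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    if X.shape[0] != y.shape[0]:
        raise ValueError("sample/label count mismatch")
    K = model.cfg.n_classes
    if y.min() < 1 or y.max() > K:
        raise ValueError(f"labels must lie in 1..{K}")
    y0 = y.astype(int) - 1

    rng = np.random.default_rng(tcfg.seed)
    opt = _Adam(model, tcfg.learning_rate)
    batch = min(tcfg.batch_size, X.shape[0])
    n = X.shape[0]
    losses = []
    for _ in range(tcfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        seen = 0
        for i in range(0, n, batch):
            idx = order[i:i + batch]
            logits = model.forward(X[idx], training=True)
            p = _softmax(logits)
            b = idx.size
            eps = 1e-12
            epoch_loss += -np.log(p[np.arange(b), y0[idx]] + eps).sum()
            seen += b
            grad = p.copy()
            grad[np.arange(b), y0[idx]] -= 1.0
            model.backward((grad / b).astype(_DTYPE))
            opt.step(model)
        losses.append(float(epoch_loss / seen))
    return model, losses


def predict(model: CNNModel, X):
    """Labels (1-based, argmax with ties to the lower index) + probabilities."""
    proba = model.predict_proba(X)
    labels = proba.argmax(axis=1) + 1
    return labels, proba


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_model(model: CNNModel, path) -> None:
    """Portable checkpoint: npz with parameters, BN stats and the config."""
    arrays = {}
    for i, layer in enumerate(model.layers):
        for name, val in layer.params.items():
            arrays[f"layer{i}.{name}"] = val
        if isinstance(layer, _BatchNorm):
            arrays[f"layer{i}.running_mean"] = layer.running_mean
            arrays[f"layer{i}.running_var"] = layer.running_var
    cfg = model.cfg
    meta = {
        "input_rows": cfg.input_rows, "input_cols": cfg.input_cols,
        "n_classes": cfg.n_classes, "variant": cfg.variant,
        "conv_channels": list(cfg.conv_channels), "fc_width": cfg.fc_width,
        "leaky_slope": cfg.leaky_slope, "seed": model.seed,
    }
    np.savez(str(path), __config__=json.dumps(meta), **arrays)


def load_model(path) -> CNNModel:
    with np.load(str(path), allow_pickle=False) as data:
        meta = json.loads(str(data["__config__"]))
        cfg = ModelConfig(
            input_rows=int(meta["input_rows"]),
            input_cols=int(meta["input_cols"]),
            n_classes=int(meta["n_classes"]),
            variant=meta["variant"],
            conv_channels=tuple(meta["conv_channels"]),
            fc_width=int(meta["fc_width"]),
            leaky_slope=float(meta["leaky_slope"]),
        )
        model = CNNModel(cfg, seed=int(meta["seed"]))
        for i, layer in enumerate(model.layers):
            for name in layer.params:
                layer.params[name] = data[f"layer{i}.{name}"]
            if isinstance(layer, _BatchNorm):
                layer.running_mean = data[f"layer{i}.running_mean"]
                layer.running_var = data[f"layer{i}.running_var"]
    return model
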