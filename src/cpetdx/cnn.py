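"""8-channel one-dimensional convolutional network classifier.

Architecture: six 1-D convolution blocks with two-sided (centered) kernels
sliding over the resampled CPET time axis, a global max pooling layer that
reduces each filter's output sequence to its maximum, and two fully connected
layers ending in a 2-class softmax.  No dropout and no batch normalization
anywhere.  Training uses Adam (lr 1e-4), batch size 4, cross-entropy loss,
and early stopping on validation loss (patience 15 epochs, minimum
improvement 0.01), restoring the best-validation weights.

The network is implemented directly on numpy (forward and backward passes,
Adam, the training loop): the data volumes involved — tens of patients, a
256-sample grid — need no accelerator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedShuffleSplit

from . import io as cio
from .schema import MODEL_CHANNELS, PatientRecord, StageAnnotation

__all__ = [
    "CNNConfig",
    "TrainConfig",
    "ConfigError",
    "CNNNet",
    "build_cnn",
    "train_cnn",
    "predict_cnn",
    "preprocess_for_cnn",
    "CNNClassifier",
]


class ConfigError(ValueError):
    """The architecture configuration is internally inconsistent."""


@dataclass(frozen=True)
class CNNConfig:
    """Architecture hyperparameters (exactly six conv blocks, 2-class head)."""

    n_channels: int = 8
    input_length: int = 256
    kernel_lengths: tuple = (7, 7, 5, 5, 3, 3)
    filters_per_block: tuple = (16, 16, 32, 32, 64, 64)
    strides: tuple = (1, 1, 2, 1, 2, 1)
    fc_widths: tuple = (32, 2)

    def __post_init__(self) -> None:
        if not (len(self.kernel_lengths) == len(self.filters_per_block)
                == len(self.strides) == 6):
            raise ConfigError("exactly 6 convolutional blocks are required")
        if len(self.fc_widths) != 2 or self.fc_widths[-1] != 2:
            raise ConfigError("head must be two fully connected layers ending in 2 classes")
        if self.input_length < 32:
            raise ConfigError("input_length must be >= 32")
        for i, k in enumerate(self.kernel_lengths):
            if k < 2 or k > self.input_length:
                raise ConfigError(f"block {i}: kernel length {k} out of range")

    def block_output_lengths(self) -> list[int]:
        """Temporal length after each block ('same' padding, stride ceil)."""
        lengths = []
        L = self.input_length
        for i, (k, s) in enumerate(zip(self.kernel_lengths, self.strides)):
            if k > L:
                raise ConfigError(
                    f"block {i}: kernel length {k} exceeds surviving sequence "
                    f"length {L}"
                )
            L = math.ceil(L / s)
            lengths.append(L)
        return lengths

    def parameter_count(self) -> int:
        n = 0
        in_ch = self.n_channels
        for k, f in zip(self.kernel_lengths, self.filters_per_block):
            n += f * in_ch * k + f
            in_ch = f
        widths = (in_ch,) + tuple(self.fc_widths)
        for a, b in zip(widths[:-1], widths[1:]):
            n += a * b + b
        return n


@dataclass(frozen=True)
class TrainConfig:
    """Training regime: Adam lr 1e-4, batch 4, early stopping 15/0.01.

    There are deliberately no dropout or batch-normalization knobs.
    """

    learning_rate: float = 1e-4
    batch_size: int = 4
    early_stopping_patience: int = 15
    early_stopping_min_delta: float = 0.01
    max_epochs: int = 300
    seed: int = 0


def _same_pad(L: int, k: int, s: int) -> tuple[int, int]:
    out = math.ceil(L / s)
    total = max((out - 1) * s + k - L, 0)
    return total // 2, total - total // 2


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


class CNNNet:
    """The network's weights plus forward/backward passes (batch-first)."""

    def __init__(self, config: CNNConfig, seed: int = 0):
        config.block_output_lengths()  # validates depth-wise feasibility
        self.config = config
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        in_ch = config.n_channels
        for i, (k, f) in enumerate(zip(config.kernel_lengths, config.filters_per_block)):
            fan_in = in_ch * k
            self.params[f"W{i}"] = rng.normal(0.0, math.sqrt(2.0 / fan_in), (f, in_ch, k))
            self.params[f"b{i}"] = np.zeros(f)
            in_ch = f
        widths = (in_ch,) + tuple(config.fc_widths)
        for j, (a, b) in enumerate(zip(widths[:-1], widths[1:])):
            self.params[f"F{j}"] = rng.normal(0.0, math.sqrt(2.0 / a), (a, b))
            self.params[f"c{j}"] = np.zeros(b)

    # -- forward -----------------------------------------------------------

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """x: (B, channels, length) -> logits (B, 2); optional backprop cache."""
        cfg = self.config
        cache: dict = {"inputs": [], "windows": [], "preact": []}
        h = np.asarray(x, float)
        for i, (k, s) in enumerate(zip(cfg.kernel_lengths, cfg.strides)):
            pl, pr = _same_pad(h.shape[2], k, s)
            padded = np.pad(h, ((0, 0), (0, 0), (pl, pr)))
            win = sliding_window_view(padded, k, axis=2)[:, :, ::s, :]  # (B,C,O,k)
            z = np.einsum("bcok,fck->bfo", win, self.params[f"W{i}"]) \
                + self.params[f"b{i}"][:, None]
            if want_cache:
                cache["inputs"].append((h.shape, pl))
                cache["windows"].append(win)
                cache["preact"].append(z)
            h = _relu(z)
        pooled = h.max(axis=2)                      # global max pooling
        if want_cache:
            cache["pool_in"] = h
            cache["pool_argmax"] = h.argmax(axis=2)
        g = pooled
        fcs = []
        for j in range(2):
            z = g @ self.params[f"F{j}"] + self.params[f"c{j}"]
            fcs.append((g, z))
            g = _relu(z) if j == 0 else z
        if want_cache:
            cache["fcs"] = fcs
            cache["pooled"] = pooled
        return (g, cache) if want_cache else g

    @staticmethod
    def softmax(logits: np.ndarray) -> np.ndarray:
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.softmax(self.forward(x))

    # -- backward ----------------------------------------------------------

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray):
        """Mean cross-entropy over the batch + gradients for every parameter."""
        B = x.shape[0]
        logits, cache = self.forward(x, want_cache=True)
        proba = self.softmax(logits)
        eps = 1e-12
        loss = float(-np.mean(np.log(proba[np.arange(B), y] + eps)))
        grads: dict[str, np.ndarray] = {}

        dlogits = proba.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        # FC head (layer 1 linear, layer 0 ReLU)
        g1_in, z1 = cache["fcs"][1]
        grads["F1"] = g1_in.T @ dlogits
        grads["c1"] = dlogits.sum(axis=0)
        dg1 = dlogits @ self.params["F1"].T
        g0_in, z0 = cache["fcs"][0]
        dz0 = dg1 * (z0 > 0)
        grads["F0"] = g0_in.T @ dz0
        grads["c0"] = dz0.sum(axis=0)
        dpooled = dz0 @ self.params["F0"].T      # (B, filters)

        # global max pool: gradient flows to the argmax position per filter
        h = cache["pool_in"]
        dh = np.zeros_like(h)
        bi, fi = np.meshgrid(np.arange(h.shape[0]), np.arange(h.shape[1]), indexing="ij")
        dh[bi, fi, cache["pool_argmax"]] = dpooled

        cfg = self.config
        for i in reversed(range(6)):
            z = cache["preact"][i]
            dz = dh * (z > 0)                     # (B, F, O)
            win = cache["windows"][i]             # (B, C, O, k)
            grads[f"W{i}"] = np.einsum("bfo,bcok->fck", dz, win)
            grads[f"b{i}"] = dz.sum(axis=(0, 2))
            if i == 0:
                break
            in_shape, pl = cache["inputs"][i]
            B_, C, L = in_shape
            k, s = cfg.kernel_lengths[i], cfg.strides[i]
            O = z.shape[2]
            dwin = np.einsum("bfo,fck->bcok", dz, self.params[f"W{i}"])
            dpad = np.zeros((B_, C, L + sum(_same_pad(L, k, s))))
            pos = (np.arange(O)[:, None] * s + np.arange(k)[None, :])  # (O, k)
            np.add.at(
                dpad,
                (np.arange(B_)[:, None, None, None],
                 np.arange(C)[None, :, None, None],
                 pos[None, None, :, :]),
                dwin,
            )
            dh = dpad[:, :, pl:pl + L]
        return loss, grads

    # -- utilities ---------------------------------------------------------

    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for k, v in weights.items():
            self.params[k] = v.copy()


def build_cnn(config: CNNConfig = CNNConfig(), seed: int = 0) -> CNNNet:
    """Instantiate an untrained network; raises ConfigError on a bad config."""
    return CNNNet(config, seed=seed)


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _mean_ce(model: CNNNet, X: np.ndarray, y: np.ndarray) -> float:
    proba = model.predict_proba(X)
    return float(-np.mean(np.log(proba[np.arange(len(y)), y] + 1e-12)))


def train_cnn(
    model: CNNNet,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    train_config: TrainConfig = TrainConfig(),
) -> list[tuple[int, float, float]]:
    """Train in place; returns history rows (epoch, train_loss, val_loss).

    Early stopping: when validation loss fails to improve on the best seen by
    at least ``early_stopping_min_delta`` for ``early_stopping_patience``
    consecutive epochs, training halts and the best-validation weights are
    restored.  Deterministic given ``train_config.seed``.
    """
    if np.unique(y_train).size < 2:
        raise ValueError("training set must contain both classes")
    if len(y_val) == 0:
        raise ValueError("validation set must be non-empty")
    cfg = train_config
    rng = np.random.default_rng(cfg.seed)
    opt = _Adam(model.params, cfg.learning_rate)
    best_val = math.inf
    best_weights = model.get_weights()
    wait = 0
    history: list[tuple[int, float, float]] = []
    n = len(y_train)
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            loss, grads = model.loss_and_grads(X_train[idx], y_train[idx])
            if not math.isfinite(loss):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}")
            opt.step(model.params, grads)
            losses.append(loss)
        val_loss = _mean_ce(model, X_val, y_val)
        if not math.isfinite(val_loss):
            raise RuntimeError(f"non-finite validation loss at epoch {epoch}")
        history.append((epoch, float(np.mean(losses)), val_loss))
        if best_val - val_loss > cfg.early_stopping_min_delta:
            best_val = val_loss
            best_weights = model.get_weights()
            wait = 0
        else:
            wait += 1
            if wait >= cfg.early_stopping_patience:
                break
    model.set_weights(best_weights)
    return history


def predict_cnn(model: CNNNet, grid: np.ndarray) -> np.ndarray:
    """Class probabilities (heart_failure, metabolic_syndrome) for grids."""
    grid = np.asarray(grid, float)
    single = grid.ndim == 2
    if single:
        grid = grid[None]
    expected = (model.config.n_channels, model.config.input_length)
    if grid.shape[1:] != expected:
        raise ValueError(f"grid shape {grid.shape[1:]} != configured {expected}")
    proba = model.predict_proba(grid)
    return proba[0] if single else proba


# ---------------------------------------------------------------------------
# preprocessing

def preprocess_for_cnn(
    record: PatientRecord,
    stages: Optional[StageAnnotation] = None,
    input_length: int = 256,
) -> np.ndarray:
    """Resample the 8 modeling channels onto a uniform grid (8 x input_length).

    The grid spans rest-start to recovery-end; each channel is piecewise-
    linearly interpolated.  Standardization with training-fold statistics is
    applied separately by the estimator.
    """
    series = record.series
    if len(series) < 3:
        raise ValueError("series shorter than 3 points")
    if stages is None:
        stages = cio.segment_stages(series)
    t = series.time
    grid_t = np.linspace(t[0], t[-1], input_length)
    rows = [np.interp(grid_t, t, getattr(series, c)) for c in MODEL_CHANNELS]
    return np.vstack(rows)


class CNNClassifier(BaseEstimator, ClassifierMixin):
    """sklearn-style estimator over the numpy CNN.

    ``fit`` resamples each training patient to the configured grid, computes
    per-channel standardization statistics from the training grids only,
    carves a stratified validation split out of the training patients for
    early stopping, and trains with the fixed regime (Adam 1e-4, batch 4,
    patience 15, min delta 0.01).
    """

    requires_fit = True
    _CLASS_ORDER = ("heart_failure", "metabolic_syndrome")

    def __init__(
        self,
        config: CNNConfig = CNNConfig(),
        learning_rate: float = 1e-4,
        batch_size: int = 4,
        early_stopping_patience: int = 15,
        early_stopping_min_delta: float = 0.01,
        max_epochs: int = 300,
        val_fraction: float = 0.25,
        random_state: int = 0,
    ):
        self.config = config
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.early_stopping_patience = early_stopping_patience
        self.early_stopping_min_delta = early_stopping_min_delta
        self.max_epochs = max_epochs
        self.val_fraction = val_fraction
        self.random_state = random_state

    def _grids(self, records: Sequence[PatientRecord]) -> np.ndarray:
        return np.stack([preprocess_for_cnn(r, input_length=self.config.input_length)
                         for r in records])

    def fit(self, X: Sequence[PatientRecord], y=None):
        if y is None:
            y = [r.label for r in X]
        y = np.asarray(y)
        self.classes_ = np.array(self._CLASS_ORDER)
        y_idx = np.array([self._CLASS_ORDER.index(v) for v in y])
        grids = self._grids(X)
        # training-fold standardization over samples and time, per channel
        self.channel_mean_ = grids.mean(axis=(0, 2))
        self.channel_scale_ = grids.std(axis=(0, 2))
        if np.any(self.channel_scale_ == 0):
            dead = [MODEL_CHANNELS[i] for i in np.flatnonzero(self.channel_scale_ == 0)]
            raise ValueError(f"zero-variance channel(s): {dead}")
        Xs = (grids - self.channel_mean_[:, None]) / self.channel_scale_[:, None]

        splitter = StratifiedShuffleSplit(
            n_splits=1, test_size=self.val_fraction, random_state=self.random_state
        )
        train_idx, val_idx = next(splitter.split(Xs, y_idx))
        self.model_ = build_cnn(self.config, seed=self.random_state)
        tc = TrainConfig(
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            early_stopping_patience=self.early_stopping_patience,
            early_stopping_min_delta=self.early_stopping_min_delta,
            max_epochs=self.max_epochs,
            seed=self.random_state,
        )
        self.history_ = train_cnn(
            self.model_, Xs[train_idx], y_idx[train_idx],
            Xs[val_idx], y_idx[val_idx], tc,
        )
        return self

    def predict_proba(self, X: Sequence[PatientRecord]) -> np.ndarray:
        grids = self._grids(X)
        Xs = (grids - self.channel_mean_[:, None]) / self.channel_scale_[:, None]
        return self.model_.predict_proba(Xs)

    def predict(self, X: Sequence[PatientRecord]) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]
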