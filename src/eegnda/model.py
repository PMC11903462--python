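"""The small "vanilla" CNN classifier, implemented directly in numpy.

Architecture: three convolutional stages — 32 filters kernel 3, 64 filters
kernel 5, 128 filters kernel 7, each convolving along the time axis over
all input feature maps — each followed by batch normalization, ReLU,
max pooling (2) and dropout (0.1); then fully connected layers ending in 6
independent sigmoid outputs (the classes co-occur, so the problem is
multi-label and trained with mean binary cross-entropy).

Forward and backward passes, Adam, and checkpointing are written out
explicitly on numpy arrays; gradients are covered by numerical
gradient-check tests. Training is single-epoch by default with periodic
validation checkpoints keeping the lowest-loss and highest-accuracy weight
snapshots.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConfigurationError, NumericError, SizingError
from .sampling import WindowBatch

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9
_BCE_EPS = 1e-7


def _as_time_kernel(k) -> int:
    """Accept a (k, 1) kernel tuple or a bare int; return the time extent."""
    if isinstance(k, (tuple, list)):
        if len(k) != 2 or k[1] != 1:
            raise ConfigurationError(f"kernels must be (k, 1)-shaped, got {k}")
        return int(k[0])
    return int(k)


@dataclass
class ModelSpec:
    """Architecture hyperparameters. Defaults follow the study's network."""

    window_length: int = 0
    n_channels: int = 32
    conv_filters: tuple[int, int, int] = (32, 64, 128)
    conv_kernels: tuple = ((3, 1), (5, 1), (7, 1))
    pool_kernel: tuple = (2, 1)
    dropout: float = 0.1
    dense_widths: tuple[int, ...] = (128, 64)
    n_classes: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conv_filters) != 3 or len(self.conv_kernels) != 3:
            raise ConfigurationError("exactly three convolutional stages required")
        if not all(a < b for a, b in zip(self.conv_filters, self.conv_filters[1:])):
            raise ConfigurationError("conv filter counts must be strictly increasing")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigurationError("dropout must lie in [0, 1)")
        if self.window_length < 0:
            raise ConfigurationError("window_length must be >= 0")

    @property
    def kernel_sizes(self) -> tuple[int, int, int]:
        return tuple(_as_time_kernel(k) for k in self.conv_kernels)

    @property
    def pool_size(self) -> int:
        return _as_time_kernel(self.pool_kernel)

    def stage_lengths(self) -> list[int]:
        """Time extents after each conv+pool stage; raises if any collapses."""
        if self.window_length < 1:
            raise ConfigurationError(
                "window_length must be set (>= 1) before building the model"
            )
        length = self.window_length
        lengths = []
        for i, k in enumerate(self.kernel_sizes):
            length = length - k + 1
            if length < 1:
                raise SizingError(
                    f"window of {self.window_length} samples collapses at "
                    f"conv stage {i + 1} (kernel {k})"
                )
            length //= self.pool_size
            if length < 1:
                raise SizingError(
                    f"window of {self.window_length} samples collapses at "
                    f"pool stage {i + 1}"
                )
            lengths.append(length)
        return lengths


@dataclass
class TrainConfig:
    """Optimization settings; a single epoch is the study's protocol."""

    epochs: int = 1
    batch_size: int = 64
    learning_rate: float = 1e-3
    checkpoint_every: int = 50
    grad_clip: float = 5.0  # global-norm clip; stabilizes the few-step regime
    seed: int = 0
    accuracy_mode: str = "per_label"  # or "exact" (exact-match over 6 labels)

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigurationError("epochs and batch_size must be >= 1")
        if self.checkpoint_every < 1:
            raise ConfigurationError("checkpoint_every must be >= 1")
        if self.accuracy_mode not in ("per_label", "exact"):
            raise ConfigurationError("accuracy_mode must be 'per_label' or 'exact'")


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """Valid cross-correlation along time. x [B,C,L], w [F,C,k] -> [B,F,L']."""
    windows = sliding_window_view(x, w.shape[2], axis=2)  # [B,C,L',k]
    out = np.tensordot(windows, w, axes=([1, 3], [1, 2]))  # [B,L',F]
    out = np.ascontiguousarray(out.transpose(0, 2, 1))
    out += b[None, :, None]
    return out, windows


def _conv_backward(
    dout: np.ndarray, windows: np.ndarray, w: np.ndarray, need_dx: bool = True
):
    db = dout.sum(axis=(0, 2))
    dw = np.tensordot(dout, windows, axes=([0, 2], [0, 2]))  # [F,C,k]
    if not need_dx:
        return None, dw, db
    k = w.shape[2]
    pad = np.pad(dout, ((0, 0), (0, 0), (k - 1, k - 1)))
    dwin = sliding_window_view(pad, k, axis=2)  # [B,F,L,k]
    dx = np.tensordot(dwin, w[:, :, ::-1], axes=([1, 3], [0, 2]))  # [B,L,C]
    return np.ascontiguousarray(dx.transpose(0, 2, 1)), dw, db


class CNN:
    """Three conv stages + dense head with explicit forward/backward."""

    def __init__(self, spec: ModelSpec, dtype=np.float32):
        self.spec = spec
        self.dtype = dtype
        self.stage_lengths = spec.stage_lengths()
        self.flat_dim = spec.conv_filters[-1] * self.stage_lengths[-1]
        self.params: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}
        self._init_params(np.random.default_rng(spec.seed))

    def _init_params(self, rng: np.random.Generator) -> None:
        spec = self.spec
        in_ch = spec.n_channels
        for i, (f, k) in enumerate(zip(spec.conv_filters, spec.kernel_sizes)):
            scale = math.sqrt(2.0 / (in_ch * k))  # He init for ReLU stacks
            self.params[f"conv{i}_W"] = (
                rng.standard_normal((f, in_ch, k)) * scale
            ).astype(self.dtype)
            self.params[f"conv{i}_b"] = np.zeros(f, dtype=self.dtype)
            self.params[f"bn{i}_gamma"] = np.ones(f, dtype=self.dtype)
            self.params[f"bn{i}_beta"] = np.zeros(f, dtype=self.dtype)
            self.buffers[f"bn{i}_mean"] = np.zeros(f, dtype=self.dtype)
            self.buffers[f"bn{i}_var"] = np.ones(f, dtype=self.dtype)
            in_ch = f
        widths = (self.flat_dim,) + tuple(spec.dense_widths) + (spec.n_classes,)
        for j, (a, b) in enumerate(zip(widths, widths[1:])):
            scale = math.sqrt(2.0 / a)
            self.params[f"fc{j}_W"] = (
                rng.standard_normal((a, b)) * scale
            ).astype(self.dtype)
            self.params[f"fc{j}_b"] = np.zeros(b, dtype=self.dtype)
        self.n_dense = len(widths) - 1

    def parameter_count(self) -> int:
        return sum(p.size for p in self.params.values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {
            "params": copy.deepcopy(self.params),
            "buffers": copy.deepcopy(self.buffers),
        }

    def load_state_dict(self, state: dict) -> None:
        self.params = copy.deepcopy(state["params"])
        self.buffers = copy.deepcopy(state["buffers"])

    # -- forward -----------------------------------------------------------

    def forward(
        self,
        x: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ):
        """Return (probabilities [B, n_classes], cache for backward)."""
        spec = self.spec
        x = np.ascontiguousarray(x, dtype=self.dtype)
        if x.shape[1] != spec.n_channels or x.shape[2] != spec.window_length:
            raise SizingError(
                f"input shape {x.shape[1:]} does not match model "
                f"({spec.n_channels}, {spec.window_length})"
            )
        cache: dict = {"stages": []}
        for i in range(3):
            w, b = self.params[f"conv{i}_W"], self.params[f"conv{i}_b"]
            z, windows = _conv_forward(x, w, b)

            gamma, beta = self.params[f"bn{i}_gamma"], self.params[f"bn{i}_beta"]
            if training:
                mu = z.mean(axis=(0, 2))
                var = z.var(axis=(0, 2))
                self.buffers[f"bn{i}_mean"] = (
                    _BN_MOMENTUM * self.buffers[f"bn{i}_mean"]
                    + (1 - _BN_MOMENTUM) * mu
                ).astype(self.dtype)
                self.buffers[f"bn{i}_var"] = (
                    _BN_MOMENTUM * self.buffers[f"bn{i}_var"]
                    + (1 - _BN_MOMENTUM) * var
                ).astype(self.dtype)
            else:
                mu = self.buffers[f"bn{i}_mean"]
                var = self.buffers[f"bn{i}_var"]
            inv_std = 1.0 / np.sqrt(var + _BN_EPS)
            xhat = (z - mu[None, :, None]) * inv_std[None, :, None]
            bn_out = gamma[None, :, None] * xhat + beta[None, :, None]

            relu_mask = bn_out > 0
            a = bn_out * relu_mask

            p = spec.pool_size
            l2 = a.shape[2] // p
            a_view = a[:, :, : l2 * p].reshape(a.shape[0], a.shape[1], l2, p)
            pool_idx = a_view.argmax(axis=3)
            pooled = np.take_along_axis(a_view, pool_idx[..., None], axis=3)[..., 0]

            if training and spec.dropout > 0:
                if rng is None:
                    raise ConfigurationError("training forward needs an rng")
                keep = (rng.random(pooled.shape) >= spec.dropout).astype(self.dtype)
                dropped = pooled * keep / (1.0 - spec.dropout)
            else:
                keep = None
                dropped = pooled

            cache["stages"].append(
                dict(
                    windows=windows,
                    w=w,
                    xhat=xhat,
                    inv_std=inv_std,
                    gamma=gamma,
                    relu_mask=relu_mask,
                    pool_idx=pool_idx,
                    pre_pool_len=a.shape[2],
                    keep=keep,
                )
            )
            x = dropped

        flat = x.reshape(x.shape[0], -1)
        cache["flat_shape"] = x.shape
        h = flat
        cache["dense_inputs"] = []
        for j in range(self.n_dense):
            cache["dense_inputs"].append(h)
            h = h @ self.params[f"fc{j}_W"] + self.params[f"fc{j}_b"]
            if j < self.n_dense - 1:
                h = np.maximum(h, 0.0)
        from scipy.special import expit

        logits = h.astype(np.float64)
        probs = expit(logits)
        cache["probs"] = probs
        return probs, cache

    # -- loss + backward ---------------------------------------------------

    def loss_and_grads(
        self, x: np.ndarray, y: np.ndarray, rng: np.random.Generator | None = None
    ) -> tuple[float, dict[str, np.ndarray]]:
        """Mean binary cross-entropy over the 6 outputs, with gradients."""
        probs, cache = self.forward(x, training=True, rng=rng)
        y = np.asarray(y, dtype=np.float64)
        p = np.clip(probs, _BCE_EPS, 1.0 - _BCE_EPS)
        loss = float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())

        grads: dict[str, np.ndarray] = {}
        dlogits = ((probs - y) / y.size).astype(self.dtype)

        dh = dlogits
        for j in range(self.n_dense - 1, -1, -1):
            h_in = cache["dense_inputs"][j]
            grads[f"fc{j}_W"] = h_in.T @ dh
            grads[f"fc{j}_b"] = dh.sum(axis=0)
            dh = dh @ self.params[f"fc{j}_W"].T
            if j > 0:
                dh = dh * (h_in > 0)

        dx = dh.reshape(cache["flat_shape"])
        for i in range(2, -1, -1):
            st = cache["stages"][i]
            if st["keep"] is not None:
                dx = dx * st["keep"] / (1.0 - self.spec.dropout)

            p_sz = self.spec.pool_size
            b_sz, f_sz, l2 = dx.shape
            da_view = np.zeros((b_sz, f_sz, l2, p_sz), dtype=self.dtype)
            np.put_along_axis(da_view, st["pool_idx"][..., None], dx[..., None], axis=3)
            da = np.zeros((b_sz, f_sz, st["pre_pool_len"]), dtype=self.dtype)
            da[:, :, : l2 * p_sz] = da_view.reshape(b_sz, f_sz, l2 * p_sz)

            dbn = da * st["relu_mask"]

            xhat, inv_std, gamma = st["xhat"], st["inv_std"], st["gamma"]
            m = dbn.shape[0] * dbn.shape[2]
            grads[f"bn{i}_beta"] = dbn.sum(axis=(0, 2))
            grads[f"bn{i}_gamma"] = (dbn * xhat).sum(axis=(0, 2))
            dz = (gamma * inv_std)[None, :, None] * (
                dbn
                - grads[f"bn{i}_beta"][None, :, None] / m
                - xhat * grads[f"bn{i}_gamma"][None, :, None] / m
            )

            dx, dw, db = _conv_backward(dz, st["windows"], st["w"], need_dx=i > 0)
            grads[f"conv{i}_W"] = dw
            grads[f"conv{i}_b"] = db
        return loss, grads


def build_model(spec: ModelSpec, dtype=np.float32) -> CNN:
    """Construct the network with deterministic (seeded) initial weights."""
    return CNN(spec, dtype=dtype)


@dataclass
class TrainedModel:
    """Final weights plus the checkpoint history and the two best snapshots."""

    model: CNN
    history: list[dict] = field(default_factory=list)
    best_loss_state: dict | None = None
    best_acc_state: dict | None = None

    @property
    def best_val_loss(self) -> float:
        return min(h["val_loss"] for h in self.history)

    @property
    def best_val_acc(self) -> float:
        return max(h["val_acc"] for h in self.history)


def _evaluate(
    model: CNN, data: np.ndarray, labels: np.ndarray, mode: str, chunk: int = 512
) -> tuple[float, float]:
    losses = []
    hits = []
    y_all = np.asarray(labels, dtype=np.float64)
    for lo in range(0, data.shape[0], chunk):
        x = data[lo : lo + chunk]
        y = y_all[lo : lo + chunk]
        probs, _ = model.forward(x, training=False)
        p = np.clip(probs, _BCE_EPS, 1.0 - _BCE_EPS)
        losses.append(-(y * np.log(p) + (1 - y) * np.log(1 - p)).sum())
        pred = probs > 0.5
        if mode == "per_label":
            hits.append((pred == y).sum())
        else:
            hits.append((pred == y).all(axis=1).sum() * y.shape[1])
    n = y_all.size
    return float(sum(losses) / n), float(sum(hits) / n)


def train(
    model: CNN,
    train_batch: WindowBatch,
    val_batch: WindowBatch,
    cfg: TrainConfig | None = None,
) -> TrainedModel:
    """Optimize mean BCE with Adam, checkpointing on the validation set.

    Validation loss and thresholded (0.5) accuracy are recorded every
    ``checkpoint_every`` batches and at each epoch end; the weight
    snapshots attaining the minimum loss and the maximum accuracy seen in
    that history are kept for the testing phase.
    """
    cfg = cfg or TrainConfig()
    if len(train_batch) == 0 or len(val_batch) == 0:
        raise SizingError("training and validation batches must be non-empty")

    rng = np.random.default_rng(cfg.seed)
    x_train = train_batch.data
    y_train = train_batch.labels

    m_state = {k: np.zeros_like(v, dtype=np.float64) for k, v in model.params.items()}
    v_state = {k: np.zeros_like(v, dtype=np.float64) for k, v in model.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    trained = TrainedModel(model=model)
    best_loss = np.inf
    best_acc = -np.inf

    def _checkpoint(batch_index: int) -> None:
        nonlocal best_loss, best_acc
        val_loss, val_acc = _evaluate(
            model, val_batch.data, val_batch.labels, cfg.accuracy_mode
        )
        trained.history.append(
            dict(step=batch_index, val_loss=val_loss, val_acc=val_acc)
        )
        if val_loss < best_loss:
            best_loss = val_loss
            trained.best_loss_state = model.state_dict()
        if val_acc > best_acc:
            best_acc = val_acc
            trained.best_acc_state = model.state_dict()

    n = x_train.shape[0]
    batch_index = 0
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            loss, grads = model.loss_and_grads(
                x_train[idx], y_train[idx].astype(np.float64), rng=rng
            )
            if not np.isfinite(loss):
                raise NumericError(f"non-finite loss at batch {batch_index}")
            if cfg.grad_clip > 0:
                norm = math.sqrt(
                    sum(float((g.astype(np.float64) ** 2).sum())
                        for g in grads.values())
                )
                if norm > cfg.grad_clip:
                    scale = cfg.grad_clip / norm
                    grads = {k: g * scale for k, g in grads.items()}
            step += 1
            for key, grad in grads.items():
                m_state[key] = beta1 * m_state[key] + (1 - beta1) * grad
                v_state[key] = beta2 * v_state[key] + (1 - beta2) * grad.astype(
                    np.float64
                ) ** 2
                m_hat = m_state[key] / (1 - beta1**step)
                v_hat = v_state[key] / (1 - beta2**step)
                model.params[key] = (
                    model.params[key]
                    - cfg.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
                ).astype(model.dtype)
            batch_index += 1
            if batch_index % cfg.checkpoint_every == 0:
                _checkpoint(batch_index)
        _checkpoint(batch_index)
    return trained


def predict(
    trained: TrainedModel, batch: WindowBatch, which: str = "best_loss"
) -> np.ndarray:
    """Per-class probabilities from a saved checkpoint (inference mode).

    Dropout is disabled and batch normalization uses its running statistics,
    so repeated calls are identical.
    """
    states = {
        "best_loss": trained.best_loss_state,
        "best_acc": trained.best_acc_state,
        "final": trained.model.state_dict(),
    }
    if which not in states:
        raise ConfigurationError(f"unknown checkpoint {which!r}")
    state = states[which]
    if state is None:
        raise ConfigurationError(f"checkpoint {which!r} was never recorded")
    if batch.window_length != trained.model.spec.window_length:
        raise SizingError(
            f"batch window length {batch.window_length} does not match model "
            f"window length {trained.model.spec.window_length}"
        )
    current = trained.model.state_dict()
    trained.model.load_state_dict(state)
    try:
        outputs = []
        for lo in range(0, len(batch), 512):
            probs, _ = trained.model.forward(batch.data[lo : lo + 512])
            outputs.append(probs)
    finally:
        trained.model.load_state_dict(current)
    return np.concatenate(outputs, axis=0)
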