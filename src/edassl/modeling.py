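"""Pretext forecaster, downstream stress regressor, training and transfer.

Two sibling 1-D CNNs share one convolutional feature extractor:

* the **pretext forecaster** maps a 7000-sample window to the next 40 samples
  (conv filters 40 → 30 → 18 → 30, leaky ReLU, then dense 70 → 30 → linear 40);
* the **downstream regressor** maps the same window to a scalar ordinal
  stress target (same conv stack, dense 50 → 30 → 10 → linear 1).

After self-supervised pre-training the conv stack is copied bit-exactly into
the downstream model and frozen; only the dense head is fine-tuned. The
purely supervised control uses the identical downstream architecture with all
layers trainable and a fresh initialization.

Kernel length 16, stride 4, valid padding and no pooling are package choices
(frame counts 7000 → 1747 → 433 → 105 → 23); all are config-exposed and
recorded in checkpoint manifests.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np

from .nn import Adam, Conv1D, Dense, Flatten, LeakyReLU, Sequential, mse_loss
from .simulate import ValidationError
from .windowing import LabeledWindow, PretextPair

__all__ = [
    "PretextArchitecture",
    "DownstreamArchitecture",
    "TrainConfig",
    "ConstructionError",
    "build_pretext_model",
    "build_downstream_model",
    "conv_stack_frames",
    "pretrain",
    "transfer_and_freeze",
    "finetune",
    "train_supervised",
    "evaluate_regressor",
    "extract_frozen_features",
    "rmse",
    "last_value_baseline_rmse",
    "window_mean_baseline_rmse",
    "pairs_to_arrays",
    "windows_to_arrays",
]


class ConstructionError(ValueError):
    """Model could not be assembled from the given architecture."""


@dataclass(frozen=True)
class PretextArchitecture:
    """Forecaster: 7000-sample input → 40-sample continuation."""

    input_len: int = 7000
    conv_filters: tuple[int, ...] = (40, 30, 18, 30)
    kernel: int = 16
    stride: int = 4
    dense_units: tuple[int, ...] = (70, 30)
    output_units: int = 40
    leaky_alpha: float = 0.01


@dataclass(frozen=True)
class DownstreamArchitecture:
    """Stress regressor: shared conv stack, dense 50/30/10, scalar output."""

    input_len: int = 7000
    conv_filters: tuple[int, ...] = (40, 30, 18, 30)
    kernel: int = 16
    stride: int = 4
    dense_units: tuple[int, ...] = (50, 30, 10)
    output_units: int = 1
    leaky_alpha: float = 0.01


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer and schedule settings shared by all training entry points.

    ``batch_size=None`` auto-selects: 32 when more than 32 examples are
    available, otherwise one full batch — tiny label budgets train with
    full-batch updates. When ``val_fraction > 0`` a seeded validation split
    drives early stopping on validation RMSE (best weights restored);
    otherwise training stops when the epoch training loss has not improved by
    ``tol`` for ``patience`` consecutive epochs.
    """

    optimizer: str = "adam"
    lr: float = 1e-3
    batch_size: int | None = None
    max_epochs: int = 200
    patience: int = 15
    val_fraction: float = 0.0
    seed: int = 0
    tol: float = 1e-5
    bias_init: str = "zeros"
    #: optional convergence target: stop as soon as the monitored metric
    #: (validation RMSE, or training loss without a validation split) drops
    #: to or below this value
    target_metric: float | None = None
    #: "constant" keeps lr fixed; "cosine" anneals it to ~0 over max_epochs
    lr_schedule: str = "constant"
    #: optional Polyak/EMA weight averaging: validation uses (and the final
    #: model keeps) an exponential moving average of the weights with this
    #: per-step decay; None disables. Requires a validation split.
    ema_decay: float | None = None
    #: optional wall-clock cap in seconds: no new epoch starts after it is
    #: exhausted (useful to bound long pre-training runs deterministically
    #: in epochs completed only up to timing jitter)
    time_budget_s: float | None = None

    def __post_init__(self) -> None:
        if self.optimizer != "adam":
            raise ValidationError(f"unsupported optimizer {self.optimizer!r}")
        if self.lr <= 0:
            raise ValidationError(f"lr must be > 0, got {self.lr}")
        if self.max_epochs < 1:
            raise ValidationError("max_epochs must be >= 1")
        if not 0 <= self.patience < self.max_epochs:
            raise ValidationError("patience must satisfy 0 <= patience < max_epochs")
        if not 0.0 <= self.val_fraction < 1.0:
            raise ValidationError("val_fraction must be in [0, 1)")
        if self.bias_init not in ("zeros", "target_mean"):
            raise ValidationError(f"unknown bias_init {self.bias_init!r}")
        if self.lr_schedule not in ("constant", "cosine"):
            raise ValidationError(f"unknown lr_schedule {self.lr_schedule!r}")
        if self.ema_decay is not None and not 0.0 < self.ema_decay < 1.0:
            raise ValidationError("ema_decay must be in (0, 1)")
        if self.ema_decay is not None and self.val_fraction <= 0:
            raise ValidationError("ema_decay requires a validation split")


def pretext_train_config(**overrides) -> TrainConfig:
    """Default pre-training schedule: Adam 1e-3 annealed by a cosine decay,
    batch 32, 10% validation split with early stopping on validation RMSE."""
    base = dict(
        lr=1e-3,
        batch_size=32,
        max_epochs=20,
        patience=3,
        val_fraction=0.1,
        lr_schedule="cosine",
    )
    base.update(overrides)
    return TrainConfig(**base)


def downstream_train_config(**overrides) -> TrainConfig:
    """Default fine-tune/supervised schedule.

    Adam 2e-3, a fixed 10-epoch budget (identical for both arms of the
    comparison, so neither method gets more optimization than the other),
    full-batch updates for tiny label sets, minibatch 32 above that, and the
    output bias initialized to the training-label mean so no epochs are spent
    merely recentering the prediction scale.
    """
    base = dict(
        lr=2e-3,
        batch_size=None,
        max_epochs=10,
        patience=0,
        val_fraction=0.0,
        bias_init="target_mean",
    )
    base.update(overrides)
    return TrainConfig(**base)


def conv_stack_frames(arch) -> list[int]:
    """Per-layer frame counts of the conv stack, input length first."""
    frames = [arch.input_len]
    n = arch.input_len
    for _ in arch.conv_filters:
        if n < arch.kernel:
            raise ConstructionError(
                f"conv input of {n} frames is shorter than kernel {arch.kernel}"
            )
        n = (n - arch.kernel) // arch.stride + 1
        frames.append(n)
    return frames


def _build(arch, seed: int) -> Sequential:
    rng = np.random.default_rng(seed)
    layers: list = []
    in_ch = 1
    for i, f in enumerate(arch.conv_filters):
        layers.append(
            Conv1D(
                in_ch, f, kernel=arch.kernel, stride=arch.stride, rng=rng, is_first=(i == 0)
            )
        )
        layers.append(LeakyReLU(arch.leaky_alpha))
        in_ch = f
    frames = conv_stack_frames(arch)
    flat = frames[-1] * arch.conv_filters[-1]
    if flat <= 0:
        raise ConstructionError("conv stack collapsed to zero features")
    layers.append(Flatten())
    width = flat
    for u in arch.dense_units:
        layers.append(Dense(width, u, rng=rng))
        layers.append(LeakyReLU(arch.leaky_alpha))
        width = u
    layers.append(Dense(width, arch.output_units, rng=rng))
    return Sequential(layers)


def build_pretext_model(arch: PretextArchitecture = PretextArchitecture(), seed: int = 0) -> Sequential:
    """Construct the forecaster with seed-deterministic initial weights."""
    return _build(arch, seed)


def build_downstream_model(arch: DownstreamArchitecture = DownstreamArchitecture(), seed: int = 0) -> Sequential:
    """Construct the stress regressor (all layers trainable, fresh weights)."""
    return _build(arch, seed)


def pairs_to_arrays(pairs: list[PretextPair]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([p.input for p in pairs]).astype(np.float32)[..., None]
    y = np.stack([p.target for p in pairs]).astype(np.float32)
    return x, y


def windows_to_arrays(windows: list[LabeledWindow]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([w.input for w in windows]).astype(np.float32)[..., None]
    y = np.array([[w.target] for w in windows], dtype=np.float32)
    return x, y


def _frozen_prefix_end(model: Sequential) -> int:
    """Index of the first layer holding trainable parameters.

    Everything before it is deterministic and fixed during training, so its
    activations can be computed once and cached — a pure speed optimization
    that leaves the arithmetic unchanged.
    """
    for i, layer in enumerate(model.layers):
        if layer.params() and layer.trainable:
            return i
    return len(model.layers)


def extract_frozen_features(model: Sequential, x: np.ndarray) -> np.ndarray:
    """Activations at the end of the leading frozen (non-trainable) prefix.

    For a transferred-and-frozen model this is the flattened conv-stack
    output; it depends only on the frozen weights, so callers may compute it
    once per window set and reuse it across many head-training runs.
    """
    split = _frozen_prefix_end(model)
    if split == 0:
        raise ValidationError("model has no frozen prefix")
    return Sequential(model.layers[:split]).predict(x)


def _fit(
    model: Sequential,
    x: np.ndarray,
    y: np.ndarray,
    config: TrainConfig,
    features: np.ndarray | None = None,
) -> dict:
    """Seeded minibatch Adam/MSE loop with early stopping; returns history.

    ``features``, if given, must equal ``extract_frozen_features(model, x)``;
    it skips recomputing the frozen prefix.
    """
    n = len(y)
    rng = np.random.default_rng(config.seed)

    split = _frozen_prefix_end(model)
    if split > 0:
        head = Sequential(model.layers[split:])
        if split >= len(model.layers):
            raise ValidationError("model has no trainable parameters")
        feats = features if features is not None else Sequential(model.layers[:split]).predict(x)
    else:
        head, feats = model, x

    n_val = int(n * config.val_fraction)
    if config.val_fraction > 0 and n_val == 0 and n > 1:
        n_val = 1
    order = rng.permutation(n)
    val_idx, train_idx = order[:n_val], order[n_val:]
    if len(train_idx) == 0:
        raise ValidationError("validation split left no training examples")
    xt, yt = feats[train_idx], y[train_idx]
    xv, yv = feats[val_idx], y[val_idx]

    if config.bias_init == "target_mean":
        last_dense = next(
            (l for l in reversed(head.layers) if isinstance(l, Dense)), None
        )
        if last_dense is not None:
            last_dense.b[...] = np.float32(yt.mean())

    batch = config.batch_size or (32 if len(xt) > 32 else len(xt))
    opt = Adam(head, lr=config.lr)

    # the first conv layer's im2col matrix depends only on the data, so for
    # label-budget-sized training sets it is computed once and re-sliced
    cols_cache = None
    first = head.layers[0]
    if isinstance(first, Conv1D) and len(xt) <= 512:
        cols_cache = first.im2col(xt)

    def _forward_batch(idx):
        if cols_cache is None:
            return head.forward(xt[idx])
        h = first.forward(None, cols=cols_cache[idx])
        for layer in head.layers[1:]:
            h = layer.forward(h)
        return h

    ema = [p.copy() for p in head.trainable_params()] if config.ema_decay else None
    t_start = time.monotonic()

    history: dict = {"train_loss": [], "val_rmse": []}
    best = np.inf
    best_weights = None
    stall = 0
    for _epoch in range(config.max_epochs):
        if config.lr_schedule == "cosine":
            opt.lr = config.lr * 0.5 * (1.0 + np.cos(np.pi * _epoch / config.max_epochs))
        perm = rng.permutation(len(xt))
        losses = []
        for i in range(0, len(xt), batch):
            idx = perm[i : i + batch]
            pred = _forward_batch(idx)
            loss, grad = mse_loss(pred, yt[idx])
            head.backward(grad)
            opt.step()
            if ema is not None:
                d = config.ema_decay
                for s, p in zip(ema, head.trainable_params()):
                    s *= d
                    s += (1.0 - d) * p
            losses.append(loss * len(idx))
        train_loss = float(np.sum(losses) / len(xt))
        history["train_loss"].append(train_loss)
        if n_val > 0:
            raw = None
            if ema is not None:
                # validate (and checkpoint) the averaged weights
                raw = [p.copy() for p in head.trainable_params()]
                for p, s in zip(head.trainable_params(), ema):
                    p[...] = s
            val_rmse = rmse(yv.ravel(), head.predict(xv).ravel())
            history["val_rmse"].append(val_rmse)
            monitored = val_rmse
            improved = monitored < best - config.tol
            reached = config.target_metric is not None and monitored <= config.target_metric
            if improved or reached:
                best_weights = head.get_weights()
            if raw is not None:
                for p, r in zip(head.trainable_params(), raw):
                    p[...] = r
        else:
            monitored = train_loss
            improved = monitored < best - config.tol
            reached = config.target_metric is not None and monitored <= config.target_metric
        if improved:
            best = monitored
            stall = 0
        else:
            stall += 1
            if config.patience and stall >= config.patience:
                break
        if reached:
            break
        if (
            config.time_budget_s is not None
            and time.monotonic() - t_start > config.time_budget_s
        ):
            break
    if best_weights is not None:
        head.set_weights(best_weights)
    return history


def pretrain(model: Sequential, pairs: list[PretextPair], config: TrainConfig | None = None) -> dict:
    """Self-supervised pre-training: minimize MSE of the 40-sample forecast.

    Trains in place and returns the history, including per-epoch validation
    RMSE; stops early when validation RMSE stops improving and restores the
    best weights seen.
    """
    if not pairs:
        raise ValidationError("pretrain requires at least one pretext pair")
    config = config or pretext_train_config()
    if config.val_fraction <= 0:
        raise ValidationError("pretrain requires val_fraction > 0 for early stopping")
    x, y = pairs_to_arrays(pairs)
    return _fit(model, x, y, config)


def transfer_and_freeze(
    pretext_model: Sequential,
    downstream_arch: DownstreamArchitecture = DownstreamArchitecture(),
    seed: int = 0,
) -> Sequential:
    """Copy the pretext conv stack into a fresh downstream model and freeze it.

    Conv weights are copied bit-exactly and marked non-trainable; the dense
    head keeps its fresh seed-deterministic initialization.
    """
    target = build_downstream_model(downstream_arch, seed=seed)
    src_convs = [l for l in pretext_model.layers if isinstance(l, Conv1D)]
    dst_convs = [l for l in target.layers if isinstance(l, Conv1D)]
    if len(src_convs) != len(dst_convs):
        raise ConstructionError(
            f"conv stack depth mismatch: {len(src_convs)} vs {len(dst_convs)}"
        )
    for i, (src, dst) in enumerate(zip(src_convs, dst_convs)):
        if src.W.shape != dst.W.shape or src.stride != dst.stride:
            raise ConstructionError(
                f"conv layer {i}: incompatible shape {src.W.shape} vs {dst.W.shape}"
            )
        dst.W[...] = src.W
        dst.b[...] = src.b
        dst.trainable = False
    return target


def finetune(
    model: Sequential,
    windows: list[LabeledWindow],
    config: TrainConfig | None = None,
    features: np.ndarray | None = None,
) -> dict:
    """Fine-tune a transferred model's dense head on labelled windows.

    The frozen conv features are computed once per call (or supplied via
    ``features``, one row per window), so training costs only dense-head
    arithmetic. Supports tiny label sets (10 windows) via full-batch updates.
    """
    if not windows:
        raise ValidationError("finetune requires at least one labelled window")
    config = config or downstream_train_config()
    if features is not None:
        _, y = None, np.array([[w.target] for w in windows], dtype=np.float32)
        return _fit(model, None, y, config, features=features.astype(np.float32))
    x, y = windows_to_arrays(windows)
    return _fit(model, x, y, config)


def train_supervised(
    arch: DownstreamArchitecture,
    windows: list[LabeledWindow],
    config: TrainConfig | None = None,
    seed: int = 0,
) -> tuple[Sequential, dict]:
    """The purely supervised control: identical architecture, all layers
    trainable, fresh initialization, same loss and schedule as finetune."""
    if not windows:
        raise ValidationError("train_supervised requires at least one labelled window")
    config = config or downstream_train_config()
    model = build_downstream_model(arch, seed=seed)
    x, y = windows_to_arrays(windows)
    history = _fit(model, x, y, config)
    return model, history


def rmse(y_true, y_pred) -> float:
    """Root-mean-squared error: sqrt of the mean squared difference."""
    a = np.asarray(y_true, dtype=np.float64).ravel()
    b = np.asarray(y_pred, dtype=np.float64).ravel()
    if a.size == 0:
        raise ValidationError("rmse requires at least one element")
    if a.shape != b.shape:
        raise ValidationError(f"length mismatch: {a.size} vs {b.size}")
    return float(np.sqrt(np.mean(np.square(a - b))))


def evaluate_regressor(
    model: Sequential,
    windows: list[LabeledWindow],
    features: np.ndarray | None = None,
) -> float:
    """Test RMSE of a stress regressor on labelled windows.

    ``features`` (one frozen-prefix row per window) skips the conv forward
    pass, exactly as in :func:`finetune`.
    """
    y = np.array([w.target for w in windows], dtype=np.float64)
    if features is not None:
        split = _frozen_prefix_end(model)
        head = Sequential(model.layers[split:])
        pred = head.predict(features.astype(np.float32))
    else:
        x, _ = windows_to_arrays(windows)
        pred = model.predict(x)
    return rmse(y, pred.ravel())


def last_value_baseline_rmse(pairs: list[PretextPair]) -> float:
    """Forecast RMSE of repeating each window's last observed value."""
    if not pairs:
        raise ValidationError("baseline requires at least one pair")
    _, y = pairs_to_arrays(pairs)
    last = np.array([p.input[-1] for p in pairs], dtype=np.float32)[:, None]
    return rmse(y, np.broadcast_to(last, y.shape))


def window_mean_baseline_rmse(pairs: list[PretextPair]) -> float:
    """Forecast RMSE of predicting each window's mean value."""
    if not pairs:
        raise ValidationError("baseline requires at least one pair")
    _, y = pairs_to_arrays(pairs)
    mean = np.array([p.input.mean() for p in pairs], dtype=np.float32)[:, None]
    return rmse(y, np.broadcast_to(mean, y.shape))
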