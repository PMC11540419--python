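"""A compact NumPy neural-network engine for 1-D convolutional regressors.

Implements exactly what the stress-sensing models need and nothing more:
valid-padding 1-D convolutions (lowered to BLAS GEMM via an im2col view),
leaky-ReLU activations, dense layers, flattening, mean-squared-error loss and
an Adam optimizer, with per-layer freezing and fully seeded deterministic
initialization. All parameters and activations are float32; with a
single-threaded BLAS, identical seeds and data reproduce identical weights
bit for bit.

Shapes follow the channels-last convention: convolution inputs are
``(batch, length, channels)``, dense inputs ``(batch, features)``.
"""

from __future__ import annotations

import numpy as np

from .simulate import ValidationError

__all__ = [
    "Conv1D",
    "Dense",
    "LeakyReLU",
    "Flatten",
    "Sequential",
    "Adam",
    "mse_loss",
]


class Layer:
    """Base class: a differentiable module with (possibly empty) parameters."""

    trainable: bool = True

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _he_uniform(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Conv1D(Layer):
    """Valid-padding strided 1-D convolution.

    Output length is ``floor((L - kernel)/stride) + 1``. The kernel is stored
    flat as ``(kernel*channels, filters)`` — matching the (tap, channel) order
    of the im2col matrix — so the forward pass and the weight gradient are
    each a single GEMM.

    ``is_first=True`` marks the model's input layer, whose input gradient
    nobody consumes; its backward pass then skips that computation.
    """

    def __init__(self, in_channels: int, filters: int, kernel: int = 16, stride: int = 4, *, rng: np.random.Generator, is_first: bool = False):
        if kernel <= 0 or stride <= 0 or filters <= 0 or in_channels <= 0:
            raise ValidationError("Conv1D sizes must be positive")
        self.in_channels = in_channels
        self.filters = filters
        self.kernel = kernel
        self.stride = stride
        self.is_first = is_first
        fan_in = in_channels * kernel
        self.W = _he_uniform(rng, fan_in, (fan_in, filters))
        self.b = np.zeros(filters, dtype=np.float32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._in_len = 0
        self._bufs: dict = {}

    def _buf(self, name: str, shape: tuple, zero: bool = False) -> np.ndarray:
        """Reusable float32 scratch buffer (large allocations are costly)."""
        buf = self._bufs.get(name)
        if buf is None or buf.shape != shape:
            buf = np.empty(shape, dtype=np.float32)
            self._bufs[name] = buf
        if zero:
            buf[...] = 0.0
        return buf

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.gW, self.gb]

    def out_len(self, in_len: int) -> int:
        if in_len < self.kernel:
            raise ValidationError(
                f"input length {in_len} shorter than kernel {self.kernel}"
            )
        return (in_len - self.kernel) // self.stride + 1

    @property
    def _frame_mode(self) -> bool:
        # when the stride divides the kernel, taps group into kernel/stride
        # whole frames of stride*channels contiguous values, so im2col and the
        # input gradient reduce to a few large contiguous copies/adds
        return self.kernel % self.stride == 0 and self.in_channels * self.stride >= 32

    def _frames(self, x: np.ndarray) -> np.ndarray:
        """Zero-pad to a stride multiple and view as (batch, frames, stride*c)."""
        n, length, c = x.shape
        s = self.stride
        f = -(-length // s)
        if length != f * s or not x.flags.c_contiguous:
            xp = self._buf("pad", (n, f * s, c))
            xp[:, :length] = x
            xp[:, length:] = 0.0
            x = xp
        return x.reshape(n, f, s * c)

    def im2col(self, x: np.ndarray, reuse: bool = False) -> np.ndarray:
        """Lower windows to a ``(batch, frames, kernel*channels)`` matrix.

        Layout is tap-major (tap index outer, channel inner), matching the
        flat kernel ``W``. With ``reuse=True`` the returned array is a scratch
        buffer overwritten by the next call.
        """
        x = np.asarray(x, dtype=np.float32)
        n, length, c = x.shape
        t = self.out_len(length)
        if self._frame_mode:
            xr = self._frames(x)
            j_max = self.kernel // self.stride
            shape = (n, t, j_max, self.stride * c)
            cols = self._buf("cols", shape) if reuse else np.empty(shape, dtype=np.float32)
            for j in range(j_max):
                cols[:, :, j, :] = xr[:, j : j + t]
            return cols.reshape(n, t, -1)
        view = np.lib.stride_tricks.sliding_window_view(x, self.kernel, axis=1)
        # (n, starts, c, k) -> keep strided starts, put taps before channels so
        # the innermost copied axis is the contiguous channel axis
        view = view[:, :: self.stride][:, :t].transpose(0, 1, 3, 2)
        return np.ascontiguousarray(view).reshape(n, t, -1)

    def forward(self, x: np.ndarray, cols: np.ndarray | None = None) -> np.ndarray:
        if cols is None:
            if x.ndim != 3 or x.shape[2] != self.in_channels:
                raise ValidationError(
                    f"expected (batch, length, {self.in_channels}), got {x.shape}"
                )
            self._in_len = x.shape[1]
            cols = self.im2col(x, reuse=True)
        self._cols = cols
        n, t, _ = cols.shape
        out = self._buf("out", (n, t, self.filters))
        np.matmul(cols, self.W, out=out)
        out += self.b
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols = self._cols
        n, t, _ = dout.shape
        dout = np.ascontiguousarray(dout, dtype=np.float32)
        flat_d = dout.reshape(n * t, self.filters)
        self.gW[...] = cols.reshape(n * t, -1).T @ flat_d
        self.gb[...] = flat_d.sum(axis=0)
        self._cols = None
        if self.is_first:
            return np.empty(0, dtype=np.float32)
        # gradient w.r.t. input: scatter the per-window gradients back
        c, s = self.in_channels, self.stride
        gcols = self._buf("gcols", (n * t, self.kernel * c))
        np.matmul(flat_d, self.W.T, out=gcols)
        if self._frame_mode:
            j_max = self.kernel // s
            gcols = gcols.reshape(n, t, j_max, s * c)
            f = -(-self._in_len // s)
            dxr = self._buf("dxr", (n, f, s * c), zero=True)
            for j in range(j_max):
                dxr[:, j : j + t] += gcols[:, :, j]
            return dxr.reshape(n, f * s, c)[:, : self._in_len]
        gcols = gcols.reshape(n, t, self.kernel, c)
        dx = self._buf("dx", (n, self._in_len, c), zero=True)
        for k in range(self.kernel):
            dx[:, k : k + s * t : s] += gcols[:, :, k, :]
        return dx


class Dense(Layer):
    """Fully connected layer ``y = x W + b``."""

    def __init__(self, in_features: int, units: int, *, rng: np.random.Generator):
        if in_features <= 0 or units <= 0:
            raise ValidationError("Dense sizes must be positive")
        self.in_features = in_features
        self.units = units
        self.W = _he_uniform(rng, in_features, (in_features, units))
        self.b = np.zeros(units, dtype=np.float32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.gW, self.gb]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 2 or x.shape[1] != self.in_features:
            raise ValidationError(
                f"expected (batch, {self.in_features}), got {x.shape}"
            )
        self._x = np.asarray(x, dtype=np.float32)
        return self._x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dout = np.asarray(dout, dtype=np.float32)
        self.gW[...] = self._x.T @ dout
        self.gb[...] = dout.sum(axis=0)
        dx = dout @ self.W.T
        self._x = None
        return dx


class LeakyReLU(Layer):
    """max(x, alpha·x); default negative slope 0.01."""

    def __init__(self, alpha: float = 0.01):
        self.alpha = np.float32(alpha)
        self._slope: np.ndarray | None = None
        self._bufs: dict = {}

    def _buf(self, name: str, shape: tuple, dtype=np.float32) -> np.ndarray:
        buf = self._bufs.get(name)
        if buf is None or buf.shape != shape:
            buf = np.empty(shape, dtype=dtype)
            self._bufs[name] = buf
        return buf

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = self._buf("out", x.shape)
        neg = self._buf("neg", x.shape, dtype=bool)
        np.less(x, 0, out=neg)
        np.multiply(x, self.alpha, out=out)
        np.maximum(x, out, out=out)  # for 0 < alpha < 1 this is leaky ReLU
        slope = self._buf("slope", x.shape)
        slope.fill(1.0)
        np.copyto(slope, self.alpha, where=neg)
        self._slope = slope
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        # in place: every backward consumes its upstream gradient exactly once
        dout *= self._slope
        self._slope = None
        return dout


class Flatten(Layer):
    """(batch, length, channels) -> (batch, length*channels)."""

    def __init__(self):
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return np.ascontiguousarray(x).reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Sequential:
    """An ordered chain of layers with a shared forward/backward contract."""

    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Forward pass in evaluation mode, batched to bound memory.

        Outputs are copied out of layer scratch buffers before the next batch.
        """
        outs = [
            np.array(self.forward(x[i : i + batch_size]))
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(outs, axis=0)

    def trainable_params(self) -> list[np.ndarray]:
        return [p for l in self.layers if l.trainable for p in l.params()]

    def trainable_grads(self) -> list[np.ndarray]:
        return [g for l in self.layers if l.trainable for g in l.grads()]

    def all_params(self) -> list[np.ndarray]:
        return [p for l in self.layers for p in l.params()]

    def n_params(self, trainable_only: bool = False) -> int:
        params = self.trainable_params() if trainable_only else self.all_params()
        return int(sum(p.size for p in params))

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.all_params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.all_params()
        if len(weights) != len(params):
            raise ValidationError(
                f"expected {len(params)} arrays, got {len(weights)}"
            )
        for p, w in zip(params, weights):
            if p.shape != w.shape:
                raise ValidationError(f"shape mismatch {p.shape} vs {w.shape}")
            p[...] = w


class Adam:
    """Adam optimizer over a model's trainable parameters."""

    def __init__(self, model: Sequential, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        if lr <= 0:
            raise ValidationError(f"learning rate must be > 0, got {lr}")
        self.model = model
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p) for p in model.trainable_params()]
        self._v = [np.zeros_like(p) for p in model.trainable_params()]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1**self.t
        corr2 = 1.0 - b2**self.t
        for p, g, m, v in zip(
            self.model.trainable_params(),
            self.model.trainable_grads(),
            self._m,
            self._v,
        ):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * np.square(g)
            p -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over all elements and its gradient w.r.t. pred."""
    if pred.shape != target.shape:
        raise ValidationError(f"shape mismatch {pred.shape} vs {target.shape}")
    diff = (pred - target).astype(np.float32)
    loss = float(np.mean(np.square(diff, dtype=np.float64)))
    return loss, (2.0 / diff.size) * diff
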