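"""Minimal neural-network primitives with explicit gradients.

All layers operate on numpy float64 arrays.  Sequence tensors are shaped
(batch, channels, length); per-sample valid lengths thread through the
convolutional stack so that zero-padding never influences batch-norm
statistics or the global max pool.

Each layer caches what its backward pass needs during ``forward`` and
accumulates parameter gradients into ``d<name>`` attributes; ``params()``
yields (array, grad) pairs updated in place by :class:`Adam`.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv1D",
    "MaskedBatchNorm1D",
    "LeakyReLU",
    "AvgPool1D",
    "masked_global_max",
    "Affine",
    "Dropout",
    "Adam",
    "sigmoid",
    "length_mask",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def length_mask(lengths: np.ndarray, total: int) -> np.ndarray:
    """Boolean (batch, total) mask of valid positions."""
    return np.arange(total)[None, :] < np.asarray(lengths)[:, None]


class Conv1D:
    """1-D convolution along the sequence axis with full-height filters."""

    def __init__(self, in_channels: int, out_channels: int, width: int,
                 rng: np.random.Generator):
        if width < 1:
            raise ValueError("filter width must be >= 1")
        scale = np.sqrt(2.0 / (in_channels * width))
        self.W = rng.normal(0.0, scale, size=(out_channels, in_channels, width))
        self.b = np.zeros(out_channels)
        self.width = width
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def out_length(self, length: int) -> int:
        return length - self.width + 1

    def _cols(self, x: np.ndarray) -> np.ndarray:
        # (B, C, L) -> (B, C*width, L_out) sliding windows
        B, C, L = x.shape
        L_out = L - self.width + 1
        windows = np.lib.stride_tricks.sliding_window_view(
            x, self.width, axis=2
        )  # (B, C, L_out, width)
        return windows.transpose(0, 1, 3, 2).reshape(B, C * self.width, L_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[2] < self.width:
            raise ValueError(
                f"filter width {self.width} exceeds input length {x.shape[2]}"
            )
        self._x_shape = x.shape
        B = x.shape[0]
        cols = self._cols(x)  # (B, K, L_out)
        self._cols_flat = cols.transpose(0, 2, 1).reshape(-1, cols.shape[1])
        self._L_out = cols.shape[2]
        Wm = self.W.reshape(self.W.shape[0], -1)
        out = self._cols_flat @ Wm.T  # (B*L_out, O)
        out = out.reshape(B, self._L_out, -1).transpose(0, 2, 1)
        return out + self.b[None, :, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, C, L = self._x_shape
        Wm = self.W.reshape(self.W.shape[0], -1)
        dout_flat = dout.transpose(0, 2, 1).reshape(-1, dout.shape[1])
        self.dW += (dout_flat.T @ self._cols_flat).reshape(self.W.shape)
        self.db += dout.sum(axis=(0, 2))
        dcols_flat = dout_flat @ Wm  # (B*L_out, K)
        dcols = dcols_flat.reshape(B, self._L_out, C * self.width)
        dcols = dcols.transpose(0, 2, 1).reshape(B, C, self.width, -1)
        dx = np.zeros((B, C, L))
        L_out = L - self.width + 1
        for w in range(self.width):
            dx[:, :, w : w + L_out] += dcols[:, :, w, :]
        return dx

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def zero_grad(self):
        self.dW[...] = 0.0
        self.db[...] = 0.0


class MaskedBatchNorm1D:
    """Per-channel batch normalization over valid sequence positions only.

    Padding positions are excluded from the batch statistics so that the
    amount of right-padding cannot perturb training.  Inference uses
    exponential running statistics.
    """

    def __init__(self, channels: int, momentum: float = 0.1,
                 eps: float = 1e-5):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.dgamma = np.zeros(channels)
        self.dbeta = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, mask: np.ndarray,
                train: bool) -> np.ndarray:
        # x: (B, C, L); mask: (B, L)
        m = mask[:, None, :]
        if train:
            n = max(mask.sum(), 1)
            mean = (x * m).sum(axis=(0, 2)) / n
            var = (((x - mean[None, :, None]) * m) ** 2).sum(axis=(0, 2)) / n
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            )
            self._n = n
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv_std[None, :, None]
        self._cache = (xhat, inv_std, m, train)
        return self.gamma[None, :, None] * xhat + self.beta[None, :, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std, m, train = self._cache
        self.dgamma += (dout * xhat * m).sum(axis=(0, 2))
        self.dbeta += (dout * m).sum(axis=(0, 2))
        dxhat = dout * self.gamma[None, :, None]
        if not train:
            return dxhat * inv_std[None, :, None]
        n = self._n
        # standard batch-norm backward restricted to valid positions
        sum_dxhat = (dxhat * m).sum(axis=(0, 2))[None, :, None]
        sum_dxhat_xhat = (dxhat * xhat * m).sum(axis=(0, 2))[None, :, None]
        dx = (
            inv_std[None, :, None]
            * (dxhat - sum_dxhat / n - xhat * sum_dxhat_xhat / n)
            * m
        )
        return dx

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def zero_grad(self):
        self.dgamma[...] = 0.0
        self.dbeta[...] = 0.0


class LeakyReLU:
    def __init__(self, slope: float = 0.01):
        self.slope = slope

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._neg = x < 0
        out = x.copy()
        out[self._neg] *= self.slope
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout.copy()
        dx[self._neg] *= self.slope
        return dx


class AvgPool1D:
    """Non-overlapping average pooling along the sequence axis."""

    def __init__(self, window: int = 2, stride: int | None = None):
        self.window = window
        self.stride = stride if stride is not None else window
        if self.stride != self.window:
            raise NotImplementedError("only stride == window supported")

    def out_length(self, length: int) -> int:
        return length // self.window

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, L = x.shape
        L_out = L // self.window
        self._in_L = L
        trimmed = x[:, :, : L_out * self.window]
        return trimmed.reshape(B, C, L_out, self.window).mean(axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, C, L_out = dout.shape
        dx = np.zeros((B, C, self._in_L))
        expanded = np.repeat(dout / self.window, self.window, axis=2)
        dx[:, :, : L_out * self.window] = expanded
        return dx


def masked_global_max(x: np.ndarray, lengths: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Global max over valid positions; returns (values (B,C), argmax (B,C)).

    Every sample must have at least one valid position.
    """
    if (np.asarray(lengths) < 1).any():
        raise ValueError("a sequence has no valid positions left to pool")
    mask = length_mask(lengths, x.shape[2])
    masked = np.where(mask[:, None, :], x, -np.inf)
    arg = masked.argmax(axis=2)
    vals = np.take_along_axis(masked, arg[:, :, None], axis=2)[:, :, 0]
    return vals, arg


def masked_global_max_backward(dout: np.ndarray, arg: np.ndarray,
                               in_shape: tuple) -> np.ndarray:
    dx = np.zeros(in_shape)
    B, C = dout.shape
    bi = np.repeat(np.arange(B), C)
    ci = np.tile(np.arange(C), B)
    np.add.at(dx, (bi, ci, arg.ravel()), dout.ravel())
    return dx


class Affine:
    """Fully connected layer y = x W + b."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / in_dim)
        self.W = rng.normal(0.0, scale, size=(in_dim, out_dim))
        self.b = np.zeros(out_dim)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW += self._x.T @ dout
        self.db += dout.sum(axis=0)
        return dout @ self.W.T

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def zero_grad(self):
        self.dW[...] = 0.0
        self.db[...] = 0.0


class Dropout:
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


class Adam:
    """Adam optimizer over (param, grad) pairs, updating params in place."""

    def __init__(self, param_items, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.items = list(param_items)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.items]
        self.v = [np.zeros_like(p) for p, _ in self.items]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(self.items):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
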