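"""Layers with forward/backward passes over float64 NumPy arrays.

Conventions: activations are (N, C, H, W) for image layers and (N, D) for
dense layers.  Each layer exposes ``params`` and ``grads`` dicts keyed by
parameter name; non-trainable state (batch-norm running statistics) lives in
``buffers``.  ``forward(x, train)`` caches whatever ``backward(dout)`` needs.
"""

from __future__ import annotations

import math

import numpy as np


class Layer:
    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _pair(v) -> tuple[int, int]:
    if isinstance(v, (tuple, list)):
        return int(v[0]), int(v[1])
    return int(v), int(v)


class Conv2d(Layer):
    """2D convolution via im2col.

    ``padding='same'`` uses ceiling output semantics: out = ceil(in / stride),
    with the total padding split low/high (extra on the high side), so six
    stride-2 layers take 208 -> 104 -> 52 -> 26 -> 13 -> 7 -> 4.
    ``padding='valid'`` slides the kernel only over fully covered positions.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size,
        stride: int = 1,
        padding: str = "same",
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kh, self.kw = _pair(kernel_size)
        self.stride = int(stride)
        if padding not in ("same", "valid"):
            raise ValueError(f"padding must be 'same' or 'valid', got {padding!r}")
        self.padding = padding
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * self.kh * self.kw
        self.params["w"] = rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(fan_in, out_channels))
        if bias:
            self.params["b"] = np.zeros(out_channels)
        self._cache = None

    def _geometry(self, h: int, w: int) -> tuple[int, int, tuple[int, int], tuple[int, int]]:
        s = self.stride
        if self.padding == "same":
            oh = -(-h // s)
            ow = -(-w // s)
            ph = max((oh - 1) * s + self.kh - h, 0)
            pw = max((ow - 1) * s + self.kw - w, 0)
            return oh, ow, (ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2)
        oh = (h - self.kh) // s + 1
        ow = (w - self.kw) // s + 1
        return oh, ow, (0, 0), (0, 0)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {c}")
        oh, ow, ph, pw = self._geometry(h, w)
        xp = np.pad(x, ((0, 0), (0, 0), ph, pw)) if (ph != (0, 0) or pw != (0, 0)) else x
        s = self.stride
        win = np.lib.stride_tricks.sliding_window_view(xp, (self.kh, self.kw), axis=(2, 3))
        win = win[:, :, ::s, ::s][:, :, :oh, :ow]  # (N, C, OH, OW, kh, kw)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, -1)
        out = cols @ self.params["w"]
        if "b" in self.params:
            out = out + self.params["b"]
        self._cache = (cols, (n, c, h, w), (oh, ow), ph, pw, xp.shape)
        return out.reshape(n, oh, ow, self.out_channels).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, (n, c, h, w), (oh, ow), ph, pw, xp_shape = self._cache
        dmat = dout.transpose(0, 2, 3, 1).reshape(n * oh * ow, self.out_channels)
        self.grads["w"] = cols.T @ dmat
        if "b" in self.params:
            self.grads["b"] = dmat.sum(axis=0)
        dcols = (dmat @ self.params["w"].T).reshape(n, oh, ow, c, self.kh, self.kw)
        dcols = dcols.transpose(0, 3, 1, 2, 4, 5)  # (N, C, OH, OW, kh, kw)
        dxp = np.zeros(xp_shape)
        s = self.stride
        for ki in range(self.kh):
            for kj in range(self.kw):
                dxp[:, :, ki : ki + s * oh : s, kj : kj + s * ow : s] += dcols[:, :, :, :, ki, kj]
        return dxp[:, :, ph[0] : ph[0] + h, pw[0] : pw[0] + w]


class BatchNorm2d(Layer):
    """Per-channel batch normalization with affine scale/shift.

    Training uses biased batch statistics over (N, H, W) and maintains
    exponential running averages (momentum 0.1) used at evaluation time.
    Running statistics are buffers, not trainable parameters.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1) -> None:
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        self.buffers["running_mean"] = np.zeros(channels)
        self.buffers["running_var"] = np.ones(channels)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.buffers["running_mean"] = (1 - m) * self.buffers["running_mean"] + m * mean
            self.buffers["running_var"] = (1 - m) * self.buffers["running_var"] + m * var
        else:
            mean = self.buffers["running_mean"]
            var = self.buffers["running_var"]
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * ivar[:, None, None]
        self._cache = (xhat, ivar, train, x.shape)
        return self.params["gamma"][:, None, None] * xhat + self.params["beta"][:, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, ivar, train, shape = self._cache
        axes = (0, 2, 3)
        self.grads["gamma"] = (dout * xhat).sum(axis=axes)
        self.grads["beta"] = dout.sum(axis=axes)
        g = self.params["gamma"][:, None, None]
        dxhat = dout * g
        if not train:
            return dxhat * ivar[:, None, None]
        nn = shape[0] * shape[2] * shape[3]
        t1 = dxhat.sum(axis=axes, keepdims=True)
        t2 = (dxhat * xhat).sum(axis=axes, keepdims=True)
        return (ivar[:, None, None] / nn) * (nn * dxhat - t1 - xhat * t2)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout: active only in training, identity at evaluation."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params["w"] = rng.normal(0.0, math.sqrt(2.0 / in_features), size=(in_features, out_features))
        self.params["b"] = np.zeros(out_features)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["w"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["w"].T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        super().__init__()
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def named_params(self, prefix: str = ""):
        for i, layer in enumerate(self.layers):
            if isinstance(layer, Sequential):
                yield from layer.named_params(f"{prefix}{i}.")
            else:
                for name in layer.params:
                    yield f"{prefix}{i}.{name}", layer, name

    def named_buffers(self, prefix: str = ""):
        for i, layer in enumerate(self.layers):
            if isinstance(layer, Sequential):
                yield from layer.named_buffers(f"{prefix}{i}.")
            else:
                for name in layer.buffers:
                    yield f"{prefix}{i}.{name}", layer, name


class Concat:
    """Concatenate per-stack feature vectors along the feature axis."""

    def forward(self, xs: list[np.ndarray]) -> np.ndarray:
        self._widths = [x.shape[1] for x in xs]
        return np.concatenate(xs, axis=1)

    def backward(self, dout: np.ndarray) -> list[np.ndarray]:
        splits = np.cumsum(self._widths)[:-1]
        return np.split(dout, splits, axis=1)
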