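"""Minimal CPU neural-network engine.

Layers store their parameter *shapes* at construction time and allocate
weights lazily, so exact parameter audits of large graphs never touch
memory. Data layout is NCHW float32 throughout. Every layer implements
``forward``/``backward`` explicitly; the only optimizer is Adam.

Conventions shared with the architecture audit:

* convolutions carry bias terms by default;
* batch normalization holds four per-channel parameters — gamma and beta
  (trainable) plus moving mean and variance (never trainable, but counted
  in full parameter totals).
"""

from __future__ import annotations

import math
from typing import Iterable, Iterator

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv2D",
    "BatchNorm2D",
    "ReLU",
    "MaxPool2D",
    "GlobalAvgPool",
    "Flatten",
    "Dense",
    "Sequential",
    "Residual",
    "Concat",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
]

_EPS_BN = 1e-5


# ---------------------------------------------------------------------------
# layer base
# ---------------------------------------------------------------------------

class Layer:
    """Base class: a named node with a block tag and a trainable flag.

    ``block`` groups layers into the coarse architectural units used by the
    freeze configurations (stem/stage names, "inception", "head").
    """

    def __init__(self, name: str = "", block: str = ""):
        self.name = name
        self.block = block
        self.trainable = True
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    # -- parameter bookkeeping -------------------------------------------
    def param_specs(self) -> list[tuple[str, tuple[int, ...], bool]]:
        """(name, shape, is_gradient_trained) for each parameter tensor."""
        return []

    def initialize(self, rng: np.random.Generator) -> None:
        pass

    @property
    def initialized(self) -> bool:
        return not self.param_specs() or bool(self.params)

    # -- graph traversal --------------------------------------------------
    def walk(self) -> Iterator["Layer"]:
        yield self

    # -- shape inference ---------------------------------------------------
    def out_shape(self, in_shape: tuple[int, ...]) -> tuple[int, ...]:
        """Output shape for a single example, channels-first (C, H, W)."""
        return in_shape

    # -- compute -----------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _conv_out(n: int, k: int, stride: int, pad: int) -> int:
    return (n + 2 * pad - k) // stride + 1


def _same_pad(k: int) -> int:
    # odd kernels only, matching the 1/3/5/7 kernels used here
    return (k - 1) // 2


# ---------------------------------------------------------------------------
# leaf layers
# ---------------------------------------------------------------------------

class Conv2D(Layer):
    """2-D convolution via im2col; padding is "same" or "valid"."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, padding: str = "same", bias: bool = True,
                 name: str = "", block: str = ""):
        super().__init__(name, block)
        self.cin, self.cout, self.k, self.stride = in_channels, out_channels, kernel, stride
        if padding not in ("same", "valid"):
            raise ValueError(f"unknown padding {padding!r}")
        self.pad = _same_pad(kernel) if padding == "same" else 0
        self.bias = bias
        self._cache: tuple | None = None

    def param_specs(self):
        specs = [("weight", (self.cout, self.cin, self.k, self.k), True)]
        if self.bias:
            specs.append(("bias", (self.cout,), True))
        return specs

    def initialize(self, rng):
        fan_in = self.cin * self.k * self.k
        scale = math.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.params = {"weight": (rng.standard_normal(
            (self.cout, self.cin, self.k, self.k)) * scale).astype(np.float32)}
        if self.bias:
            self.params["bias"] = np.zeros(self.cout, dtype=np.float32)

    def out_shape(self, in_shape):
        c, h, w = in_shape
        if c != self.cin:
            raise ValueError(f"{self.name}: expected {self.cin} channels, got {c}")
        return (self.cout,
                _conv_out(h, self.k, self.stride, self.pad),
                _conv_out(w, self.k, self.stride, self.pad))

    def _im2col(self, x: np.ndarray) -> tuple[np.ndarray, int, int]:
        n, c, h, w = x.shape
        if self.pad:
            x = np.pad(x, ((0, 0), (0, 0), (self.pad,) * 2, (self.pad,) * 2))
        win = sliding_window_view(x, (self.k, self.k), axis=(2, 3))
        win = win[:, :, ::self.stride, ::self.stride]  # N,C,Ho,Wo,k,k
        ho, wo = win.shape[2], win.shape[3]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * self.k * self.k)
        return np.ascontiguousarray(cols), ho, wo

    def forward(self, x, training=False):
        n = x.shape[0]
        cols, ho, wo = self._im2col(x)
        wmat = self.params["weight"].reshape(self.cout, -1)
        out = cols @ wmat.T
        if self.bias:
            out += self.params["bias"]
        if training:
            self._cache = (x.shape, cols)
        else:
            self._cache = None
        return out.reshape(n, ho, wo, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dy):
        x_shape, cols = self._cache
        n, c, h, w = x_shape
        ho, wo = dy.shape[2], dy.shape[3]
        dyf = dy.transpose(0, 2, 3, 1).reshape(-1, self.cout)
        if self.trainable:
            self.grads["weight"] = (dyf.T @ cols).reshape(self.params["weight"].shape)
            if self.bias:
                self.grads["bias"] = dyf.sum(axis=0)
        wmat = self.params["weight"].reshape(self.cout, -1)
        dcols = (dyf @ wmat).reshape(n, ho, wo, c, self.k, self.k)
        # col2im scatter-add over the k*k taps
        hp, wp = h + 2 * self.pad, w + 2 * self.pad
        dxp = np.zeros((n, c, hp, wp), dtype=dy.dtype)
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i:i + self.stride * ho:self.stride,
                    j:j + self.stride * wo:self.stride] += \
                    dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        if self.pad:
            dxp = dxp[:, :, self.pad:self.pad + h, self.pad:self.pad + w]
        return dxp


class BatchNorm2D(Layer):
    """Per-channel batch normalization with moving statistics.

    A frozen (non-trainable) batch-norm layer runs in inference mode even
    during training, so its moving statistics never drift — required for
    the bit-identical freeze contract.
    """

    def __init__(self, channels: int, momentum: float = 0.9,
                 name: str = "", block: str = ""):
        super().__init__(name, block)
        self.c = channels
        self.momentum = momentum
        self._cache = None

    def param_specs(self):
        return [("gamma", (self.c,), True), ("beta", (self.c,), True),
                ("moving_mean", (self.c,), False), ("moving_var", (self.c,), False)]

    def initialize(self, rng):
        self.params = {
            "gamma": np.ones(self.c, dtype=np.float32),
            "beta": np.zeros(self.c, dtype=np.float32),
            "moving_mean": np.zeros(self.c, dtype=np.float32),
            "moving_var": np.ones(self.c, dtype=np.float32),
        }

    def forward(self, x, training=False):
        g = self.params["gamma"][None, :, None, None]
        b = self.params["beta"][None, :, None, None]
        if training and self.trainable:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.params["moving_mean"] = (m * self.params["moving_mean"]
                                          + (1 - m) * mean).astype(np.float32)
            self.params["moving_var"] = (m * self.params["moving_var"]
                                         + (1 - m) * var).astype(np.float32)
            inv = 1.0 / np.sqrt(var + _EPS_BN)
            xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
            self._cache = (xhat, inv)
            return g * xhat + b
        inv = 1.0 / np.sqrt(self.params["moving_var"] + _EPS_BN)
        xhat = (x - self.params["moving_mean"][None, :, None, None]) \
            * inv[None, :, None, None]
        self._cache = (xhat, None)  # inference-mode backward treats stats as constants
        return g * xhat + b

    def backward(self, dy):
        xhat, inv = self._cache
        g = self.params["gamma"][None, :, None, None]
        if self.trainable:
            self.grads["gamma"] = (dy * xhat).sum(axis=(0, 2, 3))
            self.grads["beta"] = dy.sum(axis=(0, 2, 3))
        if inv is None:  # frozen/inference: affine transform with fixed stats
            fixed_inv = 1.0 / np.sqrt(self.params["moving_var"] + _EPS_BN)
            return dy * g * fixed_inv[None, :, None, None]
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        dxhat = dy * g
        dx = (dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True)
              - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True))
        return dx * inv[None, :, None, None]


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool2D(Layer):
    def __init__(self, kernel: int, stride: int, padding: str = "valid",
                 name: str = "", block: str = ""):
        super().__init__(name, block)
        self.k, self.stride = kernel, stride
        self.pad = _same_pad(kernel) if padding == "same" else 0

    def out_shape(self, in_shape):
        c, h, w = in_shape
        return (c, _conv_out(h, self.k, self.stride, self.pad),
                _conv_out(w, self.k, self.stride, self.pad))

    def forward(self, x, training=False):
        n, c, h, w = x.shape
        if self.pad:
            x = np.pad(x, ((0, 0), (0, 0), (self.pad,) * 2, (self.pad,) * 2),
                       constant_values=-np.inf)
        win = sliding_window_view(x, (self.k, self.k), axis=(2, 3))
        win = win[:, :, ::self.stride, ::self.stride]
        ho, wo = win.shape[2], win.shape[3]
        flat = win.reshape(n, c, ho, wo, self.k * self.k)
        self._argmax = flat.argmax(axis=-1)
        self._in_shape = (n, c, h + 2 * self.pad, w + 2 * self.pad)
        return flat.max(axis=-1)

    def backward(self, dy):
        n, c, hp, wp = self._in_shape
        ho, wo = dy.shape[2], dy.shape[3]
        dxp = np.zeros((n, c, hp, wp), dtype=dy.dtype)
        ii = self._argmax // self.k
        jj = self._argmax % self.k
        base_i = np.arange(ho)[None, None, :, None] * self.stride
        base_j = np.arange(wo)[None, None, None, :] * self.stride
        ni = np.arange(n)[:, None, None, None]
        ci = np.arange(c)[None, :, None, None]
        np.add.at(dxp, (np.broadcast_to(ni, dy.shape),
                        np.broadcast_to(ci, dy.shape),
                        base_i + ii, base_j + jj), dy)
        if self.pad:
            dxp = dxp[:, :, self.pad:hp - self.pad, self.pad:wp - self.pad]
        return dxp


class GlobalAvgPool(Layer):
    def out_shape(self, in_shape):
        return (in_shape[0],)

    def forward(self, x, training=False):
        self._in_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._in_shape
        return np.broadcast_to(dy[:, :, None, None], self._in_shape) / (h * w)


class Flatten(Layer):
    def out_shape(self, in_shape):
        return (int(np.prod(in_shape)),)

    def forward(self, x, training=False):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._in_shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 name: str = "", block: str = ""):
        super().__init__(name, block)
        self.fin, self.fout, self.bias = in_features, out_features, bias

    def param_specs(self):
        specs = [("weight", (self.fout, self.fin), True)]
        if self.bias:
            specs.append(("bias", (self.fout,), True))
        return specs

    def initialize(self, rng):
        scale = math.sqrt(2.0 / self.fin)
        self.params = {"weight": (rng.standard_normal(
            (self.fout, self.fin)) * scale).astype(np.float32)}
        if self.bias:
            self.params["bias"] = np.zeros(self.fout, dtype=np.float32)

    def out_shape(self, in_shape):
        return (self.fout,)

    def forward(self, x, training=False):
        self._x = x if training else None
        y = x @ self.params["weight"].T
        if self.bias:
            y = y + self.params["bias"]
        return y

    def backward(self, dy):
        if self.trainable:
            self.grads["weight"] = dy.T @ self._x
            if self.bias:
                self.grads["bias"] = dy.sum(axis=0)
        return dy @ self.params["weight"]


# ---------------------------------------------------------------------------
# composite layers
# ---------------------------------------------------------------------------

class Sequential(Layer):
    def __init__(self, layers: Iterable[Layer], name: str = "", block: str = ""):
        super().__init__(name, block)
        self.layers = list(layers)

    def walk(self):
        for layer in self.layers:
            yield from layer.walk()

    def out_shape(self, in_shape):
        for layer in self.layers:
            in_shape = layer.out_shape(in_shape)
        return in_shape

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class Residual(Layer):
    """y = relu(main(x) + shortcut(x)); identity shortcut when None."""

    def __init__(self, main: Layer, shortcut: Layer | None = None,
                 name: str = "", block: str = ""):
        super().__init__(name, block)
        self.main, self.shortcut = main, shortcut

    def walk(self):
        yield from self.main.walk()
        if self.shortcut is not None:
            yield from self.shortcut.walk()

    def out_shape(self, in_shape):
        main_shape = self.main.out_shape(in_shape)
        sc_shape = (self.shortcut.out_shape(in_shape)
                    if self.shortcut is not None else in_shape)
        if main_shape != sc_shape:
            raise ValueError(f"{self.name}: branch shapes differ "
                             f"{main_shape} vs {sc_shape}")
        return main_shape

    def forward(self, x, training=False):
        y = self.main.forward(x, training)
        s = self.shortcut.forward(x, training) if self.shortcut is not None else x
        z = y + s
        self._mask = z > 0
        return z * self._mask

    def backward(self, dy):
        dz = dy * self._mask
        dx = self.main.backward(dz)
        if self.shortcut is not None:
            dx = dx + self.shortcut.backward(dz)
        else:
            dx = dx + dz
        return dx


class Concat(Layer):
    """Parallel branches over a shared input, channel-concatenated."""

    def __init__(self, branches: Iterable[Layer], name: str = "", block: str = ""):
        super().__init__(name, block)
        self.branches = list(branches)

    def walk(self):
        for br in self.branches:
            yield from br.walk()

    def out_shape(self, in_shape):
        shapes = [br.out_shape(in_shape) for br in self.branches]
        spatial = {s[1:] for s in shapes}
        if len(spatial) != 1:
            raise ValueError(f"{self.name}: branch spatial sizes differ: {shapes}")
        return (sum(s[0] for s in shapes),) + shapes[0][1:]

    def forward(self, x, training=False):
        outs = [br.forward(x, training) for br in self.branches]
        self._splits = np.cumsum([o.shape[1] for o in outs])[:-1]
        return np.concatenate(outs, axis=1)

    def backward(self, dy):
        parts = np.split(dy, self._splits, axis=1)
        dx = self.branches[0].backward(parts[0])
        for br, part in zip(self.branches[1:], parts[1:]):
            dx = dx + br.backward(part)
        return dx


# ---------------------------------------------------------------------------
# loss and optimizer
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray,
                          targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch; targets may be soft (mixup).

    Returns (loss, dlogits) with dlogits already divided by the batch size.
    """
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-(targets * np.log(p + 1e-12)).sum() / n)
    return loss, (p - targets) / n


class Adam:
    """Adam over the trainable parameters of a layer graph."""

    def __init__(self, root: Layer, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.root = root
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m: dict[tuple[int, str], np.ndarray] = {}
        self.v: dict[tuple[int, str], np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1 ** self.t
        bias2 = 1 - b2 ** self.t
        for layer in self.root.walk():
            if not layer.trainable or not layer.grads:
                continue
            for pname, grad in layer.grads.items():
                key = (id(layer), pname)
                m = self.m.get(key)
                if m is None:
                    m = np.zeros_like(grad)
                    self.m[key] = m
                    self.v[key] = np.zeros_like(grad)
                v = self.v[key]
                m *= b1
                m += (1 - b1) * grad
                v *= b2
                v += (1 - b2) * grad * grad
                layer.params[pname] -= (self.lr * (m / bias1)
                                        / (np.sqrt(v / bias2) + self.eps)
                                        ).astype(layer.params[pname].dtype)
            layer.grads = {}
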