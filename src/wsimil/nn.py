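"""Minimal neural-network layer kit with analytic gradients.

Layers operate on channels-last float arrays ``(N, H, W, C)`` (convolutional
stack) or ``(N, D)`` (dense stack).  Each layer caches what its backward pass
needs during :meth:`forward` and accumulates parameter gradients in
``self.grads`` during :meth:`backward`.  The kit is deliberately small: it
covers exactly the operations the patch scorer needs (strided valid/same
convolution, ReLU, 2x2 max pooling, global average pooling, dense layers) plus
a standard Adam optimizer and a numerically stable binary cross-entropy.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2d",
    "ReLU",
    "MaxPool2",
    "GlobalAvgPool",
    "Dense",
    "Flatten",
    "Sequential",
    "Adam",
    "sigmoid",
    "bce_with_logits",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(z, dtype=np.result_type(z, np.float32))
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray):
    """Mean binary cross-entropy from logits.

    Returns ``(loss, dlogits)`` where ``dlogits`` is the gradient of the mean
    loss with respect to the logits.  Uses the softplus identity
    ``BCE = max(z,0) - z*y + log(1+exp(-|z|))`` to avoid overflow.
    """
    logits = np.asarray(logits, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.float64)
    loss = np.maximum(logits, 0.0) - logits * targets + np.log1p(np.exp(-np.abs(logits)))
    dlogits = (sigmoid(logits) - targets) / logits.size
    return float(loss.mean()), dlogits


class Layer:
    """Base class; parameter-free layers leave ``params``/``grads`` empty."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def zero_grad(self) -> None:
        for g in self.grads.values():
            g[...] = 0.0


class Conv2d(Layer):
    """2-D convolution (cross-correlation), channels-last, He-initialized.

    ``padding="same"`` is supported for stride 1 only; ``"valid"`` supports any
    stride.  The forward/backward passes loop over the ``k*k`` kernel offsets
    and express each offset as a single matmul, which is fast in numpy for the
    small kernels used here.
    """

    def __init__(self, c_in: int, c_out: int, ksize: int = 3, stride: int = 1,
                 padding: str = "valid", rng: np.random.Generator | None = None,
                 dtype=np.float32):
        super().__init__()
        if padding not in ("valid", "same"):
            raise ValueError(f"unknown padding {padding!r}")
        if padding == "same" and stride != 1:
            raise ValueError("padding='same' requires stride 1")
        rng = rng or np.random.default_rng()
        fan_in = c_in * ksize * ksize
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(ksize, ksize, c_in, c_out))
        self.params = {"W": w.astype(dtype), "b": np.zeros(c_out, dtype=dtype)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.ksize, self.stride, self.padding = ksize, stride, padding
        self._cache = None

    def forward(self, x, train=True):
        k, s = self.ksize, self.stride
        if self.padding == "same":
            p0 = (k - 1) // 2
            p1 = k - 1 - p0
            x = np.pad(x, ((0, 0), (p0, p1), (p0, p1), (0, 0)))
        n, h, w_, _ = x.shape
        oh = (h - k) // s + 1
        ow = (w_ - k) // s + 1
        if oh < 1 or ow < 1:
            raise ValueError(f"input spatial size {h}x{w_} too small for kernel {k}")
        W = self.params["W"]
        out = np.broadcast_to(self.params["b"], (n, oh, ow, W.shape[-1])).copy()
        for i in range(k):
            for j in range(k):
                xs = x[:, i:i + s * oh:s, j:j + s * ow:s, :]
                out += xs @ W[i, j]
        self._cache = (x, oh, ow)
        return out

    def backward(self, dout):
        x, oh, ow = self._cache
        k, s = self.ksize, self.stride
        W = self.params["W"]
        dx = np.zeros_like(x)
        self.grads["b"] += dout.sum(axis=(0, 1, 2))
        dflat = dout.reshape(-1, dout.shape[-1])
        for i in range(k):
            for j in range(k):
                xs = x[:, i:i + s * oh:s, j:j + s * ow:s, :]
                self.grads["W"][i, j] += xs.reshape(-1, xs.shape[-1]).T @ dflat
                dx[:, i:i + s * oh:s, j:j + s * ow:s, :] += dout @ W[i, j].T
        if self.padding == "same":
            p0 = (k - 1) // 2
            p1 = k - 1 - p0
            h = x.shape[1] - p0 - p1
            w2 = x.shape[2] - p0 - p1
            dx = dx[:, p0:p0 + h, p0:p0 + w2, :]
        return dx


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout):
        return np.where(self._mask, dout, 0.0)


class MaxPool2(Layer):
    """2x2 max pooling with stride 2; odd trailing rows/columns are dropped."""

    def forward(self, x, train=True):
        n, h, w, c = x.shape
        oh, ow = h // 2, w // 2
        xc = x[:, :2 * oh, :2 * ow, :]
        win = xc.reshape(n, oh, 2, ow, 2, c).transpose(0, 1, 3, 5, 2, 4).reshape(n, oh, ow, c, 4)
        idx = win.argmax(axis=-1)
        out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
        self._cache = (x.shape, idx)
        return out

    def backward(self, dout):
        (n, h, w, c), idx = self._cache
        oh, ow = h // 2, w // 2
        dwin = np.zeros((n, oh, ow, c, 4), dtype=dout.dtype)
        np.put_along_axis(dwin, idx[..., None], dout[..., None], axis=-1)
        dxc = dwin.reshape(n, oh, ow, c, 2, 2).transpose(0, 1, 4, 2, 5, 3).reshape(n, 2 * oh, 2 * ow, c)
        dx = np.zeros((n, h, w, c), dtype=dout.dtype)
        dx[:, :2 * oh, :2 * ow, :] = dxc
        return dx


class GlobalAvgPool(Layer):
    """Average over the spatial axes: (N, H, W, C) -> (N, C)."""

    def forward(self, x, train=True):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout):
        n, h, w, c = self._shape
        return np.broadcast_to(dout[:, None, None, :] / (h * w), self._shape).astype(dout.dtype)


class Flatten(Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        w = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out))
        self.params = {"W": w.astype(dtype), "b": np.zeros(d_out, dtype=dtype)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, train=True):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] += self._x.T @ dout
        self.grads["b"] += dout.sum(axis=0)
        return dout @ self.params["W"].T


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def zero_grad(self):
        for layer in self.layers:
            layer.zero_grad()

    def param_items(self):
        """Yield (array, grad) pairs over all layers, in a stable order."""
        for layer in self.layers:
            for name in layer.params:
                yield layer.params[name], layer.grads[name]

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for li, layer in enumerate(self.layers):
            for name, value in layer.params.items():
                state[f"{li}.{name}"] = value.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for li, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name][...] = state[f"{li}.{name}"]


class Adam:
    """Adam over a list of parameter arrays updated in place."""

    def __init__(self, param_grad_pairs, lr: float = 2e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.pairs = list(param_grad_pairs)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.pairs]
        self.v = [np.zeros_like(p) for p, _ in self.pairs]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(self.pairs):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * (g * g)
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
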