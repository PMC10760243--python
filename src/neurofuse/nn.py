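"""Minimal NumPy neural-network engine for volumetric classifiers.

Implements exactly the pieces the 3D classifier needs — 3D convolution
(im2col), batch normalization, ReLU, max pooling, adaptive average
pooling, linear layers, inverted dropout, softmax cross-entropy and Adam —
with hand-written backward passes.  Keeping the backward pass explicit is
what lets guided backpropagation be expressed as a one-line variant of the
ReLU backward rule instead of a framework hook.

Conventions: activations are float64 arrays shaped (N, C, D, H, W);
``forward(x, train=...)`` caches whatever ``backward(dout)`` needs;
parameter gradients accumulate in ``layer.grads``.
"""

from __future__ import annotations

import itertools
from typing import Iterator, Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv3d",
    "BatchNorm3d",
    "ReLU",
    "MaxPool3d",
    "AdaptiveAvgPool3d",
    "Flatten",
    "Linear",
    "Dropout",
    "Sequential",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
]


class Layer:
    """Base class: parameters, gradients, forward/backward."""

    name: str = ""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False,
                rng: Optional[np.random.Generator] = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray, guided: bool = False) -> np.ndarray:
        raise NotImplementedError

    def state(self) -> dict[str, np.ndarray]:
        """Everything needed to restore the layer (params + buffers)."""
        return {k: v.copy() for k, v in self.params.items()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.params[k] = v.copy()

    def zero_grad(self) -> None:
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def n_parameters(self) -> int:
        return sum(int(v.size) for v in self.params.values())


def _out_size(d: int, k: int, s: int, p: int) -> int:
    return (d + 2 * p - k) // s + 1


class Conv3d(Layer):
    """3D convolution (cross-correlation) via im2col + matmul."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, rng: Optional[np.random.Generator] = None,
                 name: str = "conv") -> None:
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.k, self.s, self.p = kernel, stride, padding
        self.name = name
        rng = rng or np.random.default_rng()
        fan_in = in_ch * kernel ** 3
        # He-normal: appropriate for the ReLU nonlinearity that follows
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, fan_in))
        self.params = {"w": w, "b": np.zeros(out_ch)}
        self.zero_grad()

    def forward(self, x, train=False, rng=None):
        n, c, d, h, w = x.shape
        if c != self.in_ch:
            raise ValueError(f"{self.name}: expected {self.in_ch} channels, got {c}")
        k, s, p = self.k, self.s, self.p
        if min(d, h, w) + 2 * p < k:
            raise ValueError(
                f"{self.name}: spatial dims {(d, h, w)} too small for kernel {k} "
                f"with padding {p}"
            )
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))[:, :, ::s, ::s, ::s]
        do_, ho_, wo_ = win.shape[2:5]
        cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(n, do_ * ho_ * wo_, c * k ** 3)
        out = cols @ self.params["w"].T + self.params["b"]
        self._cache = (cols, (n, c, d, h, w), (do_, ho_, wo_))
        return out.reshape(n, do_, ho_, wo_, self.out_ch).transpose(0, 4, 1, 2, 3)

    def backward(self, dout, guided=False):
        cols, (n, c, d, h, w), (do_, ho_, wo_) = self._cache
        k, s, p = self.k, self.s, self.p
        dof = dout.transpose(0, 2, 3, 4, 1).reshape(n, -1, self.out_ch)
        self.grads["w"] += np.tensordot(dof, cols, axes=([0, 1], [0, 1]))
        self.grads["b"] += dof.sum(axis=(0, 1))
        dcols = dof @ self.params["w"]
        dwin = dcols.reshape(n, do_, ho_, wo_, c, k, k, k).transpose(0, 4, 1, 2, 3, 5, 6, 7)
        dxp = np.zeros((n, c, d + 2 * p, h + 2 * p, w + 2 * p))
        for i, j, l in itertools.product(range(k), repeat=3):
            dxp[:, :, i:i + s * do_:s, j:j + s * ho_:s, l:l + s * wo_:s] += dwin[..., i, j, l]
        return dxp[:, :, p:p + d, p:p + h, p:p + w]


class BatchNorm3d(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1,
                 name: str = "bn") -> None:
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.name = name
        self.params = {"gamma": np.ones(num_features), "beta": np.zeros(num_features)}
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self.zero_grad()

    def forward(self, x, train=False, rng=None):
        axes = (0, 2, 3, 4)
        shape = (1, -1, 1, 1, 1)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean
            self.running_var = (1 - m) * self.running_var + m * var
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * invstd.reshape(shape)
        self._cache = (xhat, invstd, train, x.shape)
        return self.params["gamma"].reshape(shape) * xhat + self.params["beta"].reshape(shape)

    def backward(self, dout, guided=False):
        xhat, invstd, train, xshape = self._cache
        axes = (0, 2, 3, 4)
        shape = (1, -1, 1, 1, 1)
        self.grads["gamma"] += (dout * xhat).sum(axis=axes)
        self.grads["beta"] += dout.sum(axis=axes)
        g = self.params["gamma"].reshape(shape)
        if not train:
            return dout * g * invstd.reshape(shape)
        m = xshape[0] * xshape[2] * xshape[3] * xshape[4]
        dxhat = dout * g
        return (invstd.reshape(shape) / m) * (
            m * dxhat
            - dxhat.sum(axis=axes).reshape(shape)
            - xhat * (dxhat * xhat).sum(axis=axes).reshape(shape)
        )

    def state(self):
        s = super().state()
        s["running_mean"] = self.running_mean.copy()
        s["running_var"] = self.running_var.copy()
        return s

    def load_state(self, state):
        self.running_mean = state["running_mean"].copy()
        self.running_var = state["running_var"].copy()
        super().load_state({k: v for k, v in state.items() if k in self.params})


class ReLU(Layer):
    """Rectified linear unit; the guided backward rule lives here.

    Plain backprop zeroes the backward signal where the forward activation
    was <= 0; guided backprop additionally zeroes it where the incoming
    backward signal is negative.
    """

    def __init__(self, name: str = "relu") -> None:
        super().__init__()
        self.name = name

    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout, guided=False):
        dx = dout * self._mask
        if guided:
            dx = dx * (dout > 0)
        return dx


class MaxPool3d(Layer):
    def __init__(self, kernel: int = 3, stride: int = 2, name: str = "pool") -> None:
        super().__init__()
        self.k, self.s = kernel, stride
        self.name = name

    def forward(self, x, train=False, rng=None):
        n, c, d, h, w = x.shape
        k, s = self.k, self.s
        if min(d, h, w) < k:
            raise ValueError(
                f"{self.name}: spatial dims {(d, h, w)} too small for pooling kernel {k}"
            )
        win = sliding_window_view(x, (k, k, k), axis=(2, 3, 4))[:, :, ::s, ::s, ::s]
        do_, ho_, wo_ = win.shape[2:5]
        flat = win.reshape(n, c, do_, ho_, wo_, k ** 3)
        arg = flat.argmax(axis=-1)
        self._cache = (arg, x.shape, (do_, ho_, wo_))
        return np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def backward(self, dout, guided=False):
        arg, xshape, (do_, ho_, wo_) = self._cache
        n, c, d, h, w = xshape
        k, s = self.k, self.s
        dwin = np.zeros((n, c, do_, ho_, wo_, k ** 3))
        np.put_along_axis(dwin, arg[..., None], dout[..., None], axis=-1)
        dwin = dwin.reshape(n, c, do_, ho_, wo_, k, k, k)
        dx = np.zeros(xshape)
        for i, j, l in itertools.product(range(k), repeat=3):
            dx[:, :, i:i + s * do_:s, j:j + s * ho_:s, l:l + s * wo_:s] += dwin[..., i, j, l]
        return dx


class AdaptiveAvgPool3d(Layer):
    """Average pooling to a fixed output size, whatever the input grid.

    Bin edges follow the floor/ceil convention so bins tile the input.
    """

    def __init__(self, out_size: int = 1, name: str = "avgpool") -> None:
        super().__init__()
        self.o = out_size
        self.name = name

    @staticmethod
    def _edges(d: int, o: int) -> list[tuple[int, int]]:
        return [(int(np.floor(i * d / o)), int(np.ceil((i + 1) * d / o))) for i in range(o)]

    def forward(self, x, train=False, rng=None):
        n, c, d, h, w = x.shape
        o = self.o
        ed, eh, ew = self._edges(d, o), self._edges(h, o), self._edges(w, o)
        out = np.empty((n, c, o, o, o))
        for (i, (d0, d1)), (j, (h0, h1)), (l, (w0, w1)) in itertools.product(
            enumerate(ed), enumerate(eh), enumerate(ew)
        ):
            out[:, :, i, j, l] = x[:, :, d0:d1, h0:h1, w0:w1].mean(axis=(2, 3, 4))
        self._cache = (x.shape, ed, eh, ew)
        return out

    def backward(self, dout, guided=False):
        xshape, ed, eh, ew = self._cache
        dx = np.zeros(xshape)
        for (i, (d0, d1)), (j, (h0, h1)), (l, (w0, w1)) in itertools.product(
            enumerate(ed), enumerate(eh), enumerate(ew)
        ):
            size = (d1 - d0) * (h1 - h0) * (w1 - w0)
            dx[:, :, d0:d1, h0:h1, w0:w1] += dout[:, :, i, j, l][:, :, None, None, None] / size
        return dx


class Flatten(Layer):
    def __init__(self, name: str = "flatten") -> None:
        super().__init__()
        self.name = name

    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout, guided=False):
        return dout.reshape(self._shape)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: Optional[np.random.Generator] = None, name: str = "fc") -> None:
        super().__init__()
        self.name = name
        rng = rng or np.random.default_rng()
        bound = np.sqrt(2.0 / in_features)
        self.params = {
            "w": rng.normal(0.0, bound, size=(out_features, in_features)),
            "b": np.zeros(out_features),
        }
        self.zero_grad()

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.params["w"].T + self.params["b"]

    def backward(self, dout, guided=False):
        self.grads["w"] += dout.T @ self._x
        self.grads["b"] += dout.sum(axis=0)
        return dout @ self.params["w"]


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, rate: float = 0.5, name: str = "dropout") -> None:
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.name = name

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("train-mode dropout needs an rng for reproducibility")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout, guided=False):
        return dout if self._mask is None else dout * self._mask


class Sequential:
    """Plain layer chain with explicit forward/backward and state I/O."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False,
                rng: Optional[np.random.Generator] = None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, dout: np.ndarray, guided: bool = False) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout, guided=guided)
        return dout

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def parameters(self) -> Iterator[tuple[Layer, str]]:
        for layer in self.layers:
            for key in layer.params:
                yield layer, key

    def n_parameters(self) -> int:
        return sum(layer.n_parameters() for layer in self.layers)

    def state(self) -> list[dict[str, np.ndarray]]:
        return [layer.state() for layer in self.layers]

    def load_state(self, state: list[dict[str, np.ndarray]]) -> None:
        if len(state) != len(self.layers):
            raise ValueError("state does not match the layer stack")
        for layer, s in zip(self.layers, state):
            layer.load_state(s)


class Adam:
    """Adaptive-moment optimizer (the standard bias-corrected form)."""

    def __init__(self, net: Sequential, lr: float = 1e-3, betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8) -> None:
        self.net = net
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {(id(l), k): np.zeros_like(l.params[k]) for l, k in net.parameters()}
        self.v = {(id(l), k): np.zeros_like(l.params[k]) for l, k in net.parameters()}

    def step(self) -> None:
        self.t += 1
        for layer, key in self.net.parameters():
            g = layer.grads[key]
            slot = (id(layer), key)
            self.m[slot] = self.b1 * self.m[slot] + (1 - self.b1) * g
            self.v[slot] = self.b2 * self.v[slot] + (1 - self.b2) * g * g
            mhat = self.m[slot] / (1 - self.b1 ** self.t)
            vhat = self.v[slot] / (1 - self.b2 ** self.t)
            layer.params[key] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits)
    loss = -np.log(np.clip(p[np.arange(n), targets], 1e-12, None)).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), targets] -= 1.0
    return float(loss), dlogits / n
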