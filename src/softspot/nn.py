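"""Minimal CNN engine in NumPy.

Implements the handful of layer types a small VGG-style binary classifier
needs (3x3 convolution, ReLU, 2x2 max pooling, dense layers, softmax
cross-entropy) with explicit backward passes.  Gradients with respect to
any intermediate activation or to the input are first-class citizens here,
because the saliency methods downstream (Grad-CAM, guided backpropagation)
are defined directly in terms of them.

Conventions
-----------
* Image batches are ``(N, C, H, W)`` float32.
* ``Sequential.backward_from_logit`` propagates the gradient of one
  pre-softmax class logit backwards; with ``guided=True`` every ReLU
  applies the guided-backpropagation rule (gradient zeroed where the
  forward activation *or* the incoming gradient is negative).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2D",
    "ReLU",
    "MaxPool2",
    "Flatten",
    "Dense",
    "Sequential",
    "SGD",
    "softmax",
    "softmax_xent",
]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_xent(logits, onehot, sample_weight=None):
    """Weighted categorical cross-entropy; returns (mean loss, dlogits)."""
    p = softmax(logits)
    n = logits.shape[0]
    w = np.ones(n, dtype=logits.dtype) if sample_weight is None else sample_weight
    eps = 1e-12
    loss = float(-(w * np.log((p * onehot).sum(axis=1) + eps)).sum() / w.sum())
    dlogits = (p - onehot) * (w / w.sum())[:, None]
    return loss, dlogits


class Layer:
    """Base layer: caches what its backward pass needs during forward."""

    name: str = ""

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray, guided: bool = False) -> np.ndarray:
        raise NotImplementedError

    def params(self):
        return []


class Conv2D(Layer):
    """3x3 convolution, stride 1, zero padding 1 (spatial size preserved)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator, name: str = ""):
        self.name = name
        fan_in = in_ch * 9
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.w = (rng.standard_normal((out_ch, in_ch, 3, 3)) * scale).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def forward(self, x):
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        # (N, C, H, W, 3, 3) sliding view -> columns (N*H*W, C*9)
        win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * 9)
        self._cols = cols
        self._xshape = x.shape
        out = cols @ self.w.reshape(len(self.w), -1).T + self.b
        return np.ascontiguousarray(
            out.reshape(n, h, w, -1).transpose(0, 3, 1, 2), dtype=np.float32
        )

    def backward(self, dy, guided=False):
        n, o, h, w = dy.shape
        _, c, _, _ = self._xshape
        dy_cols = dy.transpose(0, 2, 3, 1).reshape(n * h * w, o)
        self.dw += (dy_cols.T @ self._cols).reshape(self.w.shape)
        self.db += dy_cols.sum(axis=0)
        dx_pad = np.zeros((n, c, h + 2, w + 2), dtype=np.float32)
        # accumulate each kernel tap: dx[+di,+dj] += dy conv w[:, :, di, dj]
        for di in range(3):
            for dj in range(3):
                contrib = np.tensordot(dy, self.w[:, :, di, dj], axes=([1], [0]))
                dx_pad[:, :, di : di + h, dj : dj + w] += contrib.transpose(0, 3, 1, 2)
        return dx_pad[:, :, 1 : 1 + h, 1 : 1 + w]


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dy, guided=False):
        g = dy * self._mask
        if guided:
            g = np.where(dy > 0, g, 0)
        return g


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; spatial dims must be even."""

    def forward(self, x):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2 needs even spatial dims, got {h}x{w}")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        self._x = x
        self._out = out
        return out

    def backward(self, dy, guided=False):
        n, c, h, w = self._x.shape
        up_out = np.repeat(np.repeat(self._out, 2, axis=2), 2, axis=3)
        mask = self._x == up_out
        up_dy = np.repeat(np.repeat(dy, 2, axis=2), 2, axis=3)
        return np.where(mask, up_dy, 0).astype(np.float32)


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(len(x), -1)

    def backward(self, dy, guided=False):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, name: str = ""):
        self.name = name
        scale = np.sqrt(2.0 / d_in)
        self.w = (rng.standard_normal((d_in, d_out)) * scale).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def forward(self, x):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy, guided=False):
        self.dw += self._x.T @ dy
        self.db += dy.sum(axis=0)
        return dy @ self.w.T


class Sequential:
    """Plain layer stack with named-activation access for saliency methods.

    ``input_offset`` is subtracted from inputs before the first layer so the
    net sees roughly zero-centred pixels; being constant it does not affect
    any input gradient.
    """

    def __init__(self, layers, input_offset: float = 0.0):
        self.layers = list(layers)
        self.input_offset = float(input_offset)

    def named_index(self, name: str) -> int:
        for i, lyr in enumerate(self.layers):
            if lyr.name == name:
                return i
        raise KeyError(f"no layer named {name!r}")

    def forward(self, x: np.ndarray, keep: bool = False) -> np.ndarray:
        a = np.asarray(x, dtype=np.float32) - self.input_offset
        acts = [a]
        for lyr in self.layers:
            a = lyr.forward(a)
            if keep:
                acts.append(a)
        if keep:
            self._acts = acts
        return a

    def activation(self, layer_name: str) -> np.ndarray:
        """Output of the named layer from the last ``forward(keep=True)``."""
        return self._acts[self.named_index(layer_name) + 1]

    def backward(self, dlogits: np.ndarray, stop_at: int | None = None, guided: bool = False):
        """Backpropagate ``dlogits``; return the gradient w.r.t. the output of
        layer ``stop_at`` (or w.r.t. the input when ``stop_at`` is None)."""
        g = dlogits
        for i in range(len(self.layers) - 1, -1, -1):
            if stop_at is not None and i == stop_at:
                return g
            g = self.layers[i].backward(g, guided=guided)
        return g

    def backward_from_logit(self, target_class: int, layer_name: str | None = None,
                            guided: bool = False) -> np.ndarray:
        logits = self._acts[-1]
        d = np.zeros_like(logits)
        d[:, target_class] = 1.0
        stop = None if layer_name is None else self.named_index(layer_name)
        return self.backward(d, stop_at=stop, guided=guided)

    def zero_grads(self):
        for lyr in self.layers:
            for _, g in lyr.params():
                g[...] = 0.0

    def param_arrays(self):
        out = []
        for lyr in self.layers:
            out.extend(lyr.params())
        return out

    @property
    def has_relu(self) -> bool:
        return any(isinstance(l, ReLU) for l in self.layers)


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, model: Sequential, lr: float = 0.001, momentum: float = 0.9):
        self.model = model
        self.lr = lr
        self.momentum = momentum
        self._vel = [np.zeros_like(w) for w, _ in model.param_arrays()]

    def step(self):
        for v, (w, g) in zip(self._vel, self.model.param_arrays()):
            v *= self.momentum
            v -= self.lr * g
            w += v
        self.model.zero_grads()
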