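"""Layer objects with explicit forward/backward passes.

Each layer caches what its backward pass needs during a training-mode
forward call; parameter gradients accumulate on the layer (``gW``/``gb``)
and are consumed by the optimizer.  Inference-mode forward calls cache
nothing so large slides can be processed tile by tile without memory
growth.
"""

from __future__ import annotations

import numpy as np

from slideprep.nn import ops

F32 = np.float32


class Layer:
    def params(self):
        return []

    def forward(self, x, train=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(Layer):
    """k x k convolution, stride s, explicit padding, He-initialized."""

    def __init__(self, cin, cout, k, stride=1, pad=0, rng=None, bias=True):
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.pad = ops.as_pad4(pad)
        fan_in = cin * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(cout, cin, k, k)).astype(F32)
        self.b = np.zeros(cout, dtype=F32) if bias else None
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b) if bias else None
        self._cache = None

    def params(self):
        out = [(self.W, self.gW)]
        if self.b is not None:
            out.append((self.b, self.gb))
        return out

    def forward(self, x, train=False):
        if train:
            y, cols = ops.conv_forward(x, self.W, self.b, self.stride,
                                       self.pad, return_cols=True)
            self._cache = (cols, x.shape)
            return y
        return ops.conv_forward(x, self.W, self.b, self.stride, self.pad)

    def backward(self, dy):
        cols, x_shape = self._cache
        co, ci, k, _ = self.W.shape
        self.gW += ops.conv_weight_grad(cols, dy).reshape(self.W.shape)
        if self.b is not None:
            self.gb += ops.bias_grad(dy)
        dx = ops.conv_input_grad(dy, self.W, self.stride, self.pad, x_shape)
        self._cache = None
        return dx


class ConvTranspose2d(Layer):
    """4x4 stride-2 deconvolution (pad 1) that exactly doubles H and W."""

    def __init__(self, cin, cout, k=4, stride=2, pad=1, rng=None, bias=True):
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.pad = ops.as_pad4(pad)
        self.k = k
        fan_in = cin * k * k // (stride * stride)
        # weight layout (Cin, Cout, k, k): the mirror conv's (Co, Ci, k, k)
        self.W = rng.normal(0.0, np.sqrt(2.0 / max(fan_in, 1)),
                            size=(cin, cout, k, k)).astype(F32)
        self.b = np.zeros(cout, dtype=F32) if bias else None
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b) if bias else None
        self._cache = None

    def params(self):
        out = [(self.W, self.gW)]
        if self.b is not None:
            out.append((self.b, self.gb))
        return out

    def forward(self, x, train=False):
        n, cin, h, w = x.shape
        cout = self.W.shape[1]
        y_shape = (n, cout, self.stride * h, self.stride * w)
        y = ops.conv_input_grad(x, self.W, self.stride, self.pad, y_shape)
        if self.b is not None:
            y += self.b[None, :, None, None]
        if train:
            self._cache = x
        return y

    def backward(self, dy):
        x = self._cache
        cols, _ = ops.im2col(dy, self.k, self.stride, self.pad)
        # dW[cin, cout, u, v] = sum_n x[n,cin,i,j] dy_pad[n,cout,s i+u, s j+v]
        self.gW += ops.conv_weight_grad(cols, x).reshape(self.W.shape)
        if self.b is not None:
            self.gb += ops.bias_grad(dy)
        co = self.W.shape[0]  # mirror conv output channels = cin
        k = self.k
        dcols_w = self.W.reshape(co, -1)
        dx = (cols @ dcols_w.T).reshape(dy.shape[0], x.shape[2], x.shape[3], co)
        dx = np.ascontiguousarray(dx.transpose(0, 3, 1, 2))
        self._cache = None
        return dx


class InstanceNorm(Layer):
    """Per-sample, per-channel normalization without learned affine."""

    def __init__(self, eps=1e-5):
        self.eps = eps
        self._cache = None

    def forward(self, x, train=False):
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        y = (x - mu) * inv
        if train:
            self._cache = (y, inv.astype(F32))
        return y.astype(F32, copy=False)

    def backward(self, dy):
        y, inv = self._cache
        m1 = dy.mean(axis=(2, 3), keepdims=True)
        m2 = (dy * y).mean(axis=(2, 3), keepdims=True)
        dx = inv * (dy - m1 - y * m2)
        self._cache = None
        return dx.astype(F32, copy=False)


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, train=False):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dy):
        dx = dy * self._mask
        self._mask = None
        return dx


class Dropout(Layer):
    """Inverted dropout; active only in training mode."""

    def __init__(self, rate=0.5, rng=None):
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(F32) / F32(keep)
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        dx = dy * self._mask
        self._mask = None
        return dx


class Sigmoid(Layer):
    def __init__(self):
        self._y = None

    def forward(self, x, train=False):
        y = 1.0 / (1.0 + np.exp(-x))
        if train:
            self._y = y
        return y

    def backward(self, dy):
        dx = dy * self._y * (1.0 - self._y)
        self._y = None
        return dx
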