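"""im2col/col2im convolution primitives (float32, NCHW).

Three generic operations cover both convolution and transposed
convolution together with all their gradients:

* ``conv_forward``      y[n,o] = sum_i W[o,i] * x[n,i]   (stride s, pad p)
* ``conv_input_grad``   the adjoint of conv_forward w.r.t. x
* ``conv_weight_grad``  the adjoint of conv_forward w.r.t. W

A transposed convolution *is* ``conv_input_grad`` of the mirror-image
convolution, so its forward/backward passes reuse the same three kernels.

Padding is a 4-tuple (top, bottom, left, right); 4x4 "same" stride-1
convolutions need the asymmetric (1, 2, 1, 2).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def as_pad4(pad) -> tuple:
    if isinstance(pad, tuple) and len(pad) == 4:
        return pad
    p = int(pad)
    return (p, p, p, p)


def im2col(x: np.ndarray, k: int, stride: int, pad4: tuple) -> tuple:
    """Unfold (N,C,H,W) into (N*Ho*Wo, C*k*k) patch rows."""
    pt, pb, pl, pr = pad4
    xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
    n, c, hp, wp = xp.shape
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    # (N, C, Ho, Wo, k, k) -> (N, Ho, Wo, C, k, k) -> rows
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))
    return cols.reshape(n * ho * wo, c * k * k), (ho, wo)


def col2im(cols: np.ndarray, x_shape: tuple, k: int, stride: int,
           pad4: tuple, out_hw: tuple) -> np.ndarray:
    """Adjoint of im2col: scatter-add patch rows back to (N,C,H,W)."""
    n, c, h, w = x_shape
    pt, pb, pl, pr = pad4
    ho, wo = out_hw
    xp = np.zeros((n, c, h + pt + pb, w + pl + pr), dtype=cols.dtype)
    cols6 = cols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 4, 5, 1, 2)
    for u in range(k):
        for v in range(k):
            xp[:, :, u:u + stride * ho:stride, v:v + stride * wo:stride] += cols6[:, :, u, v]
    return xp[:, :, pt:pt + h, pl:pl + w]


def conv_forward(x, W, b, stride, pad4, return_cols=False):
    """y = conv(x, W) + b.  W has shape (Co, Ci, k, k)."""
    co, ci, k, _ = W.shape
    n = x.shape[0]
    cols, (ho, wo) = im2col(x, k, stride, pad4)
    y = cols @ W.reshape(co, -1).T
    if b is not None:
        y += b
    y = y.reshape(n, ho, wo, co).transpose(0, 3, 1, 2)
    y = np.ascontiguousarray(y)
    return (y, cols) if return_cols else y


def conv_input_grad(dy, W, stride, pad4, x_shape):
    """Adjoint of conv_forward in x; also the forward of a deconvolution."""
    co, ci, k, _ = W.shape
    n, _, ho, wo = dy.shape
    dy_flat = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, co)
    dcols = dy_flat @ W.reshape(co, -1)
    return col2im(dcols, x_shape, k, stride, pad4, (ho, wo))


def conv_weight_grad(cols, dy):
    """dW given cached im2col rows of x and the output gradient."""
    co = dy.shape[1]
    dy_flat = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, co)
    return dy_flat.T @ cols  # (Co, Ci*k*k), caller reshapes


def bias_grad(dy):
    return dy.sum(axis=(0, 2, 3))
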