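"""Low-level 3D convolution primitives.

All tensors are channels-first ``(N, C, D, H, W)``.  The three functions
below form an adjoint triple for a strided "same"-padded convolution:

* :func:`conv3d_forward`          — y = W * x + b
* :func:`conv3d_backward_data`    — x-gradient (the exact adjoint of forward)
* :func:`conv3d_backward_weights` — W-gradient

Transposed convolution is expressed through the same triple (its forward
pass *is* ``conv3d_backward_data``), so the whole engine rests on three
vectorised routines built on ``sliding_window_view`` + matmul.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def same_padding(kernel: int, stride: int) -> tuple[int, int]:
    """Asymmetric 'same' padding so that output side = input side / stride.

    Requires the input side to be divisible by the stride; total padding is
    ``kernel - stride`` split low/high (TensorFlow convention: the extra
    voxel of an odd total goes on the high side).
    """
    total = kernel - stride
    if total < 0:
        raise ValueError(f"kernel {kernel} must be >= stride {stride}")
    lo = total // 2
    return lo, total - lo


def _pad(x: np.ndarray, lo: int, hi: int) -> np.ndarray:
    if lo == 0 and hi == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (lo, hi), (lo, hi), (lo, hi)))


def _im2col(xp: np.ndarray, kernel: int, stride: int) -> np.ndarray:
    """Padded input -> (N*Do*Ho*Wo, C*k^3) patch matrix."""
    win = sliding_window_view(xp, (kernel, kernel, kernel), axis=(2, 3, 4))
    win = win[:, :, ::stride, ::stride, ::stride]
    n, c, do, ho, wo = win.shape[:5]
    cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(n * do * ho * wo, c * kernel**3)
    return np.ascontiguousarray(cols)


def conv3d_forward(
    x: np.ndarray,
    weight: np.ndarray,
    bias: np.ndarray | None,
    stride: int,
) -> np.ndarray:
    """Strided same-padded 3D convolution.

    ``weight`` has shape ``(C_out, C_in, k, k, k)``.
    """
    c_out, c_in, k = weight.shape[0], weight.shape[1], weight.shape[2]
    if x.shape[1] != c_in:
        raise ValueError(f"expected {c_in} input channels, got {x.shape[1]}")
    lo, hi = same_padding(k, stride)
    xp = _pad(x, lo, hi)
    cols = _im2col(xp, k, stride)
    out = cols @ weight.reshape(c_out, -1).T
    if bias is not None:
        out += bias
    n = x.shape[0]
    do = x.shape[2] // stride
    return out.reshape(n, do, do, do, c_out).transpose(0, 4, 1, 2, 3)


def conv3d_backward_data(
    dout: np.ndarray,
    weight: np.ndarray,
    in_spatial: int,
    stride: int,
) -> np.ndarray:
    """Adjoint of :func:`conv3d_forward` with respect to the input."""
    k = weight.shape[2]
    lo, hi = same_padding(k, stride)
    n, _, do, ho, wo = dout.shape
    c_in = weight.shape[1]
    # (N, Do, Ho, Wo, C_in, k, k, k)
    dwin = np.tensordot(dout.transpose(0, 2, 3, 4, 1), weight, axes=([4], [0]))
    side = in_spatial + lo + hi
    dxp = np.zeros((n, c_in, side, side, side), dtype=dout.dtype)
    for a, b, c in product(range(k), repeat=3):
        dxp[:, :, a : a + stride * do : stride,
            b : b + stride * ho : stride,
            c : c + stride * wo : stride] += dwin[..., a, b, c].transpose(0, 4, 1, 2, 3)
    return dxp[:, :, lo : lo + in_spatial, lo : lo + in_spatial, lo : lo + in_spatial]


def conv3d_backward_weights(
    x: np.ndarray,
    dout: np.ndarray,
    kernel: int,
    stride: int,
) -> np.ndarray:
    """Weight gradient of :func:`conv3d_forward` for input ``x``."""
    lo, hi = same_padding(kernel, stride)
    xp = _pad(x, lo, hi)
    cols = _im2col(xp, kernel, stride)
    c_out = dout.shape[1]
    dout_mat = dout.transpose(0, 2, 3, 4, 1).reshape(-1, c_out)
    dw = dout_mat.T @ cols
    return dw.reshape(c_out, x.shape[1], kernel, kernel, kernel)
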