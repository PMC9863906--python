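"""Layer objects with explicit forward/backward passes.

Each layer caches what its backward pass needs on ``forward`` and
accumulates parameter gradients into ``Param.grad`` on ``backward``
(so two backward sweeps between optimiser steps sum their gradients,
which is exactly what the two-term discriminator loss requires).
"""

from __future__ import annotations

import numpy as np

from .functional import (
    conv3d_backward_data,
    conv3d_backward_weights,
    conv3d_forward,
)


class Param:
    """A trainable tensor and its accumulated gradient."""

    __slots__ = ("name", "data", "grad", "trainable")

    def __init__(self, name: str, data: np.ndarray, trainable: bool = True):
        self.name = name
        self.data = data
        self.grad = np.zeros_like(data)
        self.trainable = trainable

    @property
    def size(self) -> int:
        return self.data.size


class Layer:
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []


class Conv3d(Layer):
    """Same-padded strided 3D convolution, weight shape (C_out, C_in, k³)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 rng: np.random.Generator, init_std: float = 0.02,
                 dtype=np.float32):
        self.kernel, self.stride = kernel, stride
        w = rng.normal(0.0, init_std, size=(c_out, c_in, kernel, kernel, kernel))
        self.weight = Param("weight", w.astype(dtype))
        self.bias = Param("bias", np.zeros(c_out, dtype=dtype))
        self._x: np.ndarray | None = None

    def forward(self, x, training=False):
        self._x = x
        return conv3d_forward(x, self.weight.data, self.bias.data, self.stride)

    def backward(self, dout):
        x = self._x
        self.weight.grad += conv3d_backward_weights(x, dout, self.kernel, self.stride)
        self.bias.grad += dout.sum(axis=(0, 2, 3, 4))
        return conv3d_backward_data(dout, self.weight.data, x.shape[2], self.stride)

    def params(self):
        return [self.weight, self.bias]


class ConvTranspose3d(Layer):
    """Fractionally-strided 3D convolution (output side = stride × input side).

    Stored weight has shape (C_in, C_out, k³); the forward pass is the exact
    adjoint of the matching strided convolution, so backward reuses the plain
    convolution primitives.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 rng: np.random.Generator, init_std: float = 0.02,
                 dtype=np.float32):
        self.kernel, self.stride = kernel, stride
        w = rng.normal(0.0, init_std, size=(c_in, c_out, kernel, kernel, kernel))
        self.weight = Param("weight", w.astype(dtype))
        self.bias = Param("bias", np.zeros(c_out, dtype=dtype))
        self._x: np.ndarray | None = None

    def forward(self, x, training=False):
        self._x = x
        out_spatial = x.shape[2] * self.stride
        y = conv3d_backward_data(x, self.weight.data, out_spatial, self.stride)
        y += self.bias.data[None, :, None, None, None]
        return y

    def backward(self, dout):
        x = self._x
        # In the adjoint picture `dout` sits on the convolution's input side
        # and `x` on its output side.
        self.weight.grad += conv3d_backward_weights(dout, x, self.kernel, self.stride)
        self.bias.grad += dout.sum(axis=(0, 2, 3, 4))
        return conv3d_forward(dout, self.weight.data, None, self.stride)

    def params(self):
        return [self.weight, self.bias]


class InstanceNorm3d(Layer):
    """Per-sample, per-channel normalisation over the spatial axes."""

    def __init__(self, channels: int, eps: float = 1e-5, dtype=np.float32):
        self.eps = eps
        self.gamma = Param("gamma", np.ones(channels, dtype=dtype))
        self.beta = Param("beta", np.zeros(channels, dtype=dtype))
        self._cache = None

    def forward(self, x, training=False):
        sp = (2, 3, 4)
        mu = x.mean(axis=sp, keepdims=True)
        var = x.var(axis=sp, keepdims=True)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        self._cache = (xhat, inv_std)
        return self.gamma.data[None, :, None, None, None] * xhat + \
            self.beta.data[None, :, None, None, None]

    def backward(self, dout):
        xhat, inv_std = self._cache
        sp = (2, 3, 4)
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3, 4))
        self.beta.grad += dout.sum(axis=(0, 2, 3, 4))
        dxhat = dout * self.gamma.data[None, :, None, None, None]
        m1 = dxhat.mean(axis=sp, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=sp, keepdims=True)
        return inv_std * (dxhat - m1 - xhat * m2)

    def params(self):
        return [self.gamma, self.beta]


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope
        self._mask = None

    def forward(self, x, training=False):
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dout):
        return np.where(self._mask, dout, self.slope * dout)


class ReLU(LeakyReLU):
    def __init__(self):
        super().__init__(slope=0.0)


class Dropout(Layer):
    """Inverted dropout; identity when not training or p == 0."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng
        self._mask = None

    def forward(self, x, training=False):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class SoftmaxChannels(Layer):
    """Softmax over the channel axis; per-voxel class probabilities."""

    def forward(self, x, training=False):
        z = x - x.max(axis=1, keepdims=True)
        e = np.exp(z)
        self._y = e / e.sum(axis=1, keepdims=True)
        return self._y

    def backward(self, dout):
        y = self._y
        dot = (dout * y).sum(axis=1, keepdims=True)
        return y * (dout - dot)


class Sigmoid(Layer):
    def forward(self, x, training=False):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dout):
        return dout * self._y * (1.0 - self._y)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def params(self):
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0.0


class Residual(Layer):
    """y = x + body(x); the body must preserve shape (stride 1)."""

    def __init__(self, body: Sequential):
        self.body = body

    def forward(self, x, training=False):
        y = self.body.forward(x, training=training)
        if y.shape != x.shape:
            raise ValueError(
                f"residual body changed shape {x.shape} -> {y.shape}")
        return x + y

    def backward(self, dout):
        return dout + self.body.backward(dout)

    def params(self):
        return self.body.params()
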