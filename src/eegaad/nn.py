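"""Minimal NHWC neural-network layers with backprop and Adam, numpy only.

Just enough machinery for the generator/discriminator pair used here:
dense, conv / stride-1 transposed conv (TensorFlow-style 'same' padding),
batch norm, dropout, nearest upsampling and the usual activations. Layers
expose ``params()`` / ``grads()`` aligned lists; ``backward`` returns the
gradient with respect to the layer input.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "Dense", "Reshape", "Flatten", "Dropout", "BatchNorm",
    "ReLU", "LeakyReLU", "Tanh", "Sigmoid", "Softmax",
    "Conv2D", "ConvTranspose2D", "Upsample2x", "Sequential", "Adam",
]


class Layer:
    """Base class; stateless layers only implement forward/backward."""

    trainable: bool = True

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def param_count(self) -> int:
        """Total parameter count, Keras-style (batch-norm running stats
        included)."""
        return int(sum(p.size for p in self.params()))

    def set_rng(self, rng: np.random.Generator) -> None:
        self.rng = rng


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.W = _glorot(rng, (n_in, n_out), n_in, n_out)
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=True):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class Reshape(Layer):
    def __init__(self, shape: tuple[int, ...]):
        self.shape = shape

    def forward(self, x, train=True):
        self._in_shape = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, grad):
        return grad.reshape(self._in_shape)


class Flatten(Layer):
    def forward(self, x, train=True):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._in_shape)


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, p: float):
        if not 0 <= p < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self.rng = np.random.default_rng(0)

    def forward(self, x, train=True):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class BatchNorm(Layer):
    """Batch normalization over all axes but the last (features/channels).

    Parameter count is 4F — gamma, beta plus the (non-trainable) running
    mean and variance, matching how Keras reports it.
    """

    def __init__(self, n_features: int, momentum: float = 0.99, eps: float = 1e-3):
        self.gamma = np.ones(n_features)
        self.beta = np.zeros(n_features)
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)

    def forward(self, x, train=True):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._axes = axes
        self._m = x.size // x.shape[-1]
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._inv_std
        return self.gamma * self._xhat + self.beta

    def backward(self, grad):
        axes = self._axes
        self.dgamma[...] = (grad * self._xhat).sum(axis=axes)
        self.dbeta[...] = grad.sum(axis=axes)
        m = self._m
        gxhat = grad * self.gamma
        return (self._inv_std / m) * (
            m * gxhat
            - gxhat.sum(axis=axes)
            - self._xhat * (gxhat * self._xhat).sum(axis=axes)
        )

    def params(self):
        return [self.gamma, self.beta, self.running_mean, self.running_var]

    def grads(self):  # running stats are not optimized
        return [self.dgamma, self.dbeta, np.zeros_like(self.running_mean), np.zeros_like(self.running_var)]

    def trainable_params(self):
        return [self.gamma, self.beta]


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.2):
        self.alpha = alpha

    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, grad):
        return np.where(self._mask, grad, self.alpha * grad)


class Tanh(Layer):
    def forward(self, x, train=True):
        self._y = np.tanh(x)
        return self._y

    def backward(self, grad):
        return grad * (1.0 - self._y**2)


class Sigmoid(Layer):
    def forward(self, x, train=True):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, grad):
        return grad * self._y * (1.0 - self._y)


class Softmax(Layer):
    def forward(self, x, train=True):
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        self._y = e / e.sum(axis=-1, keepdims=True)
        return self._y

    def backward(self, grad):
        dot = (grad * self._y).sum(axis=-1, keepdims=True)
        return self._y * (grad - dot)


def _same_pads(size: int, k: int, stride: int) -> tuple[int, int, int]:
    """TensorFlow 'same' padding: returns (out_size, pad_lo, pad_hi)."""
    out = -(-size // stride)
    total = max((out - 1) * stride + k - size, 0)
    lo = total // 2
    return out, lo, total - lo


def _im2col(xp: np.ndarray, k: int, stride: int, oh: int, ow: int) -> np.ndarray:
    """(N, Hp, Wp, C) padded input -> (N, oh, ow, k*k*C) patch matrix."""
    n, _, _, c = xp.shape
    s0, s1, s2, s3 = xp.strides
    shape = (n, oh, ow, k, k, c)
    strides = (s0, s1 * stride, s2 * stride, s1, s2, s3)
    cols = np.lib.stride_tricks.as_strided(xp, shape=shape, strides=strides)
    return cols.reshape(n, oh, ow, k * k * c)


class Conv2D(Layer):
    """2-D convolution (cross-correlation), NHWC, TF-style 'same' padding."""

    def __init__(self, c_in: int, c_out: int, k: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = k * k * c_in
        self.W = _glorot(rng, (k, k, c_in, c_out), fan_in, k * k * c_out)
        self.b = np.zeros(c_out)
        self.k, self.stride, self.c_in, self.c_out = k, stride, c_in, c_out
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def _kernel(self) -> np.ndarray:
        return self.W

    def forward(self, x, train=True):
        n, h, w, c = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        k, s = self.k, self.stride
        oh, pt, pb = _same_pads(h, k, s)
        ow, pl, pr = _same_pads(w, k, s)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        cols = _im2col(xp, k, s, oh, ow)
        self._cols = cols.reshape(-1, k * k * c)
        self._geom = (x.shape, (pt, pb, pl, pr), oh, ow)
        Wm = self._kernel().reshape(-1, self.c_out)
        y = self._cols @ Wm + self.b
        return y.reshape(n, oh, ow, self.c_out)

    def backward(self, grad):
        (xshape, pads, oh, ow) = self._geom
        n, h, w, c = xshape
        k, s = self.k, self.stride
        g = grad.reshape(-1, self.c_out)
        dWm = self._cols.T @ g
        self._store_kernel_grad(dWm.reshape(self.W.shape))
        self.db[...] = g.sum(axis=0)
        dcols = (g @ self._kernel().reshape(-1, self.c_out).T).reshape(n, oh, ow, k, k, c)
        pt, pb, pl, pr = pads
        dxp = np.zeros((n, h + pt + pb, w + pl + pr, c))
        for di in range(k):
            for dj in range(k):
                dxp[:, di : di + oh * s : s, dj : dj + ow * s : s, :] += dcols[:, :, :, di, dj, :]
        return dxp[:, pt : pt + h, pl : pl + w, :]

    def _store_kernel_grad(self, dk: np.ndarray) -> None:
        self.dW[...] = dk

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class ConvTranspose2D(Conv2D):
    """Stride-1 'same' transposed convolution (odd kernel).

    With unit stride and symmetric padding this is the adjoint of a same
    convolution: a cross-correlation with the spatially flipped kernel.
    Parameter shape and count match the forward convolution.
    """

    def __init__(self, c_in: int, c_out: int, k: int,
                 rng: np.random.Generator | None = None):
        if k % 2 == 0:
            raise ValueError("only odd kernels supported for transposed conv")
        super().__init__(c_in, c_out, k, stride=1, rng=rng)

    def _kernel(self):
        return self.W[::-1, ::-1]

    def _store_kernel_grad(self, dk):
        self.dW[...] = dk[::-1, ::-1]


class Upsample2x(Layer):
    """Nearest-neighbour 2x spatial upsampling (NHWC)."""

    def forward(self, x, train=True):
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, grad):
        n, h, w, c = grad.shape
        return grad.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]

    def set_rng(self, rng):
        for layer in self.layers:
            layer.set_rng(rng)

    def param_count(self):
        return int(sum(layer.param_count() for layer in self.layers))


class Adam:
    """Adam with the GAN-conventional beta1 = 0.5 default."""

    def __init__(self, params: list[np.ndarray], lr: float = 2e-4,
                 beta1: float = 0.5, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
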