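"""Minimal feed-forward/convolutional network engine on numpy.

Layers follow an explicit forward/backward protocol with hand-derived
gradients; arrays are NCHW.  Every layer exposes ``params()`` and ``grads()``
as dicts of named arrays so optimizers and checkpoints can treat models as
flat parameter collections.

Weight equalization (the equalized-learning-rate rule): when a layer is
created with ``equalized=True`` its stored weights are kept at unit scale and
multiplied at every forward pass by ``gain * sqrt(2 / fan_in)``.  The ``gain``
attribute makes the reparameterization explicit: multiplying the raw weights
by k while dividing ``gain`` by k leaves the computed function unchanged.
"""

from __future__ import annotations

import numpy as np


def equalized_scale(fan_in: int) -> float:
    """Per-layer weight multiplier sqrt(2 / fan_in).

    ``fan_in`` is the number of input channels times the kernel area.  The
    runtime scaling keeps the effective learning rate comparable across
    layers of different width.
    """
    if fan_in < 1:
        raise ValueError(f"fan_in must be >= 1, got {fan_in}")
    return float(np.sqrt(2.0 / fan_in))


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """(N,C,H,W) -> (N, C*kh*kw, Ho*Wo) patch matrix."""
    n, c, h, w = x.shape
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (w + 2 * pad - kw) // stride + 1
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, kh, kw, ho, wo), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = x[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
    return cols.reshape(n, c * kh * kw, ho * wo), ho, wo


def _col2im(cols: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int) -> np.ndarray:
    """Adjoint of _im2col: scatter-add patches back onto the image grid."""
    n, c, h, w = x_shape
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (w + 2 * pad - kw) // stride + 1
    cols = cols.reshape(n, c, kh, kw, ho, wo)
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            xp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += cols[:, :, i, j]
    if pad:
        xp = xp[:, :, pad:-pad, pad:-pad]
    return xp


class Layer:
    """Base layer: stateless by default, trainable layers override params()."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> dict:
        return {}

    def grads(self) -> dict:
        return {}


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 equalized: bool = False, init_sd: float = 0.02):
        self.equalized = equalized
        self.gain = 1.0
        self.fan_in = in_features
        self.w = rng.normal(0.0, init_sd, (in_features, out_features))
        if equalized:
            # raw weights absorb 1/c so the effective init matches init_sd
            self.w /= equalized_scale(self.fan_in)
        self.b = np.zeros(out_features)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def _scale(self) -> float:
        return self.gain * (equalized_scale(self.fan_in) if self.equalized else 1.0)

    def forward(self, x, train=True):
        self._x = x
        return x @ (self.w * self._scale()) + self.b

    def backward(self, grad):
        c = self._scale()
        self.dw = (self._x.T @ grad) * c
        self.db = grad.sum(axis=0)
        return grad @ (self.w * c).T

    def params(self):
        return {"w": self.w, "b": self.b}

    def grads(self):
        return {"w": self.dw, "b": self.db}


class Conv2d(Layer):
    def __init__(self, in_channels: int, out_channels: int, kernel: int, stride: int,
                 pad: int, rng: np.random.Generator, equalized: bool = False,
                 init_sd: float = 0.02):
        self.cin, self.cout = in_channels, out_channels
        self.k, self.stride, self.pad = kernel, stride, pad
        self.equalized = equalized
        self.gain = 1.0
        self.fan_in = in_channels * kernel * kernel
        shape = (out_channels, in_channels, kernel, kernel)
        self.w = rng.normal(0.0, init_sd, shape)
        if equalized:
            self.w /= equalized_scale(self.fan_in)
        self.b = np.zeros(out_channels)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def _scale(self) -> float:
        return self.gain * (equalized_scale(self.fan_in) if self.equalized else 1.0)

    def forward(self, x, train=True):
        if x.shape[1] != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {x.shape[1]}")
        self._x_shape = x.shape
        self._cols, ho, wo = _im2col(x, self.k, self.k, self.stride, self.pad)
        wmat = (self.w * self._scale()).reshape(self.cout, -1)
        out = np.einsum("fk,nkp->nfp", wmat, self._cols)
        return out.reshape(x.shape[0], self.cout, ho, wo) + self.b[None, :, None, None]

    def backward(self, grad):
        n = grad.shape[0]
        c = self._scale()
        gmat = grad.reshape(n, self.cout, -1)
        self.dw = np.einsum("nfp,nkp->fk", gmat, self._cols).reshape(self.w.shape) * c
        self.db = gmat.sum(axis=(0, 2))
        wmat = (self.w * c).reshape(self.cout, -1)
        dcols = np.einsum("fk,nfp->nkp", wmat, gmat)
        return _col2im(dcols, self._x_shape, self.k, self.k, self.stride, self.pad)

    def params(self):
        return {"w": self.w, "b": self.b}

    def grads(self):
        return {"w": self.dw, "b": self.db}


class ConvTranspose2d(Layer):
    """Transposed convolution: forward is the adjoint of Conv2d's forward."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int, stride: int,
                 pad: int, rng: np.random.Generator, equalized: bool = False,
                 init_sd: float = 0.02):
        self.cin, self.cout = in_channels, out_channels
        self.k, self.stride, self.pad = kernel, stride, pad
        self.equalized = equalized
        self.gain = 1.0
        self.fan_in = in_channels * kernel * kernel
        shape = (in_channels, out_channels, kernel, kernel)
        self.w = rng.normal(0.0, init_sd, shape)
        if equalized:
            self.w /= equalized_scale(self.fan_in)
        self.b = np.zeros(out_channels)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def out_size(self, h: int) -> int:
        return (h - 1) * self.stride - 2 * self.pad + self.k

    def _scale(self) -> float:
        return self.gain * (equalized_scale(self.fan_in) if self.equalized else 1.0)

    def forward(self, x, train=True):
        if x.shape[1] != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {x.shape[1]}")
        n, _, h, w = x.shape
        ho, wo = self.out_size(h), self.out_size(w)
        self._xflat = x.reshape(n, self.cin, h * w)
        wmat = (self.w * self._scale()).reshape(self.cin, -1)  # (cin, cout*k*k)
        cols = np.einsum("ck,ncp->nkp", wmat, self._xflat)
        out = _col2im(cols, (n, self.cout, ho, wo), self.k, self.k, self.stride, self.pad)
        self._out_shape = out.shape
        return out + self.b[None, :, None, None]

    def backward(self, grad):
        n = grad.shape[0]
        c = self._scale()
        gcols, ho, wo = _im2col(grad, self.k, self.k, self.stride, self.pad)
        self.dw = np.einsum("ncp,nkp->ck", self._xflat, gcols).reshape(self.w.shape) * c
        self.db = grad.sum(axis=(0, 2, 3))
        wmat = (self.w * c).reshape(self.cin, -1)
        dx = np.einsum("ck,nkp->ncp", wmat, gcols)
        return dx.reshape(n, self.cin, ho, wo)

    def params(self):
        return {"w": self.w, "b": self.b}

    def grads(self):
        return {"w": self.dw, "b": self.db}


class BatchNorm2d(Layer):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.9):
        self.eps, self.momentum = eps, momentum
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None, None]) * self._istd[None, :, None, None]
        self._m = x.shape[0] * x.shape[2] * x.shape[3]
        self._train = train
        return self.gamma[None, :, None, None] * self._xhat + self.beta[None, :, None, None]

    def backward(self, grad):
        self.dgamma = (grad * self._xhat).sum(axis=(0, 2, 3))
        self.dbeta = grad.sum(axis=(0, 2, 3))
        g = self.gamma[None, :, None, None] * self._istd[None, :, None, None]
        if not self._train:
            return grad * g
        m = self._m
        sum_g = grad.sum(axis=(0, 2, 3)).reshape(1, -1, 1, 1)
        sum_gx = (grad * self._xhat).sum(axis=(0, 2, 3)).reshape(1, -1, 1, 1)
        return g * (grad - sum_g / m - self._xhat * sum_gx / m)

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta,
                "running_mean": self.running_mean, "running_var": self.running_var}

    def grads(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, grad):
        return np.where(self._mask, grad, self.slope * grad)


class Tanh(Layer):
    def forward(self, x, train=True):
        self._y = np.tanh(x)
        return self._y

    def backward(self, grad):
        return grad * (1.0 - self._y ** 2)


class Sigmoid(Layer):
    def forward(self, x, train=True):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, grad):
        return grad * self._y * (1.0 - self._y)


class Reshape(Layer):
    def __init__(self, shape):
        self.shape = shape  # per-sample shape

    def forward(self, x, train=True):
        self._in_shape = x.shape
        return x.reshape((x.shape[0],) + tuple(self.shape))

    def backward(self, grad):
        return grad.reshape(self._in_shape)


class Flatten(Layer):
    def forward(self, x, train=True):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._in_shape)


class CenterCrop(Layer):
    """Crop NCHW activations to a target spatial size (generator tail)."""

    def __init__(self, out_h: int, out_w: int):
        self.out_h, self.out_w = out_h, out_w

    def forward(self, x, train=True):
        self._in_shape = x.shape
        h, w = x.shape[2], x.shape[3]
        self._i0 = (h - self.out_h) // 2
        self._j0 = (w - self.out_w) // 2
        return x[:, :, self._i0 : self._i0 + self.out_h, self._j0 : self._j0 + self.out_w]

    def backward(self, grad):
        out = np.zeros(self._in_shape, dtype=grad.dtype)
        out[:, :, self._i0 : self._i0 + self.out_h, self._j0 : self._j0 + self.out_w] = grad
        return out


class GlobalAvgPool(Layer):
    def forward(self, x, train=True):
        self._in_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        n, c, h, w = self._in_shape
        return np.broadcast_to(grad[:, :, None, None], self._in_shape) / (h * w)


class Sequential(Layer):
    def __init__(self, layers):
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
        out = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.params().items():
                out[f"{i}.{k}"] = v
        return out

    def grads(self):
        out = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.grads().items():
                out[f"{i}.{k}"] = v
        return out

    def set_params(self, named: dict):
        """Load parameter arrays in place (shapes must match)."""
        own = self.params()
        for k, v in named.items():
            if k not in own:
                raise KeyError(f"unknown parameter {k}")
            if own[k].shape != v.shape:
                raise ValueError(f"shape mismatch for {k}: {own[k].shape} vs {v.shape}")
            own[k][...] = v
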