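"""Minimal NumPy building blocks for 3D convolutional networks.

Implements exactly what the sex classifier needs — 3D convolution (im2col +
BLAS matmul), batch normalisation, 2x max pooling, ReLU, average pooling,
inverted dropout, a logistic (sigmoid + binary cross-entropy) loss, Adam, and
a reduce-on-plateau learning-rate schedule — with hand-derived backward
passes. Backprop runs all the way to the input tensor, which is what the
gradient class-saliency maps are computed from.

Conventions: activations are ``float32`` arrays of shape ``(N, C, D, H, W)``;
every layer exposes ``forward(x, train)`` and ``backward(grad)``;
``backward`` must be called on the most recent forward's cache.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv3d", "BatchNorm3d", "MaxPool3d", "ReLU", "AvgPool3d", "Dropout",
    "Sequential", "bce_with_logits", "sigmoid", "Adam", "ReduceLROnPlateau",
]


def sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def bce_with_logits(logits, targets):
    """Mean binary cross-entropy on raw scores; returns (loss, dlogits).

    Numerically stable log1p(exp(-|z|)) form; ``dlogits`` is the gradient of
    the mean loss.
    """
    z = np.asarray(logits, dtype=np.float64).ravel()
    y = np.asarray(targets, dtype=np.float64).ravel()
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    dz = (sigmoid(z) - y) / z.size
    return loss, dz.astype(np.float32)


def _im2col(x, k, pad):
    """Unfold (N,C,D,H,W) into GEMM columns (N*Do*Ho*Wo, C*k^3)."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0)) + ((pad, pad),) * 3)
    n, c = x.shape[:2]
    do, ho, wo = (x.shape[2] - k + 1, x.shape[3] - k + 1, x.shape[4] - k + 1)
    win = sliding_window_view(x, (k, k, k), axis=(2, 3, 4))
    cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(n * do * ho * wo,
                                                         c * k ** 3)
    return np.ascontiguousarray(cols), (do, ho, wo)


def _col2im(gcols, in_shape, k, pad, out_spatial):
    """Scatter-add GEMM columns back onto the (padded) input grid."""
    n, c, d, h, w = in_shape
    do, ho, wo = out_spatial
    gxp = np.zeros((n, c, d + 2 * pad, h + 2 * pad, w + 2 * pad),
                   dtype=gcols.dtype)
    gr = gcols.reshape(n, do, ho, wo, c, k, k, k).transpose(0, 4, 1, 2, 3, 5, 6, 7)
    for i in range(k):
        for j in range(k):
            for l in range(k):
                gxp[:, :, i:i + do, j:j + ho, l:l + wo] += gr[..., i, j, l]
    if pad:
        return np.ascontiguousarray(gxp[:, :, pad:pad + d, pad:pad + h,
                                        pad:pad + w])
    return gxp


class Layer:
    def parameters(self):
        return []

    def forward(self, x, train=False):          # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):                   # pragma: no cover - interface
        raise NotImplementedError


class Conv3d(Layer):
    """3D convolution, stride 1, cubic kernel, 'same' padding for k=3.

    ``input_grad`` may be switched off for the network's first layer during
    weight training (nothing upstream needs that gradient); saliency mapping
    switches it back on.
    """

    def __init__(self, in_channels, out_channels, kernel_size=3, padding=None,
                 rng=None):
        if padding is None:
            padding = (kernel_size - 1) // 2
        self.k, self.pad = kernel_size, padding
        self.input_grad = True
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel_size ** 3
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(out_channels, in_channels,
                                  kernel_size, kernel_size, kernel_size)
                            ).astype(np.float32)
        self.b = np.zeros(out_channels, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def parameters(self):
        return [(self.w, self.gw), (self.b, self.gb)]

    def forward(self, x, train=False):
        n = x.shape[0]
        co = self.w.shape[0]
        self._in_shape = x.shape
        if self.k == 1:
            self._cols = None
            self._x = x
            out = np.matmul(self.w.reshape(co, -1), x.reshape(n, x.shape[1], -1))
            out = out.reshape(n, co, *x.shape[2:])
            self._out_spatial = x.shape[2:]
        else:
            cols, self._out_spatial = _im2col(x, self.k, self.pad)
            self._cols = cols
            out = cols @ self.w.reshape(co, -1).T
            out = np.ascontiguousarray(
                out.reshape(n, *self._out_spatial, co).transpose(0, 4, 1, 2, 3))
        out += self.b[None, :, None, None, None]
        return out

    def backward(self, grad):
        k, pad = self.k, self.pad
        n, co = grad.shape[:2]
        self.gb[...] = grad.sum(axis=(0, 2, 3, 4))
        wmat = self.w.reshape(co, -1)
        if k == 1:
            ci = self._in_shape[1]
            g2 = grad.reshape(n, co, -1)
            self.gw[...] = np.einsum("ncx,nkx->ck", g2,
                                     self._x.reshape(n, ci, -1)
                                     ).reshape(self.w.shape)
            if not self.input_grad:
                return None
            gx = np.matmul(wmat.T, g2)
            return gx.reshape(self._in_shape).astype(grad.dtype)
        g2 = np.ascontiguousarray(
            grad.transpose(0, 2, 3, 4, 1).reshape(-1, co))
        self.gw[...] = (g2.T @ self._cols).reshape(self.w.shape)
        if not self.input_grad:
            return None
        gcols = g2 @ wmat
        return _col2im(gcols, self._in_shape, k, pad, self._out_spatial)


class BatchNorm3d(Layer):
    def __init__(self, channels, eps=1e-5, momentum=0.1):
        self.eps, self.momentum = eps, momentum
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def parameters(self):
        return [(self.gamma, self.ggamma), (self.beta, self.gbeta)]

    @staticmethod
    def _bc(v):
        return v[None, :, None, None, None]

    def forward(self, x, train=False):
        self._train = train
        if train:
            mean = x.mean(axis=(0, 2, 3, 4))
            var = x.var(axis=(0, 2, 3, 4))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(np.float32)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        self._invstd = 1.0 / np.sqrt(np.asarray(var, dtype=x.dtype) + self.eps)
        self._xhat = (x - self._bc(mean)) * self._bc(self._invstd)
        return self._bc(self.gamma) * self._xhat + self._bc(self.beta)

    def backward(self, grad):
        xhat, invstd = self._xhat, self._invstd
        self.ggamma[...] = (grad * xhat).sum(axis=(0, 2, 3, 4))
        self.gbeta[...] = grad.sum(axis=(0, 2, 3, 4))
        if not self._train:
            return grad * self._bc(self.gamma * invstd)
        n = grad.shape[0] * grad.shape[2] * grad.shape[3] * grad.shape[4]
        gxhat = grad * self._bc(self.gamma)
        mean_g = gxhat.mean(axis=(0, 2, 3, 4))
        mean_gx = (gxhat * xhat).mean(axis=(0, 2, 3, 4))
        del n
        return (gxhat - self._bc(mean_g) - xhat * self._bc(mean_gx)) \
            * self._bc(invstd)


class MaxPool3d(Layer):
    """2x2x2 max pooling, stride 2, floor semantics on odd extents."""

    def forward(self, x, train=False):
        n, c, d, h, w = x.shape
        d2, h2, w2 = d // 2, h // 2, w // 2
        self._in_shape = x.shape
        xr = x[:, :, :2 * d2, :2 * h2, :2 * w2] \
            .reshape(n, c, d2, 2, h2, 2, w2, 2) \
            .transpose(0, 1, 2, 4, 6, 3, 5, 7) \
            .reshape(n, c, d2, h2, w2, 8)
        self._idx = xr.argmax(axis=-1)
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        n, c, d, h, w = self._in_shape
        d2, h2, w2 = d // 2, h // 2, w // 2
        gwin = np.zeros((n, c, d2, h2, w2, 8), dtype=grad.dtype)
        np.put_along_axis(gwin, self._idx[..., None], grad[..., None], axis=-1)
        gx = np.zeros(self._in_shape, dtype=grad.dtype)
        gx[:, :, :2 * d2, :2 * h2, :2 * w2] = gwin \
            .reshape(n, c, d2, h2, w2, 2, 2, 2) \
            .transpose(0, 1, 2, 5, 3, 6, 4, 7) \
            .reshape(n, c, 2 * d2, 2 * h2, 2 * w2)
        return gx


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad):
        return np.where(self._mask, grad, 0.0)


class AvgPool3d(Layer):
    """Average pooling whose kernel spans the full remaining spatial extent
    (the network's head collapses space to 1x1x1)."""

    def __init__(self, kernel):
        self.kernel = tuple(kernel)

    def forward(self, x, train=False):
        if x.shape[2:] != self.kernel:
            raise ValueError(f"avgpool kernel {self.kernel} does not match "
                             f"spatial extent {x.shape[2:]}")
        self._shape = x.shape
        return x.mean(axis=(2, 3, 4), keepdims=True)

    def backward(self, grad):
        scale = 1.0 / np.prod(self.kernel)
        return np.broadcast_to(grad * scale, self._shape).astype(grad.dtype)


class Dropout(Layer):
    """Inverted dropout; active only when ``train`` is true."""

    def __init__(self, p=0.5, rng=None):
        self.p = p
        self.rng = rng or np.random.default_rng()

    def forward(self, x, train=False):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return (x * self._mask).astype(x.dtype)

    def backward(self, grad):
        if self._mask is None:
            return grad
        return (grad * self._mask).astype(grad.dtype)


class Sequential(Layer):
    def __init__(self, layers):
        self.layers = list(layers)

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def state_dict(self):
        return [p.copy() for p, _ in self.parameters()]

    def load_state_dict(self, state):
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state does not match parameter count")
        for (p, _), s in zip(params, state):
            p[...] = s

    def zero_grad(self):
        for _, g in self.parameters():
            g[...] = 0.0


class Adam:
    def __init__(self, params, lr=0.01, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class ReduceLROnPlateau:
    """Multiply the optimiser's lr by ``factor`` after ``patience``
    consecutive epochs without validation-loss improvement (min mode)."""

    def __init__(self, optimizer, factor=0.1, patience=5):
        self.opt = optimizer
        self.factor = factor
        self.patience = patience
        self.best = np.inf
        self.stale = 0

    def step(self, metric):
        if metric < self.best:
            self.best = metric
            self.stale = 0
        else:
            self.stale += 1
            if self.stale >= self.patience:
                self.opt.lr *= self.factor
                self.stale = 0
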