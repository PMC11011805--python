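"""Minimal numpy neural-network core used by the adversarial autoencoder.

Layers follow a plain forward/backward protocol on NCHW tensors (conv
layers) or (n, features) matrices (dense layers).  Each layer exposes
``params`` and ``grads`` dicts keyed by parameter name; :class:`Adam`
holds per-array moment state.  Training noise (dropout-style stochastic
layers) is deliberately absent: all stochasticity lives in the callers,
so inference is bitwise deterministic.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "Dense", "Conv2d", "BatchNorm2d", "ReLU", "LeakyReLU",
    "Sigmoid", "Flatten", "Reshape", "MaxPool2", "Upsample2",
    "MinibatchDiscrimination", "Sequential", "Adam",
    "bce_with_logits", "bce_with_logits_grad",
]


class Layer:
    """Base class: stateless layers only override forward/backward."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k in self.grads:
            self.grads[k][...] = 0.0


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 scale: float | None = None):
        super().__init__()
        s = scale if scale is not None else np.sqrt(2.0 / n_in)
        self.params = {
            "W": rng.normal(0.0, s, size=(n_in, n_out)),
            "b": np.zeros(n_out),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, train=False):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad):
        self.grads["W"] += self._x.T @ grad
        self.grads["b"] += grad.sum(axis=0)
        return grad @ self.params["W"].T


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N,C,H,W) -> (N, C*k*k, H*W) patches for stride-1 'same' conv."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, k, k, h, w), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j, :, :] = xp[:, :, i:i + h, j:j + w]
    return cols.reshape(n, c * k * k, h * w)


def _col2im(cols: np.ndarray, shape: tuple, k: int, pad: int) -> np.ndarray:
    n, c, h, w = shape
    cols = cols.reshape(n, c, k, k, h, w)
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            xp[:, :, i:i + h, j:j + w] += cols[:, :, i, j, :, :]
    return xp[:, :, pad:pad + h, pad:pad + w]


class Conv2d(Layer):
    """Stride-1, same-padded 2D convolution via im2col."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 kernel: int = 3):
        super().__init__()
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        s = np.sqrt(2.0 / (c_in * kernel * kernel))
        self.params = {
            "W": rng.normal(0.0, s, size=(c_out, c_in * kernel * kernel)),
            "b": np.zeros(c_out),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, train=False):
        self._shape = x.shape
        n, c, h, w = x.shape
        self._cols = _im2col(x, self.k, self.k // 2)
        y = np.einsum("of,nfp->nop", self.params["W"], self._cols)
        y += self.params["b"][None, :, None]
        return y.reshape(n, self.c_out, h, w)

    def backward(self, grad):
        n, _, h, w = self._shape
        g = grad.reshape(n, self.c_out, h * w)
        self.grads["W"] += np.einsum("nop,nfp->of", g, self._cols)
        self.grads["b"] += g.sum(axis=(0, 2))
        dcols = np.einsum("of,nop->nfp", self.params["W"], g)
        return _col2im(dcols, self._shape, self.k, self.k // 2)


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params = {"gamma": np.ones(c), "beta": np.zeros(c)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None, None]) / self._std[None, :, None, None]
        self._train = train
        return (self.params["gamma"][None, :, None, None] * self._xhat
                + self.params["beta"][None, :, None, None])

    def backward(self, grad):
        self.grads["gamma"] += (grad * self._xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] += grad.sum(axis=(0, 2, 3))
        g = grad * self.params["gamma"][None, :, None, None]
        if not self._train:
            return g / self._std[None, :, None, None]
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        dxhat = g
        dx = (dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True)
              - self._xhat * (dxhat * self._xhat).mean(axis=(0, 2, 3), keepdims=True))
        del m
        return dx / self._std[None, :, None, None]


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.2):
        super().__init__()
        self.alpha = alpha

    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, grad):
        return np.where(self._mask, grad, self.alpha * grad)


class Sigmoid(Layer):
    def forward(self, x, train=False):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, grad):
        return grad * self._y * (1.0 - self._y)


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape: tuple):
        super().__init__()
        self.shape = shape

    def forward(self, x, train=False):
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, grad):
        return grad.reshape(grad.shape[0], -1)


class MaxPool2(Layer):
    """2x2 max pooling; spatial dims must be even."""

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        xr = (x.reshape(n, c, h // 2, 2, w // 2, 2)
               .transpose(0, 1, 2, 4, 3, 5)
               .reshape(n, c, h // 2, w // 2, 4))
        self._idx = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        n, c, h, w = self._shape
        out = np.zeros((n, c, h // 2, w // 2, 4), dtype=grad.dtype)
        np.put_along_axis(out, self._idx[..., None], grad[..., None], axis=-1)
        return (out.reshape(n, c, h // 2, w // 2, 2, 2)
                   .transpose(0, 1, 2, 4, 3, 5)
                   .reshape(n, c, h, w))


class Upsample2(Layer):
    """2x nearest-neighbour upsampling."""

    def forward(self, x, train=False):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, grad):
        n, c, h, w = grad.shape
        return (grad.reshape(n, c, h // 2, 2, w // 2, 2)
                    .sum(axis=(3, 5)))


class MinibatchDiscrimination(Layer):
    """Salimans-style mini-batch similarity features.

    Projects each row of the incoming feature matrix F (m, f) through a
    learned tensor T of shape (f, B, C); for kernel b the feature is
    o(x_i)_b = sum_j exp(-||M_{i,b} - M_{j,b}||_1) with M_i = F_i . T.
    The B similarity features are concatenated to F.  B=0 disables the
    layer (identity pass-through) for ablation.
    """

    def __init__(self, n_features: int, n_kernels: int, kernel_dim: int,
                 rng: np.random.Generator, init_scale: float = 0.02):
        super().__init__()
        self.B, self.C = n_kernels, kernel_dim
        if self.B > 0:
            self.params = {"T": rng.normal(
                0.0, init_scale, size=(n_features, n_kernels, kernel_dim))}
            self.grads = {"T": np.zeros_like(self.params["T"])}

    @property
    def n_out_extra(self) -> int:
        return self.B

    def similarity(self, F: np.ndarray) -> np.ndarray:
        """The o(x_i) block alone, shape (m, B)."""
        if self.B == 0:
            return np.zeros((F.shape[0], 0))
        return self._compute(F)[0]

    def _compute(self, F):
        T = self.params["T"]
        f = T.shape[0]
        M = (F @ T.reshape(f, self.B * self.C)).reshape(-1, self.B, self.C)
        # D[i,j,b] = L1 distance between kernel-b rows of samples i and j
        diff = M[:, None, :, :] - M[None, :, :, :]
        D = np.abs(diff).sum(axis=-1)
        K = np.exp(-D)
        o = K.sum(axis=1)
        return o, M, diff, K

    def forward(self, x, train=False):
        if self.B == 0:
            return x
        self._F = x
        o, M, diff, K = self._compute(x)
        self._M, self._diff, self._K = M, diff, K
        return np.concatenate([x, o], axis=1)

    def backward(self, grad):
        if self.B == 0:
            return grad
        f = self._F.shape[1]
        dF = grad[:, :f].copy()
        g = grad[:, f:]                      # (m, B) = dL/do
        sign = np.sign(self._diff)           # (m, m, B, C)
        w = -(g[:, None, :] + g[None, :, :]) * self._K   # (m, m, B)
        dM = (w[..., None] * sign).sum(axis=1)           # (m, B, C)
        T = self.params["T"]
        self.grads["T"] += (self._F.T @ dM.reshape(-1, self.B * self.C)
                            ).reshape(T.shape)
        dF += dM.reshape(-1, self.B * self.C) @ T.reshape(f, self.B * self.C).T
        return dF


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def zero_grad(self):
        for layer in self.layers:
            layer.zero_grad()

    def parameters(self):
        return [(layer, name) for layer in self.layers for name in layer.params]


class Adam:
    def __init__(self, modules: list[Sequential], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.handles = [h for m in modules for h in m.parameters()]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(l.params[n]) for l, n in self.handles]
        self.v = [np.zeros_like(l.params[n]) for l, n in self.handles]

    def step(self):
        self.t += 1
        for i, (layer, name) in enumerate(self.handles):
            g = layer.grads[name]
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            layer.params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def bce_with_logits(logits: np.ndarray, target: float) -> float:
    """Numerically stable mean binary cross-entropy from logits."""
    z = logits.ravel()
    return float(np.mean(np.maximum(z, 0) - z * target + np.log1p(np.exp(-np.abs(z)))))


def bce_with_logits_grad(logits: np.ndarray, target: float) -> np.ndarray:
    z = logits
    p = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
    return (p - target) / z.size
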