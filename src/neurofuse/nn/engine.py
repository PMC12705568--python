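"""Minimal seeded neural-network engine (NumPy).

Layers operate on channels-last arrays, carry explicit forward/backward
passes with cached activations, and draw every random decision (weight
initialization, dropout masks, shuffling) from a single
``numpy.random.Generator`` so that training is bit-reproducible on CPU.
Implemented primitives: 3x3 same-padding convolution (im2col), ReLU, 2x2 max
pooling, dense layers, 1D batch normalization, inverted dropout, and Adam.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float64


class Layer:
    """Forward/backward unit; ``params()`` yields (name, value, grad) triples."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self):
        return []


def he_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Conv2D(Layer):
    """3x3 (configurable) convolution with 'same' zero padding, NHWC layout."""

    def __init__(self, cin: int, cout: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.k = kernel
        self.cin, self.cout = cin, cout
        fan_in = kernel * kernel * cin
        self.w = he_uniform(rng, (fan_in, cout), fan_in)
        self.b = np.zeros(cout, dtype=DTYPE)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, h, w, _ = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k), axis=(1, 2))
        # win: (n, h, w, cin, k, k) -> cols (n*h*w, k*k*cin)
        cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * h * w, -1)
        self._cols, self._xshape = cols, x.shape
        y = cols @ self.w + self.b
        return y.reshape(n, h, w, self.cout)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, _ = self._xshape
        dyf = dy.reshape(n * h * w, self.cout)
        self.dw += self._cols.T @ dyf
        self.db += dyf.sum(axis=0)
        dcols = (dyf @ self.w.T).reshape(n, h, w, self.k, self.k, self.cin)
        p = self.k // 2
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, self.cin), dtype=DTYPE)
        for ki in range(self.k):
            for kj in range(self.k):
                dxp[:, ki:ki + h, kj:kj + w, :] += dcols[:, :, :, ki, kj, :]
        return dxp[:, p:p + h, p:p + w, :]

    def params(self):
        return [("w", self.w, self.dw), ("b", self.b, self.db)]


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; ties resolve to the first occurrence."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even for 2x2 pooling, got {h}x{w}")
        xr = (x.reshape(n, h // 2, 2, w // 2, 2, c)
              .transpose(0, 1, 3, 5, 2, 4).reshape(n, h // 2, w // 2, c, 4))
        self._arg = xr.argmax(axis=-1)
        self._xshape = x.shape
        return np.take_along_axis(xr, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._xshape
        dxr = np.zeros((n, h // 2, w // 2, c, 4), dtype=DTYPE)
        np.put_along_axis(dxr, self._arg[..., None], dy[..., None], axis=-1)
        return (dxr.reshape(n, h // 2, w // 2, c, 2, 2)
                .transpose(0, 1, 4, 2, 5, 3).reshape(n, h, w, c))


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, fin: int, fout: int, rng: np.random.Generator):
        self.w = he_uniform(rng, (fin, fout), fin)
        self.b = np.zeros(fout, dtype=DTYPE)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dw += self._x.T @ dy
        self.db += dy.sum(axis=0)
        return dy @ self.w.T

    def params(self):
        return [("w", self.w, self.dw), ("b", self.b, self.db)]


class BatchNorm1D(Layer):
    """Per-feature batch normalization; evaluation uses running statistics."""

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(n_features, dtype=DTYPE)
        self.beta = np.zeros(n_features, dtype=DTYPE)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.run_mean = np.zeros(n_features, dtype=DTYPE)
        self.run_var = np.ones(n_features, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mu
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mu, var = self.run_mean, self.run_var
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._istd
        return self.gamma * self._xhat + self.beta

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n = dy.shape[0]
        self.dgamma += (dy * self._xhat).sum(axis=0)
        self.dbeta += dy.sum(axis=0)
        dxhat = dy * self.gamma
        return (self._istd / n) * (
            n * dxhat - dxhat.sum(axis=0) - self._xhat * (dxhat * self._xhat).sum(axis=0))

    def params(self):
        return [("gamma", self.gamma, self.dgamma), ("beta", self.beta, self.dbeta)]


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0 <= p < 1:
            raise ValueError(f"dropout rate must be in [0, 1), got {p}")
        self.p, self.rng = p, rng

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class Adam:
    """Adam optimizer over the (value, grad) pairs exposed by the layers."""

    def __init__(self, params, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(v) for _, v, _ in self.params]
        self.v = [np.zeros_like(v) for _, v, _ in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, (_, value, grad) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * grad * grad
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for _, _, grad in self.params:
            grad[...] = 0.0


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_xent(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits)
    loss = -np.log(p[np.arange(n), labels] + 1e-12).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), dlogits / n
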