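"""Minimal deterministic feed-forward trainer (dense + conv) on numpy.

Supports exactly what the supervised embedders need: dense and strided 3x3
convolution layers, ReLU, inverted dropout, global average pooling, Adam,
mean-squared-error loss, seeded mini-batch shuffling and early stopping
with best-weight restoration.  Everything is driven by one
``numpy.random.Generator`` so a fixed seed reproduces training exactly.
"""

from __future__ import annotations

import numpy as np


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.W.T


class ReLU:
    params: list = []
    grads: list = []

    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dropout:
    params: list = []
    grads: list = []

    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng

    def forward(self, x, train):
        if not train or self.p <= 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Conv3x3:
    """3x3 convolution, arbitrary stride, no padding; NCHW layout."""

    def __init__(self, c_in: int, c_out: int, stride: int, rng: np.random.Generator):
        fan_in = c_in * 9
        limit = np.sqrt(6.0 / (fan_in + c_out))
        self.W = rng.uniform(-limit, limit, size=(c_out, c_in, 3, 3))
        self.b = np.zeros(c_out)
        self.stride = stride
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train):
        self._x = x
        n, c, h, w = x.shape
        s = self.stride
        oh, ow = (h - 3) // s + 1, (w - 3) // s + 1
        out = np.zeros((n, self.W.shape[0], oh, ow))
        for di in range(3):
            for dj in range(3):
                xs = x[:, :, di:di + oh * s:s, dj:dj + ow * s:s]
                out += np.einsum("nchw,oc->nohw", xs, self.W[:, :, di, dj])
        return out + self.b[None, :, None, None]

    def backward(self, dout):
        x = self._x
        n, c, h, w = x.shape
        s = self.stride
        oh, ow = dout.shape[2], dout.shape[3]
        dx = np.zeros_like(x)
        for di in range(3):
            for dj in range(3):
                xs = x[:, :, di:di + oh * s:s, dj:dj + ow * s:s]
                self.grads[0][:, :, di, dj] = np.einsum("nohw,nchw->oc", dout, xs)
                dx[:, :, di:di + oh * s:s, dj:dj + ow * s:s] += np.einsum(
                    "nohw,oc->nchw", dout, self.W[:, :, di, dj])
        self.grads[1][...] = dout.sum(axis=(0, 2, 3))
        return dx


class GlobalAvgPool:
    """(N, C, H, W) -> (N, C)."""

    params: list = []
    grads: list = []

    def forward(self, x, train):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape) / (h * w)


class Network:
    """A layer stack trained with Adam on MSE; deterministic given its rng."""

    def __init__(self, layers: list, rng: np.random.Generator):
        self.layers = layers
        self.rng = rng
        self._adam_m = [[np.zeros_like(p) for p in l.params] for l in layers]
        self._adam_v = [[np.zeros_like(p) for p in l.params] for l in layers]
        self._adam_t = 0

    def forward(self, x, train=False, upto: int | None = None):
        for layer in (self.layers if upto is None else self.layers[:upto]):
            x = layer.forward(x, train)
        return x

    def _backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def _adam_step(self, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self._adam_t += 1
        t = self._adam_t
        for li, layer in enumerate(self.layers):
            for pi, p in enumerate(layer.params):
                g = layer.grads[pi]
                m = self._adam_m[li][pi]
                v = self._adam_v[li][pi]
                m *= beta1
                m += (1 - beta1) * g
                v *= beta2
                v += (1 - beta2) * g * g
                mhat = m / (1 - beta1**t)
                vhat = v / (1 - beta2**t)
                p -= lr * mhat / (np.sqrt(vhat) + eps)

    def get_weights(self):
        return [[p.copy() for p in l.params] for l in self.layers]

    def set_weights(self, weights):
        for layer, ws in zip(self.layers, weights):
            for p, w in zip(layer.params, ws):
                p[...] = w

    def weight_hash(self) -> int:
        acc = 0
        for l in self.layers:
            for p in l.params:
                acc ^= hash(p.tobytes())
        return acc

    def fit(self, X, y, X_val=None, y_val=None, epochs: int = 100,
            batch_size: int = 32, lr: float = 1e-3, patience: int = 10):
        """Train with early stopping on validation MSE, restoring the best
        weights.  Without a validation set, all epochs are run."""
        X = np.asarray(X, float)
        y = np.asarray(y, float).reshape(-1, 1)
        n = X.shape[0]
        have_val = X_val is not None and len(X_val) > 0
        best_loss, best_w, best_epoch = np.inf, None, 0
        history = []
        for epoch in range(epochs):
            order = self.rng.permutation(n)
            for start in range(0, n, batch_size):
                bi = order[start:start + batch_size]
                out = self.forward(X[bi], train=True)
                diff = out - y[bi]
                self._backward(2.0 * diff / len(bi))
                self._adam_step(lr)
            if have_val:
                pv = self.forward(np.asarray(X_val, float), train=False)
                vloss = float(np.mean((pv - np.asarray(y_val, float).reshape(-1, 1)) ** 2))
                history.append(vloss)
                if vloss < best_loss:
                    best_loss, best_w, best_epoch = vloss, self.get_weights(), epoch
                elif epoch - best_epoch >= patience:
                    break
        if best_w is not None:
            self.set_weights(best_w)
        self.val_history_ = history
        self.best_val_loss_ = best_loss if have_val else None
        return self
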