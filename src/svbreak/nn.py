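"""A compact, deterministic CNN in numpy.

Implements exactly what the breakpoint classifiers need: 5x5 stride-1 "same"
convolutions, ReLU, 2x2 max pooling, dense layers, a sigmoid score head,
binary cross-entropy with logits, and Adam.  Forward/backward passes are
im2col matrix products, so everything runs through BLAS and is reproducible
given a seed (single process, fixed thread count).

Arrays are NCHW: (batch, channels, height, width).
"""

from __future__ import annotations

import numpy as np


def sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits; returns (loss, dloss/dz)."""
    z = z.ravel()
    y = y.ravel().astype(float)
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    dz = (sigmoid(z) - y) / z.size
    return loss, dz.reshape(-1, 1)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*k*k) for a stride-1 'same' convolution."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # win: (N, C, H, W, k, k) -> (N, H, W, C, k, k)
    n, c, h, w = x.shape
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
    return np.ascontiguousarray(cols)


class Conv2D:
    """5x5 (configurable) stride-1 same-padded convolution."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 init_sd: float | None = None):
        sd = init_sd if init_sd is not None else float(np.sqrt(2.0 / (cin * k * k)))
        self.W = rng.normal(0.0, sd, size=(cout, cin, k, k))
        self.b = np.zeros(cout)
        self.k = k
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        cols = _im2col(x, self.k)
        out = cols @ self.W.reshape(self.W.shape[0], -1).T + self.b
        if train:
            self._cols, self._xshape = cols, x.shape
        return out.reshape(n, h, w, -1).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, co, h, w = dout.shape
        dmat = dout.transpose(0, 2, 3, 1).reshape(-1, co)
        self.dW = (dmat.T @ self._cols).reshape(self.W.shape)
        self.db = dmat.sum(axis=0)
        # dx = same-padded correlation of dout with the spatially flipped
        # kernel, channels transposed
        Wf = self.W[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (cin, cout, k, k)
        dcols = _im2col(dout, self.k)
        dx = dcols @ Wf.reshape(Wf.shape[0], -1).T
        _, cin, hh, ww = self._xshape
        self._cols = None
        return dx.reshape(n, h, w, cin).transpose(0, 3, 1, 2)

    def params(self):
        return [("W", self.W, "dW"), ("b", self.b, "db")]


class ReLU:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask

    def params(self):
        return []


class MaxPool2:
    """2x2 max pool; a spatial axis shorter than 2 is left unpooled, and an
    odd trailing row/column is dropped (floor semantics)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        ph = 2 if h >= 2 else 1
        pw = 2 if w >= 2 else 1
        h2, w2 = h // ph, w // pw
        xt = x[:, :, : h2 * ph, : w2 * pw]
        r = xt.reshape(n, c, h2, ph, w2, pw).transpose(0, 1, 2, 4, 3, 5)
        flat = r.reshape(n, c, h2, w2, ph * pw)
        am = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, am[..., None], axis=-1)[..., 0]
        if train:
            self._am, self._shape, self._pp = am, x.shape, (ph, pw)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        ph, pw = self._pp
        h2, w2 = h // ph, w // pw
        flat = np.zeros((n, c, h2, w2, ph * pw))
        np.put_along_axis(flat, self._am[..., None], dout[..., None], axis=-1)
        dx = np.zeros((n, c, h, w))
        dx[:, :, : h2 * ph, : w2 * pw] = (
            flat.reshape(n, c, h2, w2, ph, pw).transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h2 * ph, w2 * pw)
        )
        return dx

    def params(self):
        return []


class Flatten:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)

    def params(self):
        return []


class Dense:
    def __init__(self, din: int, dout: int, rng: np.random.Generator,
                 init_sd: float | None = None):
        sd = init_sd if init_sd is not None else float(np.sqrt(2.0 / din))
        self.W = rng.normal(0.0, sd, size=(din, dout))
        self.b = np.zeros(dout)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        self._x = None
        return dout @ self.W.T

    def params(self):
        return [("W", self.W, "dW"), ("b", self.b, "db")]


class Network:
    """A plain feed-forward stack with a single logit output."""

    def __init__(self, layers: list):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def predict_scores(self, x: np.ndarray, chunk: int = 512) -> np.ndarray:
        """Sigmoid scores in [0, 1], computed in chunks."""
        outs = [
            sigmoid(self.forward(x[i:i + chunk])).ravel()
            for i in range(0, x.shape[0], chunk)
        ]
        return np.concatenate(outs) if outs else np.empty(0)

    # -- parameter access ---------------------------------------------------
    def parameter_arrays(self) -> list[np.ndarray]:
        return [arr for layer in self.layers for _, arr, _ in layer.params()]

    def parameter_count(self) -> int:
        return int(sum(a.size for a in self.parameter_arrays()))

    def get_weights(self) -> list[np.ndarray]:
        return [a.copy() for a in self.parameter_arrays()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        arrays = self.parameter_arrays()
        if len(arrays) != len(weights):
            raise ValueError("weight list length mismatch")
        for dst, src in zip(arrays, weights):
            if dst.shape != src.shape:
                raise ValueError("weight shape mismatch")
            dst[...] = src

    def gradients(self) -> list[np.ndarray]:
        return [getattr(layer, gname) for layer in self.layers
                for _, _, gname in layer.params()]


class Adam:
    def __init__(self, net: Network, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        params = net.parameter_arrays()
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self) -> None:
        self.t += 1
        params = self.net.parameter_arrays()
        grads = self.net.gradients()
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
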