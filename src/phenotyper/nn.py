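"""Minimal deterministic CNN in NumPy.

A small residual convolutional network (3x3 convolutions, max pooling,
identity-skip residual blocks, global average pooling, softmax head)
trained with Adam on weighted cross-entropy. Everything is plain NumPy so
runs are reproducible from a single seed on any platform; the default
architecture is sized for 64x64 single-channel inputs on one CPU core.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


# --------------------------------------------------------------------------
# layers
# --------------------------------------------------------------------------
class Layer:
    params: list  # list of [value, grad] pairs

    def __init__(self):
        self.params = []

    def forward(self, x, train=True):
        raise NotImplementedError

    def backward(self, grad):
        raise NotImplementedError


class Conv3x3(Layer):
    """3x3 same-padding convolution via im2col."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / (cin * 9))
        self.w = rng.normal(0.0, scale, size=(cout, cin * 9))
        self.b = np.zeros(cout)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self.params = [[self.w, self.gw], [self.b, self.gb]]
        self.cin, self.cout = cin, cout

    def _im2col(self, xp, h, w):
        n, c = xp.shape[0], xp.shape[1]
        cols = np.empty((n, c, 9, h, w), dtype=xp.dtype)
        for i in range(3):
            for j in range(3):
                cols[:, :, i * 3 + j] = xp[:, :, i:i + h, j:j + w]
        return cols.reshape(n, c * 9, h * w)

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        cols = self._im2col(xp, h, w)
        if train:
            self._cols = cols
            self._shape = x.shape
        out = np.einsum("oc,ncp->nop", self.w, cols, optimize=True)
        out += self.b[None, :, None]
        return out.reshape(n, self.cout, h, w)

    def backward(self, grad):
        n, _, h, w = grad.shape
        g = grad.reshape(n, self.cout, h * w)
        self.gw += np.einsum("nop,ncp->oc", g, self._cols, optimize=True)
        self.gb += g.sum(axis=(0, 2))
        dcols = np.einsum("oc,nop->ncp", self.w, g, optimize=True)
        dcols = dcols.reshape(n, self.cin, 9, h, w)
        dxp = np.zeros((n, self.cin, h + 2, w + 2))
        for i in range(3):
            for j in range(3):
                dxp[:, :, i:i + h, j:j + w] += dcols[:, :, i * 3 + j]
        self._cols = None
        return dxp[:, :, 1:-1, 1:-1]


class ReLU(Layer):
    def forward(self, x, train=True):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, grad):
        return grad * self._mask


class MaxPool2(Layer):
    def forward(self, x, train=True):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        flat = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx = idx
            self._shape = x.shape
        return out

    def backward(self, grad):
        n, c, h, w = self._shape
        dflat = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(dflat, self._idx[..., None], grad[..., None], axis=-1)
        dx = dflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dx.reshape(n, c, h, w)


class GlobalAvgPool(Layer):
    def forward(self, x, train=True):
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None] / (h * w), (n, c, h, w)).copy()


class Dense(Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / cin)
        self.w = rng.normal(0.0, scale, size=(cout, cin))
        self.b = np.zeros(cout)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self.params = [[self.w, self.gw], [self.b, self.gb]]

    def forward(self, x, train=True):
        if train:
            self._x = x
        return x @ self.w.T + self.b

    def backward(self, grad):
        self.gw += grad.T @ self._x
        self.gb += grad.sum(axis=0)
        return grad @ self.w


class ResidualBlock(Layer):
    """conv-relu-conv with identity skip, then relu."""

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.c1 = Conv3x3(channels, channels, rng)
        self.r1 = ReLU()
        self.c2 = Conv3x3(channels, channels, rng)
        self.r2 = ReLU()
        self.params = self.c1.params + self.c2.params

    def forward(self, x, train=True):
        out = self.c2.forward(self.r1.forward(self.c1.forward(x, train), train), train)
        return self.r2.forward(out + x, train)

    def backward(self, grad):
        g = self.r2.backward(grad)
        dx = self.c1.backward(self.r1.backward(self.c2.backward(g)))
        return dx + g


# --------------------------------------------------------------------------
# network
# --------------------------------------------------------------------------
def build_layers(arch: str, n_classes: int, rng: np.random.Generator,
                 channels=(8, 16, 32)) -> list[Layer]:
    c1, c2, c3 = channels
    if arch == "small_resnet":
        return [
            Conv3x3(1, c1, rng), ReLU(), MaxPool2(),
            ResidualBlock(c1, rng), MaxPool2(),
            Conv3x3(c1, c2, rng), ReLU(),
            ResidualBlock(c2, rng), MaxPool2(),
            Conv3x3(c2, c3, rng), ReLU(),
            ResidualBlock(c3, rng),
            GlobalAvgPool(), Dense(c3, n_classes, rng),
        ]
    if arch == "tiny":
        return [
            Conv3x3(1, c1, rng), ReLU(), MaxPool2(),
            Conv3x3(c1, c2, rng), ReLU(), MaxPool2(),
            GlobalAvgPool(), Dense(c2, n_classes, rng),
        ]
    raise ValueError(f"unknown architecture {arch!r}")


@dataclass
class TrainConfig:
    arch: str = "small_resnet"
    epochs: int = 8
    lr: float = 3e-3
    batch_size: int = 32
    seed: int = 0
    channels: tuple[int, int, int] = (8, 16, 32)


class SoftmaxClassifier:
    """CNN classifier over (N, H, W) images with arbitrary hashable labels."""

    def __init__(self, classes: list, config: TrainConfig):
        self.classes = list(classes)
        self.config = config
        self._rng = np.random.default_rng(config.seed)
        self.layers = build_layers(config.arch, len(self.classes), self._rng,
                                   config.channels)
        self._adam_state = None
        self.history: list[float] = []

    # --- forward/backward -------------------------------------------------
    def _forward(self, x, train=True):
        out = x[:, None, :, :]  # add channel axis
        for layer in self.layers:
            out = layer.forward(out, train=train)
        return out

    def _zero_grads(self):
        for layer in self.layers:
            for _, g in layer.params:
                g[...] = 0.0

    def _adam_step(self, t):
        cfg = self.config
        b1, b2, eps = 0.9, 0.999, 1e-8
        if self._adam_state is None:
            self._adam_state = [
                (np.zeros_like(p), np.zeros_like(p))
                for layer in self.layers for p, _ in layer.params
            ]
        i = 0
        for layer in self.layers:
            for p, g in layer.params:
                m, v = self._adam_state[i]
                m[...] = b1 * m + (1 - b1) * g
                v[...] = b2 * v + (1 - b2) * g * g
                mh = m / (1 - b1 ** t)
                vh = v / (1 - b2 ** t)
                p -= cfg.lr * mh / (np.sqrt(vh) + eps)
                i += 1

    # --- public API -------------------------------------------------------
    def fit(self, x: np.ndarray, labels: list) -> "SoftmaxClassifier":
        cfg = self.config
        y = np.array([self.classes.index(l) for l in labels])
        n = len(y)
        counts = np.bincount(y, minlength=len(self.classes)).astype(float)
        weights = np.where(counts > 0, n / (len(self.classes) * np.maximum(counts, 1)), 0.0)
        t = 0
        for _ in range(cfg.epochs):
            order = self._rng.permutation(n)
            epoch_loss = 0.0
            for s in range(0, n, cfg.batch_size):
                idx = order[s:s + cfg.batch_size]
                xb, yb = x[idx], y[idx]
                self._zero_grads()
                logits = self._forward(xb, train=True)
                logits = logits - logits.max(axis=1, keepdims=True)
                p = np.exp(logits)
                p /= p.sum(axis=1, keepdims=True)
                wb = weights[yb]
                wsum = wb.sum()
                eps = 1e-12
                epoch_loss += float(-(wb * np.log(p[np.arange(len(yb)), yb] + eps)).sum())
                grad = p.copy()
                grad[np.arange(len(yb)), yb] -= 1.0
                grad *= wb[:, None] / max(wsum, eps)
                for layer in reversed(self.layers):
                    grad = layer.backward(grad)
                t += 1
                self._adam_step(t)
            self.history.append(epoch_loss / n)
        return self

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = []
        for s in range(0, len(x), batch_size):
            logits = self._forward(x[s:s + batch_size], train=False)
            logits = logits - logits.max(axis=1, keepdims=True)
            p = np.exp(logits)
            out.append(p / p.sum(axis=1, keepdims=True))
        return np.concatenate(out, axis=0)

    def predict(self, x: np.ndarray) -> list:
        idx = self.predict_proba(x).argmax(axis=1)
        return [self.classes[i] for i in idx]
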