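"""A small residual convolutional classifier in pure numpy.

No deep-learning framework is assumed: convolution is im2col + matmul,
batch normalization and the residual blocks are implemented with their
standard backward formulas, and optimization is stochastic gradient
descent with momentum under an externally supplied learning-rate
schedule.  The default configuration — three stride-2 conv stages each
followed by one residual block, global average pooling and a 3-way
softmax head — has roughly 120k parameters, which trains in minutes on
one CPU at desk-scale image sizes.

Layout is NHWC throughout; all parameters are float32.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-5


class Conv2D:
    """3x3 'same' convolution with configurable stride (He-initialized)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, stride: int = 1, k: int = 3):
        self.k, self.stride, self.cin, self.cout = k, stride, cin, cout
        scale = np.sqrt(2.0 / (k * k * cin))
        self.W = (rng.standard_normal((k * k * cin, cout)) * scale).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.params = [("W", self.W), ("b", self.b)]
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k), axis=(1, 2))
        win = win[:, :: self.stride, :: self.stride]  # (n, ho, wo, c, k, k)
        ho, wo = win.shape[1], win.shape[2]
        cols = np.ascontiguousarray(win).reshape(n * ho * wo, c * self.k * self.k)
        y = (cols @ self.W + self.b).reshape(n, ho, wo, self.cout)
        self._cache = (cols, x.shape, (ho, wo))
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, xshape, (ho, wo) = self._cache
        n, h, w, c = xshape
        dflat = dout.reshape(n * ho * wo, self.cout).astype(np.float32)
        self.dW = cols.T @ dflat
        self.db = dflat.sum(axis=0)
        dcols = dflat @ self.W.T  # (n*ho*wo, c*k*k)
        dwin = dcols.reshape(n, ho, wo, c, self.k, self.k)
        p = self.k // 2
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=np.float32)
        s = self.stride
        for ki in range(self.k):
            for kj in range(self.k):
                dxp[:, ki : ki + (ho - 1) * s + 1 : s, kj : kj + (wo - 1) * s + 1 : s, :] += dwin[
                    :, :, :, :, ki, kj
                ]
        return dxp[:, p : p + h, p : p + w, :]

    def grads(self):
        return [self.dW, self.db]


class BatchNorm:
    def __init__(self, c: int, momentum: float = 0.9):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.params = [("gamma", self.gamma), ("beta", self.beta)]
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean[:] = m * self.running_mean + (1 - m) * mean
            self.running_var[:] = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + _EPS)
        xhat = (x - mean) * inv_std
        self._cache = (xhat, inv_std, axes, x.shape)
        return (self.gamma * xhat + self.beta).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std, axes, shape = self._cache
        m = float(np.prod([shape[a] for a in axes]))
        self.dgamma = (dout * xhat).sum(axis=axes)
        self.dbeta = dout.sum(axis=axes)
        dxhat = dout * self.gamma
        dx = (inv_std / m) * (
            m * dxhat - dxhat.sum(axis=axes) - xhat * (dxhat * xhat).sum(axis=axes)
        )
        return dx.astype(np.float32)

    def grads(self):
        return [self.dgamma, self.dbeta]


class ReLU:
    params: list = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask

    def grads(self):
        return []


class Dense:
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / cin)
        self.W = (rng.standard_normal((cin, cout)) * scale).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.params = [("W", self.W), ("b", self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T

    def grads(self):
        return [self.dW, self.db]


class ResidualBlock:
    """conv-bn-relu-conv-bn with an identity skip, then relu."""

    def __init__(self, c: int, rng: np.random.Generator):
        self.conv1, self.bn1, self.relu1 = Conv2D(c, c, rng), BatchNorm(c), ReLU()
        self.conv2, self.bn2 = Conv2D(c, c, rng), BatchNorm(c)
        self.relu_out = ReLU()
        self.layers = [self.conv1, self.bn1, self.relu1, self.conv2, self.bn2]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        y = x
        for layer in self.layers:
            y = layer.forward(y, train)
        return self.relu_out.forward(y + x, train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.relu_out.backward(dout)
        dskip = d
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return d + dskip

    def sublayers(self):
        return self.layers


class ResNetClassifier:
    """Stages of (stride-2 conv, bn, relu, residual block), then global
    average pooling and a softmax head."""

    def __init__(
        self,
        input_shape: tuple[int, int, int],
        n_classes: int = 3,
        widths: tuple[int, ...] = (16, 32, 64),
        seed: int = 0,
    ):
        self.input_shape = tuple(input_shape)
        self.n_classes = n_classes
        self.widths = tuple(widths)
        rng = np.random.default_rng(seed)
        layers: list = []
        cin = input_shape[2]
        for wdt in widths:
            layers += [Conv2D(cin, wdt, rng, stride=2), BatchNorm(wdt), ReLU(), ResidualBlock(wdt, rng)]
            cin = wdt
        self.layers = layers
        self.head = Dense(cin, n_classes, rng)

    # -- plumbing ---------------------------------------------------------
    def _flat_layers(self):
        for layer in self.layers:
            if isinstance(layer, ResidualBlock):
                yield from layer.sublayers()
            else:
                yield layer
        yield self.head

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self._flat_layers() for _, p in layer.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self._flat_layers() for g in layer.grads()]

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self._flat_layers()):
            for name, p in layer.params:
                out[f"l{i}_{name}"] = p
            if isinstance(layer, BatchNorm):
                out[f"l{i}_running_mean"] = layer.running_mean
                out[f"l{i}_running_var"] = layer.running_var
        return out

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for key, arr in self.state_arrays().items():
            arr[...] = state[key]

    def get_state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.state_arrays().items()}

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    # -- compute ----------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = x.astype(np.float32)
        for layer in self.layers:
            y = layer.forward(y, train)
        self._pool_shape = y.shape
        pooled = y.mean(axis=(1, 2))
        return self.head.forward(pooled, train)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        n, h, w, c = self._pool_shape
        d = np.broadcast_to(d[:, None, None, :] / (h * w), self._pool_shape).astype(np.float32)
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, train=False))


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    n = len(labels)
    probs = softmax(logits)
    loss = -float(np.log(probs[np.arange(n), labels] + 1e-12).mean())
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, (grad / n).astype(np.float32)


class SGD:
    """SGD with momentum and global-norm gradient clipping (clipping keeps
    the large warm-restart learning rate stable without a framework's
    fused batch-norm numerics)."""

    def __init__(self, model: ResNetClassifier, momentum: float = 0.9, clip_norm: float = 5.0):
        self.model = model
        self.momentum = momentum
        self.clip_norm = clip_norm
        self.velocity = [np.zeros_like(p) for p in model.parameters()]

    def step(self, lr: float) -> None:
        params = self.model.parameters()
        grads = self.model.gradients()
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g ** 2).sum()) for g in grads))
            if total > self.clip_norm:
                grads = [g * (self.clip_norm / total) for g in grads]
        for p, g, v in zip(params, grads, self.velocity):
            v[...] = self.momentum * v - lr * g
            p += v
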