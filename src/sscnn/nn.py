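"""Minimal numpy neural-network kernels: 1-D convolution, dense, ReLU,
inverted dropout, softmax cross-entropy, and SGD with momentum and
hyperbolic learning-rate decay.

Shapes follow the (batch, positions, channels) convention.  Convolutions use
valid border treatment: an input of spatial length L with kernel width k
yields L - k + 1 output positions.

Everything is seeded through ``numpy.random.Generator`` objects so training
runs are bit-reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "Conv1D", "Dense", "ReLU", "Dropout", "Flatten",
    "Sequential", "softmax", "SGD",
]

_DTYPE = np.float32


class Layer:
    """Base layer: forward/backward plus flat parameter access."""

    def forward(self, x: np.ndarray, train: bool, rng) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def params(self) -> list:
        return []

    @property
    def grads(self) -> list:
        return []

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params)


class Conv1D(Layer):
    """Valid-border 1-D convolution over the position axis.

    Weights have shape (kernel_width, in_channels, out_channels); the output
    at position t is ``sum_i x[t + i] @ W[i] + b``.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_width: int,
                 rng: np.random.Generator):
        fan_in = in_channels * kernel_width
        limit = np.sqrt(6.0 / fan_in)  # He-uniform
        self.W = rng.uniform(-limit, limit,
                             (kernel_width, in_channels, out_channels)).astype(_DTYPE)
        self.b = np.zeros(out_channels, dtype=_DTYPE)
        self.k = kernel_width
        self._x: np.ndarray | None = None
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train, rng):
        self._x = x
        N, L, _ = x.shape
        Lout = L - self.k + 1
        if Lout < 1:
            raise ValueError(f"input length {L} shorter than kernel {self.k}")
        out = np.broadcast_to(self.b, (N, Lout, self.b.size)).copy()
        for i in range(self.k):
            out += x[:, i:i + Lout, :] @ self.W[i]
        return out

    def backward(self, dout):
        x = self._x
        N, L, _ = x.shape
        Lout = dout.shape[1]
        self.db = dout.sum(axis=(0, 1))
        dx = np.zeros_like(x)
        for i in range(self.k):
            xs = x[:, i:i + Lout, :]
            self.dW[i] = np.tensordot(xs, dout, axes=([0, 1], [0, 1]))
            dx[:, i:i + Lout, :] += dout @ self.W[i].T
        return dx

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / in_features)
        self.W = rng.uniform(-limit, limit, (in_features, out_features)).astype(_DTYPE)
        self.b = np.zeros(out_features, dtype=_DTYPE)
        self._x: np.ndarray | None = None
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]


class ReLU(Layer):
    def forward(self, x, train, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout: active only during training, identity at inference."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._mask = None

    def forward(self, x, train, rng):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(_DTYPE) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class Flatten(Layer):
    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Sequential:
    """A feed-forward stack ending in logits; softmax applied on demand."""

    def __init__(self, layers: list):
        self.layers = layers

    def forward(self, x, train: bool = False, rng: np.random.Generator | None = None):
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def predict_proba(self, x, batch_size: int = 4096) -> np.ndarray:
        out = []
        for i in range(0, x.shape[0], batch_size):
            out.append(softmax(self.forward(x[i:i + batch_size], train=False)))
        return np.concatenate(out, axis=0)

    def loss_and_grad(self, x, y, rng) -> tuple:
        """Mean categorical cross-entropy and accuracy; backprops gradients."""
        logits = self.forward(x, train=True, rng=rng)
        probs = softmax(logits)
        n = x.shape[0]
        eps = np.finfo(_DTYPE).tiny
        loss = -np.log(probs[np.arange(n), y] + eps).mean()
        acc = float((probs.argmax(axis=1) == y).mean())
        dlogits = probs
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        dout = dlogits.astype(_DTYPE)
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return float(loss), acc

    @property
    def params(self) -> list:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list:
        return [g for layer in self.layers for g in layer.grads]

    @property
    def n_params(self) -> int:
        return sum(layer.n_params for layer in self.layers)

    def get_weights(self) -> list:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list) -> None:
        for p, w in zip(self.params, weights, strict=True):
            p[...] = w


class SGD:
    """Stochastic gradient descent with classical momentum.

    The effective learning rate decays hyperbolically with the update count:
    ``lr_t = lr / (1 + decay * t)`` — the schedule implied by a fixed decay
    constant of ``lr / n_epochs``.
    """

    def __init__(self, params: list, lr: float = 0.01, momentum: float = 0.9,
                 decay: float = 0.0, nesterov: bool = False):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.decay = decay
        self.nesterov = nesterov
        self.iterations = 0
        self.velocities = [np.zeros_like(p) for p in params]

    @property
    def current_lr(self) -> float:
        return self.lr / (1.0 + self.decay * self.iterations)

    def step(self, grads: list) -> None:
        lr = self.current_lr
        for p, g, v in zip(self.params, grads, self.velocities, strict=True):
            v *= self.momentum
            v -= lr * g
            if self.nesterov:
                p += self.momentum * v - lr * g
            else:
                p += v
        self.iterations += 1
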