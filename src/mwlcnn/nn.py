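"""Minimal feedforward network engine: layers, loss and optimizers.

Implements exactly what the workload classifiers need — valid-padding
stride-1 2-D convolution, average pooling, fully-connected layers, ReLU and
a softmax cross-entropy head — as plain numpy with analytic gradients.
Everything is float64 and deterministic given the initialization seed, so
training runs are bit-reproducible and gradients can be checked numerically.

Optimizers: Nesterov momentum (NM), Adagrad, Adadelta and Adam, each with
per-parameter state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv2D",
    "ReLU",
    "AvgPool2D",
    "Flatten",
    "Dense",
    "SoftmaxCrossEntropy",
    "Network",
    "OptimizerConfig",
    "make_optimizer",
    "DivergenceError",
]


class Layer:
    """A differentiable module with optional parameters."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


class Conv2D(Layer):
    """Valid-padding, stride-1 2-D convolution on (N, C, H, W) inputs."""

    def __init__(self, in_channels: int, out_channels: int, kh: int, kw: int, rng: np.random.Generator):
        super().__init__()
        # He-style uniform fan-in scaling; keeps signal variance through ReLUs
        fan_in = in_channels * kh * kw
        bound = np.sqrt(6.0 / fan_in)
        self.w = rng.uniform(-bound, bound, size=(out_channels, in_channels, kh, kw))
        self.b = rng.uniform(-bound, bound, size=out_channels)
        self.kh, self.kw = kh, kw
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[2] < self.kh or x.shape[3] < self.kw:
            raise ValueError(
                f"input {x.shape[2]}x{x.shape[3]} smaller than kernel {self.kh}x{self.kw}"
            )
        # (N, C, H', W', kh, kw) view; contiguous copy keeps einsum fast
        self._cols = sliding_window_view(x, (self.kh, self.kw), axis=(2, 3))
        self._x_shape = x.shape
        out = np.einsum("nchwij,ocij->nohw", self._cols, self.w, optimize=True)
        return out + self.b[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads[0][...] = np.einsum("nchwij,nohw->ocij", self._cols, dy, optimize=True)
        self.grads[1][...] = dy.sum(axis=(0, 2, 3))
        dx = np.zeros(self._x_shape)
        hp, wp = dy.shape[2], dy.shape[3]
        for i in range(self.kh):
            for j in range(self.kw):
                dx[:, :, i : i + hp, j : j + wp] += np.einsum(
                    "nohw,oc->nchw", dy, self.w[:, :, i, j], optimize=True
                )
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class AvgPool2D(Layer):
    """Non-overlapping average pooling; trailing rows/columns that do not
    fill a window are dropped (floor semantics)."""

    def __init__(self, ph: int, pw: int):
        super().__init__()
        self.ph, self.pw = ph, pw

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        ho, wo = h // self.ph, w // self.pw
        if ho < 1 or wo < 1:
            raise ValueError(f"input {h}x{w} too small for pool {self.ph}x{self.pw}")
        self._x_shape = x.shape
        xc = x[:, :, : ho * self.ph, : wo * self.pw]
        return xc.reshape(n, c, ho, self.ph, wo, self.pw).mean(axis=(3, 5))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, ho, wo = dy.shape
        dx = np.zeros(self._x_shape)
        spread = np.repeat(np.repeat(dy, self.ph, axis=2), self.pw, axis=3)
        dx[:, :, : ho * self.ph, : wo * self.pw] = spread / (self.ph * self.pw)
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        bound = np.sqrt(6.0 / in_features)
        self.w = rng.uniform(-bound, bound, size=(in_features, out_features))
        self.b = rng.uniform(-bound, bound, size=out_features)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.w.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class SoftmaxCrossEntropy:
    """Softmax posterior + mean cross-entropy loss head."""

    def forward(self, logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
        p = softmax(logits)
        n = logits.shape[0]
        eps = np.finfo(float).tiny
        loss = -np.log(p[np.arange(n), targets] + eps).mean()
        grad = p.copy()
        grad[np.arange(n), targets] -= 1.0
        return float(loss), grad / n


class DivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""

    def __init__(self, epoch: int):
        super().__init__(f"non-finite loss at training epoch {epoch}")
        self.epoch = epoch


class Network:
    """A sequential stack of layers with a softmax cross-entropy head."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers
        self.head = SoftmaxCrossEntropy()

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x))

    def loss_and_grad(self, x: np.ndarray, y: np.ndarray) -> float:
        """Forward + backward pass; leaves gradients in ``self.grads``."""
        loss, dy = self.head.forward(self.forward(x), y)
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return loss

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params, state):
            p[...] = s


@dataclass(frozen=True)
class OptimizerConfig:
    """Algorithm choice and hyperparameters for network training.

    Defaults follow the configurations compared in the study: learning rate
    1e-4 for NM/Adagrad/Adam, momentum 0.9 for NM, Adam decay rates
    (0.9, 0.999).  Adadelta uses its standard decay 0.95 / epsilon 1e-6 and
    takes no learning rate.
    """

    algorithm: str = "nm"
    learning_rate: float = 1e-4
    momentum: float = 0.9
    beta1: float = 0.9
    beta2: float = 0.999
    rho: float = 0.95
    epsilon: float = 1e-8
    adadelta_epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if self.algorithm not in ("nm", "adagrad", "adadelta", "adam"):
            raise ValueError(f"unknown optimizer {self.algorithm!r}")
        if self.learning_rate < 0:
            raise ValueError("learning rate must be nonnegative")


class _Optimizer:
    def __init__(self, params: list[np.ndarray], config: OptimizerConfig):
        self.params = params
        self.c = config

    def step(self, grads: list[np.ndarray]) -> None:  # pragma: no cover - abstract
        raise NotImplementedError


class _NesterovMomentum(_Optimizer):
    def __init__(self, params, config):
        super().__init__(params, config)
        self.v = [np.zeros_like(p) for p in params]

    def step(self, grads):
        mu, lr = self.c.momentum, self.c.learning_rate
        for p, g, v in zip(self.params, grads, self.v):
            v *= mu
            v += g
            p -= lr * (g + mu * v)


class _Adagrad(_Optimizer):
    def __init__(self, params, config):
        super().__init__(params, config)
        self.acc = [np.zeros_like(p) for p in params]

    def step(self, grads):
        lr, eps = self.c.learning_rate, self.c.epsilon
        for p, g, a in zip(self.params, grads, self.acc):
            a += g * g
            p -= lr * g / (np.sqrt(a) + eps)


class _Adadelta(_Optimizer):
    def __init__(self, params, config):
        super().__init__(params, config)
        self.eg = [np.zeros_like(p) for p in params]
        self.ed = [np.zeros_like(p) for p in params]

    def step(self, grads):
        rho, eps = self.c.rho, self.c.adadelta_epsilon
        for p, g, eg, ed in zip(self.params, grads, self.eg, self.ed):
            eg *= rho
            eg += (1 - rho) * g * g
            dx = -np.sqrt(ed + eps) / np.sqrt(eg + eps) * g
            ed *= rho
            ed += (1 - rho) * dx * dx
            p += dx


class _Adam(_Optimizer):
    def __init__(self, params, config):
        super().__init__(params, config)
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        c = self.c
        self.t += 1
        bc1 = 1 - c.beta1**self.t
        bc2 = 1 - c.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= c.beta1
            m += (1 - c.beta1) * g
            v *= c.beta2
            v += (1 - c.beta2) * g * g
            p -= c.learning_rate * (m / bc1) / (np.sqrt(v / bc2) + c.epsilon)


_OPTIMIZERS = {
    "nm": _NesterovMomentum,
    "adagrad": _Adagrad,
    "adadelta": _Adadelta,
    "adam": _Adam,
}


def make_optimizer(params: list[np.ndarray], config: OptimizerConfig) -> _Optimizer:
    return _OPTIMIZERS[config.algorithm](params, config)
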