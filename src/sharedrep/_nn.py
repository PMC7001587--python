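"""Minimal dense-network building blocks.

Dense layers with sigmoid / relu / softmax / linear activations, Glorot
initialization, the AdaDelta update rule (accumulated squared gradients
and updates, rho=0.95, eps=1e-6, step size 1.0), binary and categorical
cross-entropy. float32 throughout; everything is seeded and
deterministic for a fixed platform.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32
_EPS = 1e-7


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Dense:
    """A densely connected layer with a pointwise activation.

    ``activation`` is one of 'sigmoid', 'relu', 'linear', 'softmax'
    (softmax only as an output layer paired with categorical
    cross-entropy, whose combined gradient is (y - t)).
    """

    def __init__(self, n_in: int, n_out: int, activation: str,
                 rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, (n_in, n_out)).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.activation = activation
        self._x: np.ndarray | None = None
        self._a: np.ndarray | None = None
        # AdaDelta accumulators
        self._Eg2 = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self._Ed2 = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        z = x @ self.W + self.b
        if self.activation == "sigmoid":
            a = sigmoid(z)
        elif self.activation == "relu":
            a = np.maximum(z, 0.0)
        elif self.activation == "softmax":
            a = softmax(z)
        elif self.activation == "linear":
            a = z
        else:  # pragma: no cover - guarded at build time
            raise ValueError(f"unknown activation {self.activation!r}")
        if cache:
            self._x, self._a = x, a
        return a

    def backward(self, grad_a: np.ndarray, *, grad_is_dz: bool = False,
                 rho: float = 0.95, eps: float = 1e-6, lr: float = 1.0) -> np.ndarray:
        """Backpropagate, apply the AdaDelta update, return grad wrt input."""
        x, a = self._x, self._a
        if grad_is_dz or self.activation == "linear":
            dz = grad_a
        elif self.activation == "sigmoid":
            dz = grad_a * a * (1.0 - a)
        elif self.activation == "relu":
            dz = grad_a * (a > 0)
        else:
            raise ValueError("softmax backward requires grad_is_dz=True")
        gW = x.T @ dz
        gb = dz.sum(axis=0)
        grad_x = dz @ self.W.T
        for p, g, Eg2, Ed2 in ((self.W, gW, self._Eg2[0], self._Ed2[0]),
                               (self.b, gb, self._Eg2[1], self._Ed2[1])):
            Eg2 *= rho
            Eg2 += (1.0 - rho) * g * g
            step = -np.sqrt(Ed2 + eps) / np.sqrt(Eg2 + eps) * g
            Ed2 *= rho
            Ed2 += (1.0 - rho) * step * step
            p += lr * step
        return grad_x

    def checksum(self) -> float:
        return float(np.abs(self.W).sum() + np.abs(self.b).sum())


def forward_chain(layers: list[Dense], x: np.ndarray, cache: bool = True) -> np.ndarray:
    for layer in layers:
        x = layer.forward(x, cache=cache)
    return x


def backward_chain(layers: list[Dense], grad: np.ndarray, *,
                   first_grad_is_dz: bool = False) -> np.ndarray:
    for i, layer in enumerate(reversed(layers)):
        grad = layer.backward(grad, grad_is_dz=(first_grad_is_dz and i == 0))
    return grad


def binary_cross_entropy(y: np.ndarray, t: np.ndarray) -> float:
    """Binary cross-entropy summed over features, averaged over the
    batch (nats). The per-sample sum reduction keeps reconstruction
    gradients well scaled for AdaDelta's normalization."""
    y = np.clip(y, _EPS, 1.0 - _EPS)
    return float(-(t * np.log(y) + (1.0 - t) * np.log(1.0 - y)).sum(axis=1).mean())


def bce_grad_dz(y: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Gradient of the BCE loss wrt the pre-activation of a sigmoid output."""
    return (y - t) / np.float32(y.shape[0])


def categorical_cross_entropy(y: np.ndarray, t_onehot: np.ndarray) -> float:
    y = np.clip(y, _EPS, 1.0)
    return float(-(t_onehot * np.log(y)).sum(axis=1).mean())


def cce_grad_dz(y: np.ndarray, t_onehot: np.ndarray) -> np.ndarray:
    """Gradient of mean categorical CE wrt softmax pre-activation."""
    return (y - t_onehot) / np.float32(y.shape[0])


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((len(labels), n_classes), dtype=DTYPE)
    out[np.arange(len(labels)), labels] = 1.0
    return out
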