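"""Minimal feed-forward neural-network primitives with manual backprop.

Everything downstream (VAE backbones, the conditional generator, the
top-down modulator, the recurrent context network) is built from the
pieces here: a `Linear` layer with cached activations, a plain `MLP`,
a `GRUCell`, softmax/cross-entropy helpers and an `Adam` optimizer.
All randomness flows through an explicit `numpy.random.Generator`, so
every training routine in the package is bit-deterministic given its
seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Param",
    "Linear",
    "MLP",
    "GRUCell",
    "Adam",
    "relu",
    "sigmoid",
    "softmax",
    "cross_entropy",
    "params_digest",
]


@dataclass
class Param:
    """A trainable array and its accumulated gradient."""

    v: np.ndarray
    g: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.v = np.ascontiguousarray(self.v, dtype=np.float64)
        self.g = np.zeros_like(self.v)

    def zero_grad(self) -> None:
        self.g[...] = 0.0


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean CE loss and gradient w.r.t. logits for integer labels."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = -float(np.mean(np.log(p[np.arange(n), labels] + eps)))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


class Linear:
    """y = x @ W (+ b). Caches the last input for backward."""

    def __init__(
        self,
        n_in: int,
        n_out: int,
        rng: np.random.Generator,
        bias: bool = True,
        scale: float | None = None,
    ) -> None:
        if scale is None:
            scale = np.sqrt(2.0 / n_in)  # He init, ReLU-friendly
        self.W = Param(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out)) if bias else None
        self._x: np.ndarray | None = None

    @property
    def params(self) -> list[Param]:
        return [self.W] + ([self.b] if self.b is not None else [])

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        y = x @ self.W.v
        if self.b is not None:
            y = y + self.b.v
        return y

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        assert self._x is not None, "forward() must run before backward()"
        self.W.g += self._x.T @ gy
        if self.b is not None:
            self.b.g += gy.sum(axis=0)
        return gy @ self.W.v.T


class MLP:
    """Fully connected net with ReLU between layers and a linear head."""

    def __init__(
        self,
        dims: list[int],
        rng: np.random.Generator,
        bias: bool = True,
    ) -> None:
        self.layers = [
            Linear(dims[i], dims[i + 1], rng, bias=bias) for i in range(len(dims) - 1)
        ]
        self._pre: list[np.ndarray] = []

    @property
    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._pre = []
        for i, layer in enumerate(self.layers):
            x = layer.forward(x)
            if i < len(self.layers) - 1:
                self._pre.append(x)
                x = relu(x)
        return x

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for i in range(len(self.layers) - 1, -1, -1):
            if i < len(self.layers) - 1:
                gy = gy * (self._pre[i] > 0)
            gy = self.layers[i].backward(gy)
        return gy


class GRUCell:
    """Standard gated recurrent unit.

    r = sig(x Wr + h Ur + br);  z = sig(x Wz + h Uz + bz)
    n = tanh(x Wn + r * (h Un) + bn);  h' = (1 - z) * n + z * h
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator) -> None:
        s_in = np.sqrt(1.0 / n_in)
        s_h = np.sqrt(1.0 / n_hidden)
        self.n_hidden = n_hidden
        self.Wr = Param(rng.normal(0, s_in, (n_in, n_hidden)))
        self.Wz = Param(rng.normal(0, s_in, (n_in, n_hidden)))
        self.Wn = Param(rng.normal(0, s_in, (n_in, n_hidden)))
        self.Ur = Param(rng.normal(0, s_h, (n_hidden, n_hidden)))
        self.Uz = Param(rng.normal(0, s_h, (n_hidden, n_hidden)))
        self.Un = Param(rng.normal(0, s_h, (n_hidden, n_hidden)))
        self.br = Param(np.zeros(n_hidden))
        self.bz = Param(np.zeros(n_hidden))
        self.bn = Param(np.zeros(n_hidden))

    @property
    def params(self) -> list[Param]:
        return [self.Wr, self.Wz, self.Wn, self.Ur, self.Uz, self.Un,
                self.br, self.bz, self.bn]

    def forward(self, x: np.ndarray, h: np.ndarray) -> tuple[np.ndarray, dict]:
        r = sigmoid(x @ self.Wr.v + h @ self.Ur.v + self.br.v)
        z = sigmoid(x @ self.Wz.v + h @ self.Uz.v + self.bz.v)
        hn = h @ self.Un.v
        n = np.tanh(x @ self.Wn.v + r * hn + self.bn.v)
        h_new = (1.0 - z) * n + z * h
        cache = {"x": x, "h": h, "r": r, "z": z, "n": n, "hn": hn}
        return h_new, cache

    def backward(self, gh_new: np.ndarray, cache: dict) -> tuple[np.ndarray, np.ndarray]:
        """Returns (gx, gh) for one step given d(loss)/d(h')."""
        x, h, r, z, n, hn = (cache[k] for k in ("x", "h", "r", "z", "n", "hn"))
        gn = gh_new * (1.0 - z)
        gz = gh_new * (h - n)
        gh = gh_new * z

        gn_pre = gn * (1.0 - n * n)
        self.Wn.g += x.T @ gn_pre
        self.bn.g += gn_pre.sum(axis=0)
        gr = gn_pre * hn
        ghn = gn_pre * r
        self.Un.g += h.T @ ghn
        gh += ghn @ self.Un.v.T
        gx = gn_pre @ self.Wn.v.T

        gz_pre = gz * z * (1.0 - z)
        self.Wz.g += x.T @ gz_pre
        self.Uz.g += h.T @ gz_pre
        self.bz.g += gz_pre.sum(axis=0)
        gx += gz_pre @ self.Wz.v.T
        gh += gz_pre @ self.Uz.v.T

        gr_pre = gr * r * (1.0 - r)
        self.Wr.g += x.T @ gr_pre
        self.Ur.g += h.T @ gr_pre
        self.br.g += gr_pre.sum(axis=0)
        gx += gr_pre @ self.Wr.v.T
        gh += gr_pre @ self.Ur.v.T
        return gx, gh


class Adam:
    """Adam with the usual bias correction (beta1=0.9, beta2=0.999)."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.v) for p in params]
        self.s = [np.zeros_like(p.v) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, s in zip(self.params, self.m, self.s):
            m *= self.b1
            m += (1.0 - self.b1) * p.g
            s *= self.b2
            s += (1.0 - self.b2) * p.g * p.g
            p.v -= self.lr * (m / b1t) / (np.sqrt(s / b2t) + self.eps)


def params_digest(params: list[Param]) -> str:
    """SHA-256 over parameter bytes; used for freeze-conservation checks."""
    h = hashlib.sha256()
    for p in params:
        h.update(np.ascontiguousarray(p.v).tobytes())
    return h.hexdigest()
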