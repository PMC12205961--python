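"""Two-compartment network core.

A population of n model pyramidal neurons receives a feed-forward
(basal) drive ``b = f(x)`` from a frozen pretrained encoder and a
top-down (apical) drive ``a = g(c ⊕ Uσ(b))`` from a context network.
The firing rate combines the two compartments multiplicatively,

    h = σ(b) ⊙ (σ(a) + 1),      σ = ReLU,

so apical input acts as a thresholded gain on already-active neurons:
it can amplify but never create activity (h_i = 0 whenever b_i <= 0),
and with a <= 0 everywhere the population output is exactly σ(b).
The latent read ``μ = U h`` uses the frozen final linear map of the
pretrained encoder. An additive rule (σ(b) + σ(a)) and a
single-compartment variant (context summed into the basal
pre-activation before one shared nonlinearity) are provided as
ablations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .glyphs import IMG_SIZE, LabeledImage, stack
from .nnops import (Adam, GRUCell, Linear, MLP, cross_entropy, params_digest,
                    relu, sigmoid)

Rule = Literal["hadamard", "additive", "single_compartment"]

__all__ = [
    "BackboneEncoder",
    "Projection",
    "CompartmentState",
    "ContextVector",
    "TopDownNet",
    "ContextGRU",
    "Readout",
    "pretrain_backbone",
    "train_readout",
    "encode_basal",
    "integrate",
    "project_mu",
    "compute_apical",
    "onehot_context",
    "soften_context",
    "train_context_gru",
    "temporal_context",
    "forward",
    "forward_single",
    "extended_categories",
    "pair_category_index",
]


# ---------------------------------------------------------------------------
# backbone (pretrained frozen VAE encoder) and projection
# ---------------------------------------------------------------------------

@dataclass
class Projection:
    """Frozen linear latent read μ = U h (no bias)."""

    U: np.ndarray  # (latent_dim, n_units)

    def project(self, h: np.ndarray) -> np.ndarray:
        return h @ self.U.T


class BackboneEncoder:
    """MLP variational autoencoder; the encoder's penultimate
    pre-activation is the basal vector ``b`` and its final linear map to
    the posterior mean is the projection ``U``."""

    def __init__(self, n_units: int, latent_dim: int, hidden: int,
                 rng: np.random.Generator) -> None:
        self.n_units = n_units
        self.latent_dim = latent_dim
        d = IMG_SIZE * IMG_SIZE
        self.enc1 = Linear(d, hidden, rng)
        self.enc2 = Linear(hidden, n_units, rng)
        self.mu_head = Linear(n_units, latent_dim, rng, bias=False)
        self.logvar_head = Linear(n_units, latent_dim, rng)
        self.dec = MLP([latent_dim, hidden, d], rng)
        self.frozen = False
        self.elbo_history: list[float] = []

    @property
    def params(self):
        return (self.enc1.params + self.enc2.params + self.mu_head.params
                + self.logvar_head.params + self.dec.params)

    @property
    def encoder_params(self):
        return self.enc1.params + self.enc2.params + self.mu_head.params

    def digest(self) -> str:
        return params_digest(self.encoder_params)

    @property
    def projection(self) -> Projection:
        return Projection(U=self.mu_head.W.v.T.copy())

    def basal(self, X: np.ndarray) -> np.ndarray:
        """Pre-activation of the penultimate layer, b = f(x)."""
        a1 = relu(X @ self.enc1.W.v + self.enc1.b.v)
        return a1 @ self.enc2.W.v + self.enc2.b.v

    def latent(self, X: np.ndarray) -> np.ndarray:
        """Contextually naive latent U σ(b)."""
        return relu(self.basal(X)) @ self.mu_head.W.v


def _as_matrix(images) -> np.ndarray:
    if isinstance(images, LabeledImage):
        return images.pixels.reshape(1, -1)
    if isinstance(images, np.ndarray):
        return images.reshape(images.shape[0], -1) if images.ndim > 2 else images
    X, _ = stack(images)
    return X


def pretrain_backbone(images: Sequence[LabeledImage], epochs: int, seed: int,
                      n_units: int = 128, latent_dim: int = 16,
                      hidden: int = 256, batch_size: int = 64,
                      lr: float = 1e-3, holdout_frac: float = 0.1
                      ) -> BackboneEncoder:
    """Train the backbone VAE on unambiguous images with the ELBO
    (Bernoulli reconstruction + KL to a unit Gaussian), then freeze it.

    ``elbo_history[0]`` is the held-out ELBO before any update.
    """
    if len(images) == 0:
        raise ValueError("cannot pretrain on an empty dataset")
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    if any(im.ambiguity is not None for im in images):
        raise ValueError("backbone pretraining expects unambiguous images only")
    X, _ = stack(images)
    rng = np.random.default_rng(seed)
    net = BackboneEncoder(n_units, latent_dim, hidden, rng)

    n_hold = max(1, int(len(X) * holdout_frac))
    perm = rng.permutation(len(X))
    X_hold, X_tr = X[perm[:n_hold]], X[perm[n_hold:]]

    opt = Adam(net.params, lr=lr)
    eval_rng = np.random.default_rng(seed + 1)
    eval_eps = eval_rng.standard_normal((len(X_hold), latent_dim))

    def holdout_elbo() -> float:
        loss, _ = _vae_pass(net, X_hold, eval_eps, train=False)
        return -loss

    net.elbo_history.append(holdout_elbo())
    for _ in range(epochs):
        order = rng.permutation(len(X_tr))
        for i in range(0, len(X_tr), batch_size):
            xb = X_tr[order[i:i + batch_size]]
            eps = rng.standard_normal((len(xb), latent_dim))
            opt.zero_grad()
            _vae_pass(net, xb, eps, train=True)
            opt.step()
        net.elbo_history.append(holdout_elbo())
    net.frozen = True
    return net


def _vae_pass(net: BackboneEncoder, X: np.ndarray, eps: np.ndarray,
              train: bool) -> tuple[float, None]:
    B = len(X)
    a1_pre = net.enc1.forward(X)
    a1 = relu(a1_pre)
    b = net.enc2.forward(a1)
    h0 = relu(b)
    mu = net.mu_head.forward(h0)
    logvar = np.clip(net.logvar_head.forward(h0), -8.0, 8.0)
    std = np.exp(0.5 * logvar)
    z = mu + std * eps
    logits = net.dec.forward(z)
    p = sigmoid(logits)
    peps = 1e-7
    recon = -np.sum(X * np.log(p + peps) + (1 - X) * np.log(1 - p + peps)) / B
    kl = -0.5 * np.sum(1 + logvar - mu ** 2 - np.exp(logvar)) / B
    loss = float(recon + kl)
    if not train:
        return loss, None
    gz = net.dec.backward((p - X) / B)
    gmu = gz + mu / B
    glogvar = gz * 0.5 * std * eps + 0.5 * (np.exp(logvar) - 1.0) / B
    gh0 = net.mu_head.backward(gmu) + net.logvar_head.backward(glogvar)
    gb = gh0 * (b > 0)
    ga1 = net.enc2.backward(gb) * (a1_pre > 0)
    net.enc1.backward(ga1)
    return loss, None


def encode_basal(encoder: BackboneEncoder, x) -> np.ndarray:
    """Basal pre-activation vector(s) for one image or a batch."""
    if not encoder.frozen:
        raise ValueError("encoder must be frozen (pretrained) before use")
    X = _as_matrix(x)
    b = encoder.basal(X)
    return b[0] if isinstance(x, LabeledImage) else b


# ---------------------------------------------------------------------------
# compartment integration
# ---------------------------------------------------------------------------

@dataclass
class CompartmentState:
    """Per-example basal/apical pre-activations, firing rate and latent."""

    b: np.ndarray
    a: np.ndarray
    h: np.ndarray
    mu: np.ndarray


def integrate(b: np.ndarray, a: np.ndarray, rule: Rule = "hadamard") -> np.ndarray:
    """Combine basal and apical pre-activations into a firing rate."""
    b = np.asarray(b, dtype=np.float64)
    a = np.asarray(a, dtype=np.float64)
    if b.shape != a.shape:
        raise ValueError(f"shape mismatch: b {b.shape} vs a {a.shape}")
    if rule == "hadamard":
        return relu(b) * (relu(a) + 1.0)
    if rule == "additive":
        return relu(b) + relu(a)
    if rule == "single_compartment":
        raise ValueError("single-compartment integration is a separate forward "
                         "path; use forward_single()")
    raise ValueError(f"unknown integration rule: {rule!r}")


def project_mu(proj: Projection, h: np.ndarray) -> np.ndarray:
    """μ = U h."""
    h = np.asarray(h, dtype=np.float64)
    if h.shape[-1] != proj.U.shape[1]:
        raise ValueError(f"h has width {h.shape[-1]}, U expects {proj.U.shape[1]}")
    return h @ proj.U.T


# ---------------------------------------------------------------------------
# context sources
# ---------------------------------------------------------------------------

@dataclass
class ContextVector:
    c: np.ndarray
    source: Literal["oracle", "softened", "temporal"]


def onehot_context(y: int, C: int) -> ContextVector:
    """Oracle context: indicator of the context class."""
    if not (0 <= y < C):
        raise ValueError(f"class id {y} out of range for C={C}")
    c = np.zeros(C)
    c[y] = 1.0
    return ContextVector(c=c, source="oracle")


def soften_context(y: int, C: int, certainty: float) -> ContextVector:
    """Context with stated certainty on the target class and the
    residual mass spread uniformly over the other classes."""
    if not (0 <= y < C):
        raise ValueError(f"class id {y} out of range for C={C}")
    if not (1.0 / C < certainty <= 1.0):
        raise ValueError(f"certainty must lie in (1/C, 1], got {certainty}")
    c = np.full(C, (1.0 - certainty) / (C - 1))
    c[y] = certainty
    return ContextVector(c=c, source="softened" if certainty < 1.0 else "oracle")


# ---------------------------------------------------------------------------
# top-down network
# ---------------------------------------------------------------------------

class TopDownNet:
    """One-hidden-layer MLP g mapping (context ⊕ naive latent) to the
    apical pre-activation vector a."""

    def __init__(self, latent_dim: int, context_dim: int, n_units: int,
                 hidden: int, rng: np.random.Generator,
                 rule: Rule = "hadamard") -> None:
        self.latent_dim = latent_dim
        self.context_dim = context_dim
        self.n_units = n_units
        self.rule = rule
        self.net = MLP([latent_dim + context_dim, hidden, n_units], rng)

    @property
    def params(self):
        return self.net.params

    def apical(self, mu_naive: np.ndarray, c: np.ndarray) -> np.ndarray:
        if c.shape[-1] != self.context_dim:
            raise ValueError(f"context width {c.shape[-1]} != {self.context_dim}")
        if mu_naive.shape[-1] != self.latent_dim:
            raise ValueError(f"latent width {mu_naive.shape[-1]} != {self.latent_dim}")
        return self.net.forward(np.concatenate([c, mu_naive], axis=-1))


def compute_apical(g: TopDownNet, mu_naive: np.ndarray, c) -> np.ndarray:
    """a = g(c ⊕ U σ(b))."""
    cv = c.c if isinstance(c, ContextVector) else np.asarray(c, dtype=np.float64)
    single = mu_naive.ndim == 1
    mu2 = mu_naive[None, :] if single else mu_naive
    c2 = np.broadcast_to(cv, (mu2.shape[0], cv.shape[-1])) if cv.ndim == 1 else cv
    a = g.apical(mu2, c2)
    return a[0] if single else a


def forward(encoder: BackboneEncoder, proj: Projection, g: TopDownNet,
            x, c, rule: Rule = "hadamard") -> CompartmentState:
    """Full two-compartment pass: b, a, h and μ for one image or a batch."""
    if rule == "single_compartment":
        raise ValueError("use forward_single() for the single-compartment ablation")
    b = encode_basal(encoder, x)
    mu_naive = project_mu(proj, relu(b))
    a = compute_apical(g, mu_naive, c)
    h = integrate(b, a, rule)
    mu = project_mu(proj, h)
    return CompartmentState(b=b, a=a, h=h, mu=mu)


def forward_single(encoder: BackboneEncoder, proj: Projection,
                   g_single: TopDownNet, x, c) -> np.ndarray:
    """Single-compartment ablation: context is summed into the basal
    pre-activation before one shared nonlinearity,
    μ = U σ(b + g(c ⊕ Uσ(b)))."""
    b = encode_basal(encoder, x)
    mu_naive = project_mu(proj, relu(b))
    delta = compute_apical(g_single, mu_naive, c)
    return project_mu(proj, relu(b + delta))


# ---------------------------------------------------------------------------
# readout
# ---------------------------------------------------------------------------

class Readout:
    """MLP classifier over latent space (bias-free by default so that
    relevance propagation conserves the class logit exactly)."""

    def __init__(self, latent_dim: int, n_classes: int, hidden: int,
                 rng: np.random.Generator, bias: bool = False) -> None:
        self.n_classes = n_classes
        self.net = MLP([latent_dim, hidden, n_classes], rng, bias=bias)

    @property
    def params(self):
        return self.net.params

    def digest(self) -> str:
        return params_digest(self.params)

    def logits(self, mu: np.ndarray) -> np.ndarray:
        return self.net.forward(np.atleast_2d(mu))

    def predict(self, mu: np.ndarray) -> np.ndarray:
        return self.logits(mu).argmax(axis=-1)


def train_readout(encoder: BackboneEncoder, latents: np.ndarray,
                  labels: np.ndarray, n_classes: int, epochs: int = 40,
                  seed: int = 0, hidden: int = 64, lr: float = 1e-3,
                  batch_size: int = 64, bias: bool = False) -> Readout:
    """Cross-entropy training of the readout over frozen latents."""
    if not encoder.frozen:
        raise ValueError("encoder must be frozen before training a readout")
    labels = np.asarray(labels, dtype=np.int64)
    if labels.size == 0:
        raise ValueError("empty label set")
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError("label outside the declared alphabet")
    rng = np.random.default_rng(seed)
    ro = Readout(latents.shape[1], n_classes, hidden, rng, bias=bias)
    opt = Adam(ro.params, lr=lr)
    for _ in range(epochs):
        order = rng.permutation(len(latents))
        for i in range(0, len(latents), batch_size):
            idx = order[i:i + batch_size]
            opt.zero_grad()
            logits = ro.net.forward(latents[idx])
            _, gl = cross_entropy(logits, labels[idx])
            ro.net.backward(gl)
            opt.step()
    return ro


def extended_categories(n_classes: int) -> list[tuple[int, ...]]:
    """Readout alphabet of single classes plus all unordered pairs.

    For 10 source classes this has 10 + 45 = 55 categories.
    """
    cats: list[tuple[int, ...]] = [(i,) for i in range(n_classes)]
    cats += [(i, j) for i in range(n_classes) for j in range(i + 1, n_classes)]
    return cats


def pair_category_index(n_classes: int, y0: int, y1: int) -> int:
    """Index of the unordered-pair category (y0, y1) in the extended alphabet."""
    i, j = min(y0, y1), max(y0, y1)
    if i == j:
        raise ValueError("pair categories need two distinct classes")
    # singles occupy [0, n); pairs follow in lexicographic order
    return n_classes + i * n_classes - i * (i + 1) // 2 + (j - i - 1)


# ---------------------------------------------------------------------------
# temporal context (GRU over latent sequences)
# ---------------------------------------------------------------------------

class ContextGRU:
    """GRU over backbone latents; its final hidden state is the
    temporal context signal, and a linear head predicts the modulo-K sum
    of the sequence digits during training."""

    def __init__(self, input_dim: int, n_classes: int, hidden_size: int,
                 rng: np.random.Generator) -> None:
        self.input_dim = input_dim
        self.hidden_size = hidden_size
        self.cell = GRUCell(input_dim, hidden_size, rng)
        self.head = Linear(hidden_size, n_classes, rng)
        self.trained = False

    @property
    def params(self):
        return self.cell.params + self.head.params

    def digest(self) -> str:
        return params_digest(self.params)

    def hidden(self, seq: np.ndarray) -> np.ndarray:
        """Final hidden state for a (B, T, input_dim) latent sequence."""
        B = seq.shape[0]
        h = np.zeros((B, self.hidden_size))
        for t in range(seq.shape[1]):
            h, _ = self.cell.forward(seq[:, t, :], h)
        return h

    def predict_sum(self, seq: np.ndarray) -> np.ndarray:
        return self.head.forward(self.hidden(seq)).argmax(axis=-1)


def train_context_gru(encoder: BackboneEncoder, sequences: np.ndarray,
                      sum_labels: np.ndarray, epochs: int = 60, seed: int = 0,
                      hidden_size: int = 128, lr: float = 1e-3,
                      batch_size: int = 64, seq_len: int = 2) -> ContextGRU:
    """Train the GRU to classify the modulo-K sum of a two-digit latent
    sequence (inputs are U σ(b) latents, not pixels)."""
    if not encoder.frozen:
        raise ValueError("encoder must be frozen before training the GRU")
    sequences = np.asarray(sequences, dtype=np.float64)
    if sequences.size == 0:
        raise ValueError("empty sequence set")
    if sequences.ndim != 3 or sequences.shape[1] != seq_len:
        raise ValueError(f"expected (B, {seq_len}, latent) sequences, "
                         f"got {sequences.shape}")
    if sequences.shape[2] != encoder.latent_dim:
        raise ValueError("sequence latent width does not match the encoder")
    sum_labels = np.asarray(sum_labels, dtype=np.int64)
    n_classes = int(sum_labels.max()) + 1
    rng = np.random.default_rng(seed)
    gru = ContextGRU(encoder.latent_dim, n_classes, hidden_size, rng)
    opt = Adam(gru.params, lr=lr)
    T = sequences.shape[1]
    for _ in range(epochs):
        order = rng.permutation(len(sequences))
        for i in range(0, len(sequences), batch_size):
            idx = order[i:i + batch_size]
            xb, yb = sequences[idx], sum_labels[idx]
            opt.zero_grad()
            h = np.zeros((len(xb), hidden_size))
            caches = []
            for t in range(T):
                h, cache = gru.cell.forward(xb[:, t, :], h)
                caches.append(cache)
            logits = gru.head.forward(h)
            _, gl = cross_entropy(logits, yb)
            gh = gru.head.backward(gl)
            for t in range(T - 1, -1, -1):
                _, gh = gru.cell.backward(gh, caches[t])
            opt.step()
    gru.trained = True
    return gru


def temporal_context(gru: ContextGRU, latents: np.ndarray) -> ContextVector:
    """Final GRU hidden state as the context signal."""
    if not gru.trained:
        raise ValueError("GRU must be trained before providing context")
    latents = np.asarray(latents, dtype=np.float64)
    single = latents.ndim == 2
    seq = latents[None, ...] if single else latents
    if seq.shape[-1] != gru.input_dim:
        raise ValueError(f"latent width {seq.shape[-1]} != GRU input {gru.input_dim}")
    h = gru.hidden(seq)
    return ContextVector(c=h[0] if single else h, source="temporal")
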