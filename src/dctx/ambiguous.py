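"""Ambiguous-image generation by conditional generative interpolation.

A class-conditioned variational autoencoder (CVAE) is trained on
unambiguous images. Blends between two classes are then decoded from
prior latent draws with a condition vector interpolated between the two
class one-hots. Candidates are kept only if an independent classifier
(trained on the unambiguous source set) places them near the 50%
decision boundary between the two parent classes — by default within
50% +/- 5% of the two-class renormalized probability. Surviving blends
are organized into triplets (unambiguous exemplar of each parent class
plus the blend), the unit downstream scenario construction works on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .glyphs import IMG_SIZE, LabeledImage, stack
from .nnops import Adam, Linear, MLP, cross_entropy, sigmoid, softmax

__all__ = [
    "ConditionalGenerator",
    "AmbiguityFilter",
    "AmbiguousTriplet",
    "train_cvae",
    "interpolate_condition",
    "generate_ambiguous",
    "train_ambiguity_classifier",
    "filter_by_ambiguity",
    "build_triplets",
    "make_ambiguous_dataset",
]


# ---------------------------------------------------------------------------
# conditional generator
# ---------------------------------------------------------------------------

class ConditionalGenerator:
    """MLP CVAE. The decoder maps (latent, condition) to a 28x28 image
    in [0, 1]; the condition is any non-negative vector of length
    ``n_classes`` summing to 1 (one-hots and their interpolations)."""

    def __init__(self, latent_dim: int, n_classes: int, hidden: int,
                 rng: np.random.Generator) -> None:
        d = IMG_SIZE * IMG_SIZE
        self.latent_dim = latent_dim
        self.n_classes = n_classes
        self.enc = MLP([d + n_classes, hidden, hidden], rng)
        self.mu_head = Linear(hidden, latent_dim, rng)
        self.logvar_head = Linear(hidden, latent_dim, rng)
        self.dec = MLP([latent_dim + n_classes, hidden, d], rng)
        self.trained = False
        self.elbo_history: list[float] = []

    @property
    def params(self):
        return (self.enc.params + self.mu_head.params
                + self.logvar_head.params + self.dec.params)

    def decode(self, z: np.ndarray, cond: np.ndarray) -> np.ndarray:
        """Decode latents with a condition vector; returns (B, 28, 28)."""
        z = np.atleast_2d(z)
        cond = np.atleast_2d(cond)
        if cond.shape[-1] != self.n_classes:
            raise ValueError(f"condition width {cond.shape[-1]} != {self.n_classes}")
        if np.any(cond < 0) or not np.allclose(cond.sum(axis=-1), 1.0):
            raise ValueError("condition entries must be non-negative and sum to 1")
        logits = self.dec.forward(np.concatenate([z, cond], axis=-1))
        return sigmoid(logits).reshape(-1, IMG_SIZE, IMG_SIZE)


def _onehot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((len(labels), n_classes))
    out[np.arange(len(labels)), labels] = 1.0
    return out


def train_cvae(images: Sequence[LabeledImage], latent_dim: int = 8,
               epochs: int = 150, seed: int = 0, hidden: int = 384,
               batch_size: int = 64, lr: float = 1.5e-3,
               holdout_frac: float = 0.1) -> ConditionalGenerator:
    """ELBO training of the class-conditioned generator on unambiguous
    images; deterministic given the seed. ``elbo_history[0]`` is the
    held-out ELBO before any update."""
    if len(images) == 0:
        raise ValueError("cannot train a CVAE on an empty dataset")
    if any(im.ambiguity is not None for im in images):
        raise ValueError("CVAE training expects unambiguous images only")
    X, y = stack(images)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("CVAE training needs at least two classes")
    n_classes = int(y.max()) + 1
    Y = _onehot(y, n_classes)

    rng = np.random.default_rng(seed)
    gen = ConditionalGenerator(latent_dim, n_classes, hidden, rng)
    opt = Adam(gen.params, lr=lr)

    n_hold = max(1, int(len(X) * holdout_frac))
    perm = rng.permutation(len(X))
    hold, tr = perm[:n_hold], perm[n_hold:]
    eval_eps = np.random.default_rng(seed + 1).standard_normal((n_hold, latent_dim))

    def holdout_elbo() -> float:
        return -_cvae_pass(gen, X[hold], Y[hold], eval_eps, train=False)

    gen.elbo_history.append(holdout_elbo())
    for _ in range(epochs):
        order = rng.permutation(len(tr))
        for i in range(0, len(tr), batch_size):
            idx = tr[order[i:i + batch_size]]
            eps = rng.standard_normal((len(idx), latent_dim))
            opt.zero_grad()
            _cvae_pass(gen, X[idx], Y[idx], eps, train=True)
            opt.step()
        gen.elbo_history.append(holdout_elbo())
    gen.trained = True
    return gen


def _cvae_pass(gen: ConditionalGenerator, X: np.ndarray, Y: np.ndarray,
               eps: np.ndarray, train: bool) -> float:
    B = len(X)
    henc = gen.enc.forward(np.concatenate([X, Y], axis=-1))
    mu = gen.mu_head.forward(henc)
    logvar = np.clip(gen.logvar_head.forward(henc), -8.0, 8.0)
    std = np.exp(0.5 * logvar)
    z = mu + std * eps
    logits = gen.dec.forward(np.concatenate([z, Y], axis=-1))
    p = sigmoid(logits)
    peps = 1e-7
    recon = -np.sum(X * np.log(p + peps) + (1 - X) * np.log(1 - p + peps)) / B
    kl = -0.5 * np.sum(1 + logvar - mu ** 2 - np.exp(logvar)) / B
    loss = float(recon + kl)
    if not train:
        return loss
    gzy = gen.dec.backward((p - X) / B)
    gz = gzy[:, :gen.latent_dim]
    gmu = gz + mu / B
    glogvar = gz * 0.5 * std * eps + 0.5 * (np.exp(logvar) - 1.0) / B
    ghenc = gen.mu_head.backward(gmu) + gen.logvar_head.backward(glogvar)
    gen.enc.backward(ghenc)
    return loss


def interpolate_condition(y0: int, y1: int, alpha: float,
                          n_classes: int) -> np.ndarray:
    """(1 - alpha) * onehot(y0) + alpha * onehot(y1)."""
    if y0 == y1:
        raise ValueError("parent classes must differ")
    if not (0 <= y0 < n_classes and 0 <= y1 < n_classes):
        raise ValueError("class ids out of range")
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    c = np.zeros(n_classes)
    c[y0] = 1.0 - alpha
    c[y1] += alpha
    return c


def generate_ambiguous(gen: ConditionalGenerator, y0: int, y1: int,
                       n_samples: int, alpha_range: tuple[float, float] = (0.5, 0.5),
                       seed: int = 0) -> list[LabeledImage]:
    """Decode prior latent draws with interpolated conditions; each
    output carries ambiguity annotation (y0, y1, alpha)."""
    if not gen.trained:
        raise ValueError("generator must be trained before sampling")
    if y0 == y1:
        raise ValueError("parent classes must differ")
    lo, hi = alpha_range
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError("alpha_range must satisfy 0 <= lo <= hi <= 1")
    rng = np.random.default_rng(seed)
    alphas = rng.uniform(lo, hi, size=n_samples) if hi > lo else np.full(n_samples, lo)
    z = rng.standard_normal((n_samples, gen.latent_dim))
    cond = np.stack([interpolate_condition(y0, y1, a, gen.n_classes) for a in alphas])
    pix = np.clip(gen.decode(z, cond), 0.0, 1.0)
    return [
        LabeledImage(pixels=pix[i],
                     label=y0 if alphas[i] <= 0.5 else y1,
                     ambiguity=(y0, y1, float(alphas[i])))
        for i in range(n_samples)
    ]


# ---------------------------------------------------------------------------
# ambiguity filter
# ---------------------------------------------------------------------------

class PixelClassifier:
    """Softmax MLP over raw pixels used only to score ambiguity."""

    def __init__(self, n_classes: int, hidden: int, rng: np.random.Generator) -> None:
        self.n_classes = n_classes
        self.net = MLP([IMG_SIZE * IMG_SIZE, hidden, n_classes], rng)

    @property
    def params(self):
        return self.net.params

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return softmax(self.net.forward(np.atleast_2d(X)))


def train_ambiguity_classifier(images: Sequence[LabeledImage], epochs: int = 30,
                               seed: int = 0, hidden: int = 128,
                               batch_size: int = 64, lr: float = 1e-3
                               ) -> PixelClassifier:
    """Train the filter's classifier on the unambiguous source set."""
    if len(images) == 0:
        raise ValueError("cannot train a classifier on an empty dataset")
    X, y = stack(images)
    n_classes = int(y.max()) + 1
    rng = np.random.default_rng(seed)
    clf = PixelClassifier(n_classes, hidden, rng)
    opt = Adam([p for layer in clf.net.layers for p in layer.params], lr=lr)
    for _ in range(epochs):
        order = rng.permutation(len(X))
        for i in range(0, len(X), batch_size):
            idx = order[i:i + batch_size]
            opt.zero_grad()
            logits = clf.net.forward(X[idx])
            _, gl = cross_entropy(logits, y[idx])
            clf.net.backward(gl)
            opt.step()
    return clf


@dataclass
class AmbiguityFilter:
    """Keeps a blend iff the classifier's two-class renormalized
    probability p(y0) / (p(y0) + p(y1)) lies in [center - half_width,
    center + half_width] (default 50% +/- 5%)."""

    classifier: PixelClassifier
    center: float = 0.5
    half_width: float = 0.05

    def two_class_probability(self, images: Sequence[LabeledImage]) -> np.ndarray:
        for im in images:
            if im.ambiguity is None:
                raise ValueError("candidate is missing its ambiguity annotation")
        X, _ = stack(images)
        proba = self.classifier.predict_proba(X)
        y0 = np.array([im.ambiguity[0] for im in images])
        y1 = np.array([im.ambiguity[1] for im in images])
        idx = np.arange(len(images))
        p0, p1 = proba[idx, y0], proba[idx, y1]
        return p0 / np.maximum(p0 + p1, 1e-12)

    def accepts(self, images: Sequence[LabeledImage]) -> np.ndarray:
        p = self.two_class_probability(images)
        return (p >= self.center - self.half_width) & (p <= self.center + self.half_width)


def filter_by_ambiguity(candidates: Sequence[LabeledImage],
                        filt: AmbiguityFilter) -> list[LabeledImage]:
    """Order-preserving subset of candidates inside the ambiguity band."""
    if len(candidates) == 0:
        return []
    keep = filt.accepts(candidates)
    return [im for im, k in zip(candidates, keep) if k]


# ---------------------------------------------------------------------------
# triplets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AmbiguousTriplet:
    """Two unambiguous parent exemplars plus the filtered blend."""

    x0: LabeledImage
    x1: LabeledImage
    x_ambig: LabeledImage

    def __post_init__(self) -> None:
        amb = self.x_ambig.ambiguity
        if amb is None:
            raise ValueError("x_ambig must carry an ambiguity annotation")
        y0, y1, _ = amb
        if y0 == y1:
            raise ValueError("parent classes must differ")
        if self.x0.label != y0 or self.x1.label != y1:
            raise ValueError("parent labels must match the blend annotation")
        if self.x0.ambiguity is not None or self.x1.ambiguity is not None:
            raise ValueError("parent exemplars must be unambiguous")

    @property
    def y0(self) -> int:
        return self.x0.label

    @property
    def y1(self) -> int:
        return self.x1.label

    @property
    def alpha(self) -> float:
        return self.x_ambig.ambiguity[2]


def build_triplets(unambiguous: Sequence[LabeledImage],
                   ambiguous: Sequence[LabeledImage],
                   pairing_seed: int = 0) -> list[AmbiguousTriplet]:
    """Pair each blend with one exemplar of each parent class, sampling
    without replacement per class until exhaustion, then with
    replacement."""
    rng = np.random.default_rng(pairing_seed)
    by_class: dict[int, list[LabeledImage]] = {}
    for im in unambiguous:
        if im.ambiguity is not None:
            raise ValueError("unambiguous pool contains a blended image")
        by_class.setdefault(im.label, []).append(im)
    queues: dict[int, list[int]] = {
        k: list(rng.permutation(len(v))) for k, v in by_class.items()
    }

    def draw(cls: int) -> LabeledImage:
        pool = by_class.get(cls)
        if not pool:
            raise ValueError(f"no unambiguous exemplars for class {cls}")
        if queues[cls]:
            return pool[queues[cls].pop()]
        return pool[rng.integers(len(pool))]

    triplets = []
    for blend in ambiguous:
        if blend.ambiguity is None:
            raise ValueError("ambiguous image missing its annotation")
        y0, y1, _ = blend.ambiguity
        triplets.append(AmbiguousTriplet(x0=draw(y0), x1=draw(y1), x_ambig=blend))
    return triplets


def make_ambiguous_dataset(gen: ConditionalGenerator, filt: AmbiguityFilter,
                           pairs: Sequence[tuple[int, int]], n_per_pair: int,
                           seed: int = 0,
                           alpha_range: tuple[float, float] = (0.5, 0.5),
                           batch_candidates: int = 400,
                           max_attempts: int = 8,
                           min_parent_mass: float = 0.9) -> list[LabeledImage]:
    """Generate-and-filter loop: fresh prior draws per attempt until
    ``n_per_pair`` survivors per pair or the attempt budget is spent (a
    shortfall is reported with a warning, not an error).

    Besides the 50%-band filter, candidates must put at least
    ``min_parent_mass`` of the classifier's total probability on the two
    parent classes — a blend is only "ambiguous between y0 and y1" if it
    actually resembles them, not if it is equally unlike both.
    """
    out: list[LabeledImage] = []
    for k, (y0, y1) in enumerate(pairs):
        kept: list[LabeledImage] = []
        for attempt in range(max_attempts):
            cands = generate_ambiguous(
                gen, y0, y1, batch_candidates, alpha_range,
                seed=seed + 7919 * k + 104_729 * attempt)
            if min_parent_mass > 0:
                proba = filt.classifier.predict_proba(
                    np.stack([im.pixels.reshape(-1) for im in cands]))
                mass = proba[:, y0] + proba[:, y1]
                cands = [im for im, m in zip(cands, mass)
                         if m >= min_parent_mass]
            kept.extend(filter_by_ambiguity(cands, filt))
            if len(kept) >= n_per_pair:
                break
        if len(kept) < n_per_pair:
            warnings.warn(
                f"pair ({y0},{y1}): only {len(kept)}/{n_per_pair} blends "
                f"survived the ambiguity band", stacklevel=2)
        out.extend(kept[:n_per_pair])
    return out
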