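"""Interpretability suite: epsilon-rule relevance propagation over the
readout path, 95%-coverage relevance sets, Jaccard separability,
compartment-amplitude summaries, the apical masking ablation, and
representation metrics (per-pair silhouette, cosine-distance profile,
apical-basal mutual information, t-SNE wrapper).

Relevance is propagated from one class logit back through the frozen
latent projection U and the readout MLP to the firing-rate layer h.
Because that path is bias-free, the per-example relevance sum equals
the class logit up to the epsilon stabilizer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score

from .model import CompartmentState, Projection, Readout, Rule, TopDownNet, project_mu
from .nnops import relu
from .scenarios import ScenarioBatch

__all__ = [
    "RelevanceMap",
    "RelevanceSet",
    "SeparabilityMatrix",
    "lrp_relevance",
    "relevance_sets",
    "separability",
    "amplitude_by_subset",
    "mask_apical_ablation",
    "silhouette_by_pair",
    "cosine_distance_profile",
    "histogram_mutual_info",
    "mutual_info_apical_basal",
    "tsne_projection",
]


# ---------------------------------------------------------------------------
# layer-wise relevance propagation
# ---------------------------------------------------------------------------

@dataclass
class RelevanceMap:
    """Per-neuron relevance of the h layer for one readout class."""

    scores: np.ndarray   # (examples, n)
    class_id: int
    logits: np.ndarray   # (examples,) pre-softmax score of class_id


@dataclass
class RelevanceSet:
    """Minimal descending-relevance prefix reaching the coverage level."""

    class_id: int
    members: tuple[int, ...]
    coverage: float


@dataclass
class SeparabilityMatrix:
    values: np.ndarray  # (C, C), symmetric, zero diagonal, in [0, 1]


def _epsilon_backprop(weights: list[np.ndarray], acts: list[np.ndarray],
                      R_out: np.ndarray, epsilon: float) -> np.ndarray:
    """Propagate relevance back through stacked linear(+ReLU) layers.

    ``weights[k]`` maps acts[k] -> pre-activation k+1; ``acts`` holds the
    forward (post-ReLU) activations, acts[0] being the h layer.
    """
    R = R_out
    for W, A in zip(reversed(weights), reversed(acts)):
        Z = A @ W
        denom = Z + epsilon * np.where(Z >= 0, 1.0, -1.0)
        S = R / denom
        R = A * (S @ W.T)
    return R


def lrp_relevance(readout: Readout, h_batch: np.ndarray, class_id: int,
                  epsilon: float = 1e-6,
                  proj: Projection | None = None) -> RelevanceMap:
    """Epsilon-rule relevance of firing rates h for one readout class.

    If ``proj`` is given the propagation path is h -> U -> readout MLP,
    i.e. ``h_batch`` holds firing rates; otherwise ``h_batch`` is taken
    to be the readout's direct input. Any bias term on the path would
    absorb relevance, so the readout must be bias-free.
    """
    if not (0 <= class_id < readout.n_classes):
        raise ValueError(f"class_id {class_id} out of range")
    for layer in readout.net.layers:
        if layer.b is not None:
            raise ValueError("relevance propagation requires a bias-free readout")
    h_batch = np.atleast_2d(np.asarray(h_batch, dtype=np.float64))
    weights: list[np.ndarray] = []
    acts: list[np.ndarray] = [h_batch]
    x = h_batch
    if proj is not None:
        weights.append(proj.U.T)
        x = x @ proj.U.T
        acts.append(x)
    for i, layer in enumerate(readout.net.layers):
        weights.append(layer.W.v)
        x = x @ layer.W.v
        if i < len(readout.net.layers) - 1:
            x = relu(x)
            acts.append(x)
    logits = x[:, class_id]
    R_out = np.zeros_like(x)
    R_out[:, class_id] = logits
    scores = _epsilon_backprop(weights, acts, R_out, epsilon)
    return RelevanceMap(scores=scores, class_id=class_id, logits=logits)


def relevance_sets(maps: Sequence[RelevanceMap],
                   coverage: float = 0.95) -> list[RelevanceSet]:
    """Minimal prefix of neurons (sorted by descending mean relevance,
    ties by index) whose cumulative non-negative relevance reaches the
    coverage fraction of the total positive relevance."""
    if not (0.0 < coverage <= 1.0):
        raise ValueError("coverage must lie in (0, 1]")
    out = []
    for m in maps:
        mean_r = m.scores.mean(axis=0)
        n = mean_r.shape[0]
        order = np.lexsort((np.arange(n), -mean_r))
        pos = np.clip(mean_r, 0.0, None)
        total = pos.sum()
        if total <= 0:
            out.append(RelevanceSet(m.class_id, (), coverage))
            continue
        cum = np.cumsum(pos[order]) / total
        k = int(np.searchsorted(cum, coverage - 1e-12) + 1)
        out.append(RelevanceSet(m.class_id, tuple(int(i) for i in order[:k]),
                                coverage))
    return out


def separability(sets: Sequence[RelevanceSet]) -> SeparabilityMatrix:
    """1 - Jaccard overlap between relevance sets (0 identical,
    1 disjoint)."""
    C = len(sets)
    vals = np.zeros((C, C))
    members = [frozenset(s.members) for s in sets]
    for i in range(C):
        for j in range(i + 1, C):
            union = members[i] | members[j]
            if not union:
                warnings.warn(f"sets {i} and {j} are both empty; separability "
                              "defined as 0", stacklevel=2)
                v = 0.0
            else:
                v = 1.0 - len(members[i] & members[j]) / len(union)
            vals[i, j] = vals[j, i] = v
    return SeparabilityMatrix(values=vals)


# ---------------------------------------------------------------------------
# compartment amplitudes
# ---------------------------------------------------------------------------

def amplitude_by_subset(states: Mapping[str, CompartmentState],
                        sets: Mapping[str, Sequence[int]],
                        compartment: Literal["apical", "basal"] = "apical"
                        ) -> pd.DataFrame:
    """Mean post-nonlinearity amplitude per neuron subset and scenario,
    normalized by the mean over all neurons in that scenario."""
    rows = []
    for scenario, st in states.items():
        act = relu(st.a if compartment == "apical" else st.b)
        overall = act.mean()
        for name, idx in sets.items():
            idx = np.asarray(list(idx), dtype=np.int64)
            if len(idx) and (idx.min() < 0 or idx.max() >= act.shape[1]):
                raise ValueError(f"subset {name!r} has out-of-range indices")
            amp = act[:, idx].mean() if len(idx) else 0.0
            rows.append((scenario, name, compartment,
                         float(amp / overall) if overall > 0 else 0.0))
    return pd.DataFrame(rows, columns=["scenario", "subset", "compartment",
                                       "amplitude"])


# ---------------------------------------------------------------------------
# apical masking ablation
# ---------------------------------------------------------------------------

def mask_apical_ablation(proj: Projection, g: TopDownNet, readout: Readout,
                         batch: ScenarioBatch,
                         relevance_order: Mapping[int, Sequence[int]],
                         sizes: Sequence[int], n_random_draws: int = 5,
                         seed: int = 0, rule: Rule = "hadamard"
                         ) -> pd.DataFrame:
    """Accuracy on a matched-context ambiguous batch when the apical
    contribution of (i) the top-k context-relevant neurons or (ii) k
    random neurons is masked (sigma(a) set to 0 so masked neurons revert
    to their unmodulated output)."""
    n = g.n_units
    if any(k > n or k < 0 for k in sizes):
        raise ValueError(f"mask sizes must lie in [0, {n}]")
    a = g.apical(batch.mu_naive, batch.c)
    sa = relu(a)
    sb = relu(batch.b)
    rng = np.random.default_rng(seed)

    def accuracy(sa_masked: np.ndarray) -> float:
        if rule == "hadamard":
            h = sb * (1.0 + sa_masked)
        elif rule == "additive":
            h = sb + sa_masked
        else:
            raise ValueError("masking ablation applies to two-compartment rules")
        preds = readout.predict(project_mu(proj, h))
        return float(np.mean(preds == batch.context_class))

    rows = []
    for k in sizes:
        sa_rel = sa.copy()
        if k > 0:
            for i, ctx in enumerate(batch.context_class):
                top = np.asarray(relevance_order[int(ctx)], dtype=np.int64)[:k]
                sa_rel[i, top] = 0.0
        rows.append((int(k), "context_relevant", accuracy(sa_rel), 0.0))
        accs = []
        for _ in range(n_random_draws):
            sa_rand = sa.copy()
            if k > 0:
                cols = rng.choice(n, size=k, replace=False)
                sa_rand[:, cols] = 0.0
            accs.append(accuracy(sa_rand))
        rows.append((int(k), "random", float(np.mean(accs)),
                     float(np.std(accs))))
    return pd.DataFrame(rows, columns=["size", "condition", "accuracy", "sd"])


# ---------------------------------------------------------------------------
# representation metrics
# ---------------------------------------------------------------------------

def silhouette_by_pair(latents: np.ndarray, labels: np.ndarray,
                       pairs: Sequence[tuple[int, int]]) -> pd.DataFrame:
    """Silhouette coefficient per class pair, restricted to that pair."""
    labels = np.asarray(labels)
    rows = []
    for (i, j) in pairs:
        mask = (labels == i) | (labels == j)
        if np.sum(labels == i) < 2 or np.sum(labels == j) < 2:
            raise ValueError(f"pair ({i},{j}) needs >= 2 examples per class")
        score = float(silhouette_score(latents[mask], labels[mask]))
        rows.append((i, j, score))
    return pd.DataFrame(rows, columns=["class_a", "class_b", "silhouette"])


def _cosine_distance(ref: np.ndarray, X: np.ndarray) -> np.ndarray:
    ref = np.broadcast_to(ref, X.shape)
    num = np.sum(ref * X, axis=-1)
    den = np.linalg.norm(ref, axis=-1) * np.linalg.norm(X, axis=-1)
    out = np.ones(len(X))
    ok = den > 0
    if not np.all(ok):
        warnings.warn("zero-norm vector in cosine distance; defined as 1",
                      stacklevel=2)
    out[ok] = 1.0 - num[ok] / den[ok]
    return out


def cosine_distance_profile(reference_h: np.ndarray,
                            states: Mapping[str, CompartmentState]
                            ) -> pd.DataFrame:
    """Mean cosine distance between a reference firing-rate pattern and
    the basal activation, apical activation and firing rate per
    scenario."""
    rows = []
    for scenario, st in states.items():
        for signal, X in (("basal", relu(st.b)), ("apical", relu(st.a)),
                          ("rate", st.h)):
            d = _cosine_distance(reference_h, X)
            rows.append((scenario, signal, float(d.mean())))
    return pd.DataFrame(rows, columns=["scenario", "signal", "distance"])


def histogram_mutual_info(x: np.ndarray, y: np.ndarray,
                          n_bins: int = 16) -> float:
    """Equal-width-binned mutual information (nats), non-negative."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    joint, _, _ = np.histogram2d(x, y, bins=n_bins)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


def mutual_info_apical_basal(states: Mapping[str, CompartmentState],
                             n_bins: int = 16) -> pd.DataFrame:
    """MI between mean apical and mean basal activation per neuron
    (averaged across examples), per scenario."""
    rows = []
    for scenario, st in states.items():
        xa = relu(st.a).mean(axis=0)
        xb = relu(st.b).mean(axis=0)
        rows.append((scenario, histogram_mutual_info(xa, xb, n_bins)))
    return pd.DataFrame(rows, columns=["scenario", "mutual_information"])


def tsne_projection(latents: np.ndarray, seed: int = 0) -> np.ndarray:
    """Two-dimensional t-SNE embedding (plotting aid only)."""
    latents = np.asarray(latents, dtype=np.float64)
    if latents.ndim != 2 or len(latents) < 10:
        raise ValueError("t-SNE projection needs at least 10 points")
    perplexity = min(30.0, (len(latents) - 1) / 3.0)
    emb = TSNE(n_components=2, random_state=seed, perplexity=perplexity,
               init="pca").fit_transform(latents)
    return np.asarray(emb, dtype=np.float64)
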