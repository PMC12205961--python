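"""Five-scenario contextual training of the top-down network.

The top-down MLP g is the only trainable component; backbone, latent
projection and readout stay frozen. Every optimization step draws a
shared minibatch of triplets and builds one batch per input/context
scenario:

  s=1 ambig.Match    ambiguous input, context = one parent class;
                     target = that parent exemplar's unmodulated latent
  s=2 unambig.Match  unambiguous input, context = its own class;
                     target = its own unmodulated latent
  s=3 unambig.Irrel  unambiguous input, context outside the pair;
                     target = its own unmodulated latent
  s=4 ambig.Irrel    ambiguous input, context outside the pair;
                     target = the blend's own unmodulated latent
  s=5 unambig.Contra unambiguous input, context = the other parent;
                     target = its own unmodulated latent by default
                     (``contra_target="context"`` selects the other
                     parent's latent instead)

The loss is the scenario-summed mean squared error between predicted
and target latents, minimized with Adam over g's parameters only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .ambiguous import AmbiguousTriplet
from .model import (BackboneEncoder, ContextGRU, Projection, Readout,
                    TopDownNet, Rule, onehot_context, project_mu,
                    soften_context)
from .nnops import Adam, relu

SCENARIO_TAGS = ("ambig_match", "unambig_match", "unambig_irrel",
                 "ambig_irrel", "unambig_contra")
SCENARIO_INDEX = {tag: s for s, tag in enumerate(SCENARIO_TAGS, start=1)}

__all__ = [
    "SCENARIO_TAGS",
    "SCENARIO_INDEX",
    "ScenarioBatch",
    "TrainState",
    "OracleContext",
    "SoftenedContext",
    "TemporalContext",
    "TripletTensors",
    "make_scenario_batch",
    "predict_scenario",
    "scenario_loss",
    "train_topdown",
    "evaluate_scenarios",
    "certainty_sweep",
]


# ---------------------------------------------------------------------------
# context sources
# ---------------------------------------------------------------------------

class OracleContext:
    """One-hot context over the C source classes."""

    def __init__(self, n_classes: int) -> None:
        self.n_classes = n_classes
        self.dim = n_classes

    def batch(self, classes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        return np.stack([onehot_context(int(y), self.n_classes).c for y in classes])


class SoftenedContext:
    """Context with a stated certainty on the target class; the residual
    mass is uniform over the other classes."""

    def __init__(self, n_classes: int, certainty: float) -> None:
        self.n_classes = n_classes
        self.dim = n_classes
        self.certainty = certainty
        soften_context(0, n_classes, certainty)  # validate eagerly

    def batch(self, classes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        return np.stack([
            soften_context(int(y), self.n_classes, self.certainty).c
            for y in classes
        ])


class TemporalContext:
    """Context realized as the final hidden state of a GRU fed a
    two-digit latent sequence whose modulo-K sum equals the context
    class."""

    def __init__(self, gru: ContextGRU, latents_by_class: dict[int, np.ndarray],
                 n_classes: int) -> None:
        if not gru.trained:
            raise ValueError("temporal context needs a trained GRU")
        self.gru = gru
        self.latents_by_class = latents_by_class
        self.n_classes = n_classes
        self.dim = gru.hidden_size

    def batch(self, classes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        K = self.n_classes
        seq = np.empty((len(classes), 2, self.gru.input_dim))
        for i, y in enumerate(classes):
            d1 = int(rng.integers(K))
            d2 = (int(y) - d1) % K
            pool1 = self.latents_by_class[d1]
            pool2 = self.latents_by_class[d2]
            seq[i, 0] = pool1[rng.integers(len(pool1))]
            seq[i, 1] = pool2[rng.integers(len(pool2))]
        return self.gru.hidden(seq)


ContextSource = OracleContext | SoftenedContext | TemporalContext


# ---------------------------------------------------------------------------
# triplet tensors and scenario batches
# ---------------------------------------------------------------------------

class TripletTensors:
    """Precomputed basal vectors and naive latents for a triplet list."""

    def __init__(self, encoder: BackboneEncoder, proj: Projection,
                 triplets: Sequence[AmbiguousTriplet]) -> None:
        if len(triplets) == 0:
            raise ValueError("empty triplet list")
        if not encoder.frozen:
            raise ValueError("encoder must be frozen")
        X0 = np.stack([t.x0.pixels.reshape(-1) for t in triplets])
        X1 = np.stack([t.x1.pixels.reshape(-1) for t in triplets])
        XA = np.stack([t.x_ambig.pixels.reshape(-1) for t in triplets])
        self.b0 = encoder.basal(X0)
        self.b1 = encoder.basal(X1)
        self.ba = encoder.basal(XA)
        self.mu0 = project_mu(proj, relu(self.b0))
        self.mu1 = project_mu(proj, relu(self.b1))
        self.mua = project_mu(proj, relu(self.ba))
        self.y0 = np.array([t.y0 for t in triplets], dtype=np.int64)
        self.y1 = np.array([t.y1 for t in triplets], dtype=np.int64)
        self.n_classes = int(max(self.y0.max(), self.y1.max())) + 1
        self.n = len(triplets)

    def latents_by_class(self) -> dict[int, np.ndarray]:
        """Unambiguous parent latents grouped by class (GRU input pool)."""
        out: dict[int, list[np.ndarray]] = {}
        for side_mu, side_y in ((self.mu0, self.y0), (self.mu1, self.y1)):
            for mu, y in zip(side_mu, side_y):
                out.setdefault(int(y), []).append(mu)
        return {k: np.stack(v) for k, v in out.items()}


@dataclass
class ScenarioBatch:
    """One minibatch for one input/context scenario."""

    scenario: str
    b: np.ndarray           # basal pre-activations of the inputs (B, n)
    mu_naive: np.ndarray    # U sigma(b) of the inputs (B, latent)
    c: np.ndarray           # context vectors (B, context_dim)
    target_mu: np.ndarray   # mu* per scenario (B, latent)
    context_class: np.ndarray  # context class id per example (B,)
    input_label: np.ndarray    # true label of unambiguous inputs; the
                               # context-matching parent for ambiguous ones
    pair: np.ndarray           # (B, 2) parent classes (y0, y1)


def _irrelevant_classes(y0: np.ndarray, y1: np.ndarray, n_classes: int,
                        rng: np.random.Generator) -> np.ndarray:
    if n_classes < 3:
        raise ValueError("irrelevant-context scenarios need >= 3 classes")
    out = np.empty(len(y0), dtype=np.int64)
    for i in range(len(y0)):
        choices = [c for c in range(n_classes) if c not in (y0[i], y1[i])]
        out[i] = choices[rng.integers(len(choices))]
    return out


def _build_batch(tt: TripletTensors, scenario: str, source: ContextSource,
                 idx: np.ndarray, rng: np.random.Generator,
                 contra_target: Literal["input", "context"] = "input"
                 ) -> ScenarioBatch:
    y0, y1 = tt.y0[idx], tt.y1[idx]
    side = rng.integers(2, size=len(idx))
    b_un = np.where(side[:, None] == 0, tt.b0[idx], tt.b1[idx])
    mu_un = np.where(side[:, None] == 0, tt.mu0[idx], tt.mu1[idx])
    y_un = np.where(side == 0, y0, y1)
    y_other = np.where(side == 0, y1, y0)
    mu_other = np.where(side[:, None] == 0, tt.mu1[idx], tt.mu0[idx])

    if scenario == "ambig_match":
        b, mu_naive = tt.ba[idx], tt.mua[idx]
        ctx, target, label = y_un, mu_un, y_un
    elif scenario == "unambig_match":
        b, mu_naive = b_un, mu_un
        ctx, target, label = y_un, mu_un, y_un
    elif scenario == "unambig_irrel":
        b, mu_naive = b_un, mu_un
        ctx = _irrelevant_classes(y0, y1, tt.n_classes, rng)
        target, label = mu_un, y_un
    elif scenario == "ambig_irrel":
        b, mu_naive = tt.ba[idx], tt.mua[idx]
        ctx = _irrelevant_classes(y0, y1, tt.n_classes, rng)
        target, label = tt.mua[idx], y_un
    elif scenario == "unambig_contra":
        b, mu_naive = b_un, mu_un
        ctx = y_other
        target = mu_un if contra_target == "input" else mu_other
        label = y_un
    else:
        raise ValueError(f"unknown scenario {scenario!r}")

    c = source.batch(ctx, rng)
    return ScenarioBatch(scenario=scenario, b=b, mu_naive=mu_naive, c=c,
                         target_mu=target, context_class=ctx,
                         input_label=label, pair=np.stack([y0, y1], axis=1))


def make_scenario_batch(encoder: BackboneEncoder, proj: Projection,
                        triplets: Sequence[AmbiguousTriplet], scenario: str,
                        context_source: ContextSource, batch_size: int,
                        seed: int,
                        contra_target: Literal["input", "context"] = "input"
                        ) -> ScenarioBatch:
    """Sample one scenario batch from a triplet dataset."""
    if scenario not in SCENARIO_TAGS:
        raise ValueError(f"unknown scenario {scenario!r}")
    tt = TripletTensors(encoder, proj, triplets)
    rng = np.random.default_rng(seed)
    idx = rng.integers(tt.n, size=batch_size)
    return _build_batch(tt, scenario, context_source, idx, rng, contra_target)


def predict_scenario(proj: Projection, g: TopDownNet, batch: ScenarioBatch,
                     rule: Rule = "hadamard") -> np.ndarray:
    """Predicted latents mu_hat for one scenario batch."""
    a = g.apical(batch.mu_naive, batch.c)
    if rule == "hadamard":
        h = relu(batch.b) * (1.0 + relu(a))
    elif rule == "additive":
        h = relu(batch.b) + relu(a)
    elif rule == "single_compartment":
        h = relu(batch.b + a)
    else:
        raise ValueError(f"unknown integration rule {rule!r}")
    return project_mu(proj, h)


def scenario_loss(mu_hat_by_scenario: dict[str, np.ndarray],
                  target_by_scenario: dict[str, np.ndarray]) -> float:
    """Scenario-summed squared error, averaged over the minibatch."""
    missing = [s for s in SCENARIO_TAGS if s not in mu_hat_by_scenario
               or s not in target_by_scenario]
    if missing:
        raise ValueError(f"missing scenarios: {missing}")
    total = 0.0
    for s in SCENARIO_TAGS:
        d = mu_hat_by_scenario[s] - target_by_scenario[s]
        total += float(np.mean(np.sum(d * d, axis=-1)))
    return total


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainState:
    g: TopDownNet
    step: int
    loss_history: list[float]
    per_scenario_loss: dict[str, list[float]] = field(default_factory=dict)
    backbone_digest_before: str = ""
    backbone_digest_after: str = ""
    readout_digest_before: str = ""
    readout_digest_after: str = ""


def train_topdown(encoder: BackboneEncoder, proj: Projection, g: TopDownNet,
                  triplets: Sequence[AmbiguousTriplet],
                  context_source: ContextSource, steps: int = 2000,
                  lr: float = 1e-3, seed: int = 0, batch_size: int = 32,
                  rule: Rule = "hadamard",
                  contra_target: Literal["input", "context"] = "input",
                  readout: Readout | None = None) -> TrainState:
    """Adam on g's parameters only, all five scenarios equally
    represented in every step (one shared triplet minibatch)."""
    if not encoder.frozen:
        raise ValueError("backbone must be frozen before top-down training")
    tt = TripletTensors(encoder, proj, triplets)
    rng = np.random.default_rng(seed)
    opt = Adam(g.params, lr=lr)
    state = TrainState(g=g, step=0, loss_history=[],
                       per_scenario_loss={s: [] for s in SCENARIO_TAGS},
                       backbone_digest_before=encoder.digest(),
                       readout_digest_before=readout.digest() if readout else "")
    for _ in range(steps):
        idx = rng.integers(tt.n, size=batch_size)
        opt.zero_grad()
        total = 0.0
        for s in SCENARIO_TAGS:
            batch = _build_batch(tt, s, context_source, idx, rng, contra_target)
            a = g.apical(batch.mu_naive, batch.c)
            sb = relu(batch.b)
            if rule == "hadamard":
                h = sb * (1.0 + relu(a))
            elif rule == "additive":
                h = sb + relu(a)
            elif rule == "single_compartment":
                h = relu(batch.b + a)
            else:
                raise ValueError(f"unknown integration rule {rule!r}")
            mu_hat = project_mu(proj, h)
            d = mu_hat - batch.target_mu
            loss_s = float(np.mean(np.sum(d * d, axis=-1)))
            gmu = 2.0 * d / len(idx)
            gh = gmu @ proj.U
            if rule == "hadamard":
                ga = gh * sb * (a > 0)
            elif rule == "additive":
                ga = gh * (a > 0)
            else:
                ga = gh * (batch.b + a > 0)
            g.net.backward(ga)
            state.per_scenario_loss[s].append(loss_s)
            total += loss_s
        opt.step()
        state.step += 1
        state.loss_history.append(total)
    state.backbone_digest_after = encoder.digest()
    state.readout_digest_after = readout.digest() if readout else ""
    return state


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def _accuracy_rows(preds: np.ndarray, batch: ScenarioBatch, scenario: str,
                   scoring: Literal["designated_parent", "either_parent"]
                   ) -> float:
    if scenario in ("ambig_baseline", "ambig_irrel"):
        if scoring == "either_parent":
            return float(np.mean((preds == batch.pair[:, 0])
                                 | (preds == batch.pair[:, 1])))
        # designated-parent score: one parent is the (uniformly random)
        # ground truth, so the accuracy is the exact expectation
        # 0.5 P(pred == y0) + 0.5 P(pred == y1)
        return float(np.mean(0.5 * (preds == batch.pair[:, 0])
                             + 0.5 * (preds == batch.pair[:, 1])))
    if scenario == "ambig_match":
        return float(np.mean(preds == batch.context_class))
    return float(np.mean(preds == batch.input_label))


def evaluate_scenarios(encoder: BackboneEncoder, proj: Projection,
                       g: TopDownNet, readout: Readout,
                       triplets: Sequence[AmbiguousTriplet],
                       context_source: ContextSource,
                       rule: Rule = "hadamard", seed: int = 0,
                       scoring: Literal["designated_parent",
                                        "either_parent"] = "designated_parent",
                       contra_target: Literal["input", "context"] = "input"
                       ) -> pd.DataFrame:
    """Readout accuracy per scenario plus the no-modulation baseline on
    ambiguous inputs. Ambiguous inputs are scored against the context
    class when context matches, and against a designated parent class
    otherwise (config-exposed)."""
    if readout is None:
        raise ValueError("a trained readout is required for evaluation")
    tt = TripletTensors(encoder, proj, triplets)
    idx = np.arange(tt.n)
    rows = []
    # no-modulation baseline on ambiguous inputs
    base_preds = readout.predict(tt.mua)
    base_batch = _build_batch(tt, "ambig_match", context_source, idx,
                              np.random.default_rng(seed + 1), contra_target)
    rows.append(("ambig_baseline",
                 _accuracy_rows(base_preds, base_batch, "ambig_baseline",
                                scoring), tt.n))
    for s in SCENARIO_TAGS:
        batch = _build_batch(tt, s, context_source, idx,
                             np.random.default_rng(seed + 1), contra_target)
        mu_hat = predict_scenario(proj, g, batch, rule)
        preds = readout.predict(mu_hat)
        rows.append((s, _accuracy_rows(preds, batch, s, scoring), tt.n))
    return pd.DataFrame(rows, columns=["scenario", "accuracy", "n"])


def certainty_sweep(encoder: BackboneEncoder, proj: Projection, g: TopDownNet,
                    readout: Readout, triplets: Sequence[AmbiguousTriplet],
                    certainties: Sequence[float], rule: Rule = "hadamard",
                    seed: int = 0) -> pd.DataFrame:
    """ambig.Match and unambig.Contra accuracy as contextual certainty
    varies (softened context), for the given integration rule."""
    tt = TripletTensors(encoder, proj, triplets)
    frames = []
    for p in certainties:
        source = SoftenedContext(tt.n_classes, p)
        df = evaluate_scenarios(encoder, proj, g, readout, triplets, source,
                                rule=rule, seed=seed)
        df = df[df.scenario.isin(["ambig_match", "unambig_contra"])].copy()
        df["certainty"] = p
        df["rule"] = rule
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
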