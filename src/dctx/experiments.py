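"""Canned fixture experiments: glyph task construction and full model
training in memory.

These are the package's reference study conditions: a 4-class glyph
alphabet, a class-conditioned generator producing 50%-band blends for
every class pair, a frozen VAE backbone, frozen readouts, and a
top-down network trained on the five input/context scenarios with
either oracle or temporal context. Both the test suite and
``scripts/acceptance.py`` run these functions; the pipeline driver adds
file I/O around the same steps.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from . import ambiguous as ag
from . import glyphs
from .model import (BackboneEncoder, ContextGRU, Projection, Readout,
                    TopDownNet, Rule, extended_categories,
                    pair_category_index, pretrain_backbone,
                    train_context_gru, train_readout)
from .scenarios import (OracleContext, TemporalContext, TrainState,
                        TripletTensors, train_topdown)

__all__ = ["FixtureTask", "OracleModel", "build_fixture_task",
           "train_oracle_model", "train_temporal_context",
           "make_sum_sequences"]


@dataclass
class FixtureTask:
    """Dataset side of a fixture run: glyphs, blends, triplets."""

    n_classes: int
    specs: list
    train_images: list
    test_images: list
    generator: ag.ConditionalGenerator
    ambiguity_filter: ag.AmbiguityFilter
    triplets_train: list
    triplets_test: list
    pairs: list[tuple[int, int]]


@dataclass
class OracleModel:
    """Trained model side: frozen backbone/readouts plus the top-down net."""

    encoder: BackboneEncoder
    proj: Projection
    readout: Readout           # over the K source classes
    readout_ext: Readout       # over singles + unordered pairs (bias-free)
    g: TopDownNet
    train_state: TrainState
    context: OracleContext | TemporalContext
    rule: Rule = "hadamard"
    gru: ContextGRU | None = None


def build_fixture_task(seed: int, n_classes: int = 4,
                       n_train_per_class: int = 150,
                       n_test_per_class: int = 40,
                       n_ambig_train_per_pair: int = 40,
                       n_ambig_test_per_pair: int = 15,
                       cvae_latent: int = 8, cvae_epochs: int = 150,
                       classifier_epochs: int = 25) -> FixtureTask:
    """Generate glyphs, train the conditional generator and ambiguity
    classifier, and assemble train/test triplets for every class pair."""
    specs = glyphs.make_glyph_alphabet(n_classes, seed)
    train_images = glyphs.make_dataset(specs, n_train_per_class, seed)
    test_images = glyphs.make_dataset(specs, n_test_per_class, seed + 500_009)

    gen = ag.train_cvae(train_images, latent_dim=cvae_latent,
                        epochs=cvae_epochs, seed=seed + 1)
    clf = ag.train_ambiguity_classifier(train_images,
                                        epochs=classifier_epochs,
                                        seed=seed + 2)
    filt = ag.AmbiguityFilter(classifier=clf)
    pairs = list(combinations(range(n_classes), 2))

    ambig_train = ag.make_ambiguous_dataset(
        gen, filt, pairs, n_ambig_train_per_pair, seed=seed + 3)
    ambig_test = ag.make_ambiguous_dataset(
        gen, filt, pairs, n_ambig_test_per_pair, seed=seed + 4)

    triplets_train = ag.build_triplets(train_images, ambig_train,
                                       pairing_seed=seed + 5)
    triplets_test = ag.build_triplets(test_images, ambig_test,
                                      pairing_seed=seed + 6)
    return FixtureTask(n_classes=n_classes, specs=specs,
                       train_images=train_images, test_images=test_images,
                       generator=gen, ambiguity_filter=filt,
                       triplets_train=triplets_train,
                       triplets_test=triplets_test, pairs=pairs)


def _extended_training_latents(encoder: BackboneEncoder, task: FixtureTask
                               ) -> tuple[np.ndarray, np.ndarray, int]:
    """Latents + labels over the extended alphabet (singles then pairs)."""
    K = task.n_classes
    X_un, y_un = glyphs.stack(task.train_images)
    mu_un = encoder.latent(X_un)
    amb = [t.x_ambig for t in task.triplets_train]
    X_amb, _ = glyphs.stack(amb)
    mu_amb = encoder.latent(X_amb)
    y_amb = np.array([pair_category_index(K, im.ambiguity[0], im.ambiguity[1])
                      for im in amb], dtype=np.int64)
    latents = np.concatenate([mu_un, mu_amb])
    labels = np.concatenate([y_un, y_amb])
    return latents, labels, len(extended_categories(K))


def train_oracle_model(task: FixtureTask, seed: int,
                       rule: Rule = "hadamard",
                       backbone_epochs: int = 50, n_units: int = 128,
                       latent_dim: int = 16, g_hidden: int = 128,
                       readout_epochs: int = 40, topdown_steps: int = 2500,
                       contra_target: str = "input") -> OracleModel:
    """Pretrain + freeze the backbone, train both readouts, then train
    the top-down network with oracle (one-hot) context."""
    encoder = pretrain_backbone(task.train_images, epochs=backbone_epochs,
                                seed=seed + 10, n_units=n_units,
                                latent_dim=latent_dim)
    proj = encoder.projection

    X_un, y_un = glyphs.stack(task.train_images)
    mu_un = encoder.latent(X_un)
    readout = train_readout(encoder, mu_un, y_un, task.n_classes,
                            epochs=readout_epochs, seed=seed + 11)
    lat_ext, lab_ext, C_ext = _extended_training_latents(encoder, task)
    readout_ext = train_readout(encoder, lat_ext, lab_ext, C_ext,
                                epochs=readout_epochs, seed=seed + 12)

    context = OracleContext(task.n_classes)
    g = TopDownNet(latent_dim=encoder.latent_dim, context_dim=context.dim,
                   n_units=encoder.n_units, hidden=g_hidden,
                   rng=np.random.default_rng(seed + 13), rule=rule)
    state = train_topdown(encoder, proj, g, task.triplets_train, context,
                          steps=topdown_steps, seed=seed + 14, rule=rule,
                          contra_target=contra_target, readout=readout)
    return OracleModel(encoder=encoder, proj=proj, readout=readout,
                       readout_ext=readout_ext, g=g, train_state=state,
                       context=context, rule=rule)


def make_sum_sequences(encoder: BackboneEncoder, proj: Projection,
                       images: list, n_sequences: int, seed: int
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Random two-digit latent sequences and their modulo-K sums."""
    X, y = glyphs.stack(images)
    mu = encoder.latent(X)
    K = int(y.max()) + 1
    rng = np.random.default_rng(seed)
    i1 = rng.integers(len(X), size=n_sequences)
    i2 = rng.integers(len(X), size=n_sequences)
    seq = np.stack([mu[i1], mu[i2]], axis=1)
    sums = (y[i1] + y[i2]) % K
    return seq, sums


def train_temporal_context(model: OracleModel, task: FixtureTask, seed: int,
                           n_sequences: int = 4000, gru_epochs: int = 40,
                           topdown_steps: int = 2500, g_hidden: int = 128
                           ) -> OracleModel:
    """Train the GRU sum-predictor, then retrain a top-down network that
    consumes the GRU hidden state as context."""
    seq, sums = make_sum_sequences(model.encoder, model.proj,
                                   task.train_images, n_sequences, seed + 20)
    gru = train_context_gru(model.encoder, seq, sums, epochs=gru_epochs,
                            seed=seed + 21)
    tt = TripletTensors(model.encoder, model.proj, task.triplets_train)
    context = TemporalContext(gru, tt.latents_by_class(), task.n_classes)
    g = TopDownNet(latent_dim=model.encoder.latent_dim,
                   context_dim=context.dim, n_units=model.encoder.n_units,
                   hidden=g_hidden, rng=np.random.default_rng(seed + 22))
    state = train_topdown(model.encoder, model.proj, g, task.triplets_train,
                          context, steps=topdown_steps, seed=seed + 23,
                          readout=model.readout)
    return OracleModel(encoder=model.encoder, proj=model.proj,
                       readout=model.readout, readout_ext=model.readout_ext,
                       g=g, train_state=state, context=context, gru=gru)
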