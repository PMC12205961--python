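"""Shared fixtures.

The heavyweight session fixtures build the reference 4-class glyph task
and train the full two-compartment model once; unit tests mostly use
tiny nets and synthetic arrays instead.
"""

import warnings

import numpy as np
import pytest

from dctx import glyphs
from dctx.experiments import (build_fixture_task, train_oracle_model,
                              train_temporal_context)
from dctx.model import pair_category_index, extended_categories
from dctx.nnops import relu
from dctx.relevance import lrp_relevance, relevance_sets


@pytest.fixture(scope="session")
def task1():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_fixture_task(seed=1)


@pytest.fixture(scope="session")
def model1(task1):
    return train_oracle_model(task1, seed=1)


@pytest.fixture(scope="session")
def temporal1(task1, model1):
    return train_temporal_context(model1, task1, seed=1)


@pytest.fixture(scope="session")
def relevance_bundle(task1, model1):
    """Per-category relevance maps and 95% sets on unmodulated rates."""
    enc = model1.encoder
    K = task1.n_classes
    cats = extended_categories(K)
    Xu, yu = glyphs.stack(task1.train_images)
    hu = relu(enc.basal(Xu))
    amb = [t.x_ambig for t in task1.triplets_train]
    Xa, _ = glyphs.stack(amb)
    ha = relu(enc.basal(Xa))
    amb_cat = np.array([pair_category_index(K, im.ambiguity[0], im.ambiguity[1])
                        for im in amb])
    maps = []
    for ci, cat in enumerate(cats):
        h = hu[yu == cat[0]] if len(cat) == 1 else ha[amb_cat == ci]
        if len(h) == 0:
            h = np.zeros((1, enc.n_units))
        maps.append(lrp_relevance(model1.readout_ext, h, ci, proj=model1.proj))
    sets = relevance_sets(maps)
    order = {ci: tuple(np.argsort(-m.scores.mean(axis=0), kind="stable"))
             for ci, m in enumerate(maps) if ci < K}
    return {"maps": maps, "sets": sets, "order": order}


@pytest.fixture(scope="session")
def mini_backbone():
    """A small, quickly pretrained backbone for plumbing tests."""
    from dctx.model import pretrain_backbone
    specs = glyphs.make_glyph_alphabet(3, 0)
    images = glyphs.make_dataset(specs, 60, 0)
    enc = pretrain_backbone(images, epochs=30, seed=0, n_units=48,
                            latent_dim=8, hidden=128)
    return enc, images, specs
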