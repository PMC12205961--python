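"""Scenario batches, the five-term objective, top-down training and
scenario evaluation."""

import numpy as np
import pytest

from dctx import glyphs
from dctx.ambiguous import build_triplets, generate_ambiguous, train_cvae
from dctx.model import Projection, TopDownNet, pretrain_backbone
from dctx.nnops import relu
from dctx.scenarios import (SCENARIO_TAGS, OracleContext, TripletTensors,
                            evaluate_scenarios, make_scenario_batch,
                            predict_scenario, scenario_loss, train_topdown)


@pytest.fixture(scope="module")
def tiny_world():
    """Three classes, a quick CVAE, backbone and triplets."""
    specs = glyphs.make_glyph_alphabet(3, seed=0)
    images = glyphs.make_dataset(specs, 40, seed=0)
    gen = train_cvae(images, latent_dim=6, epochs=8, seed=0, hidden=96)
    blends = []
    for (a, b) in ((0, 1), (0, 2), (1, 2)):
        blends += generate_ambiguous(gen, a, b, 10, (0.5, 0.5), seed=a * 3 + b)
    triplets = build_triplets(images, blends, pairing_seed=0)
    enc = pretrain_backbone(images, epochs=4, seed=0, n_units=32,
                            latent_dim=8, hidden=64)
    return enc, enc.projection, triplets


def test_scenario_targets_follow_the_objective(tiny_world):
    enc, proj, triplets = tiny_world
    ctx = OracleContext(3)
    tt = TripletTensors(enc, proj, triplets)
    # ambiguous input with irrelevant context: target is the blend's own
    # unmodulated latent
    b4 = make_scenario_batch(enc, proj, triplets, "ambig_irrel", ctx, 64, seed=1)
    assert np.allclose(b4.target_mu, b4.mu_naive)
    assert np.all(b4.context_class != b4.pair[:, 0])
    assert np.all(b4.context_class != b4.pair[:, 1])
    # matched ambiguous input: context is a parent class and the target is
    # that parent exemplar's latent (it differs from the blend's own latent)
    b1 = make_scenario_batch(enc, proj, triplets, "ambig_match", ctx, 64, seed=2)
    assert np.all((b1.context_class == b1.pair[:, 0])
                  | (b1.context_class == b1.pair[:, 1]))
    parent_pool = np.concatenate([tt.mu0, tt.mu1])
    for row in b1.target_mu:
        assert np.any(np.all(np.isclose(parent_pool, row), axis=1))
    assert not np.allclose(b1.target_mu, b1.mu_naive)
    # unambiguous matched/irrelevant/contradictory: target is input's own latent
    for tag in ("unambig_match", "unambig_irrel", "unambig_contra"):
        bb = make_scenario_batch(enc, proj, triplets, tag, ctx, 64, seed=3)
        assert np.allclose(bb.target_mu, bb.mu_naive)
    with pytest.raises(ValueError):
        make_scenario_batch(enc, proj, triplets, "nonsense", ctx, 8, seed=0)


def test_irrelevant_context_needs_three_classes(tiny_world):
    enc, proj, _ = tiny_world
    specs = glyphs.make_glyph_alphabet(2, seed=0)
    images = glyphs.make_dataset(specs, 30, seed=0)
    blends = [glyphs.morph_glyphs(specs[0], specs[1], 0.5, s) for s in range(6)]
    triplets = build_triplets(images, blends, pairing_seed=0)
    ctx = OracleContext(2)
    with pytest.raises(ValueError):
        make_scenario_batch(enc, proj, triplets, "unambig_irrel", ctx, 8, seed=0)


def test_predict_scenario_matches_per_example_loop(tiny_world):
    enc, proj, triplets = tiny_world
    ctx = OracleContext(3)
    g = TopDownNet(latent_dim=enc.latent_dim, context_dim=3,
                   n_units=enc.n_units, hidden=16,
                   rng=np.random.default_rng(1))
    batch = make_scenario_batch(enc, proj, triplets, "ambig_match", ctx, 16, seed=4)
    mu_hat = predict_scenario(proj, g, batch, "hadamard")
    for i in range(len(batch.b)):
        a_i = g.apical(batch.mu_naive[i:i + 1], batch.c[i:i + 1])[0]
        h_i = np.array([max(bj, 0.0) * (1.0 + max(aj, 0.0))
                        for bj, aj in zip(batch.b[i], a_i)])
        assert np.allclose(mu_hat[i], proj.U @ h_i)


def test_negative_apical_output_predicts_unmodulated_latent(tiny_world):
    enc, proj, triplets = tiny_world
    ctx = OracleContext(3)
    g = TopDownNet(latent_dim=enc.latent_dim, context_dim=3,
                   n_units=enc.n_units, hidden=16,
                   rng=np.random.default_rng(2))
    g.net.layers[-1].W.v[...] = 0.0
    g.net.layers[-1].b.v[...] = -2.0
    for tag in SCENARIO_TAGS:
        batch = make_scenario_batch(enc, proj, triplets, tag, ctx, 8, seed=5)
        assert np.allclose(predict_scenario(proj, g, batch), batch.mu_naive)


def test_scenario_loss_examples_and_loop_oracle():
    rng = np.random.default_rng(3)
    perfect = {s: rng.normal(size=(4, 5)) for s in SCENARIO_TAGS}
    assert scenario_loss(perfect, {s: v.copy() for s, v in perfect.items()}) == 0.0
    # unit offset on one example in one scenario, batch size 1
    mu = {s: np.zeros((1, 5)) for s in SCENARIO_TAGS}
    tg = {s: np.zeros((1, 5)) for s in SCENARIO_TAGS}
    mu["ambig_match"] = np.eye(5)[:1]
    assert scenario_loss(mu, tg) == 1.0
    # random tensors equal a scalar-loop recomputation
    mh = {s: rng.normal(size=(3, 4)) for s in SCENARIO_TAGS}
    tt = {s: rng.normal(size=(3, 4)) for s in SCENARIO_TAGS}
    ref = 0.0
    for s in SCENARIO_TAGS:
        for i in range(3):
            ref += sum((mh[s][i, j] - tt[s][i, j]) ** 2 for j in range(4)) / 3
    assert np.isclose(scenario_loss(mh, tt), ref)
    with pytest.raises(ValueError):
        scenario_loss({k: v for k, v in mh.items() if k != "ambig_match"}, tt)


def test_zero_loss_fixed_point_constructed_case():
    """With U = I (n=2) and g emitting the exact multiplicative
    correction, every scenario's predicted latent equals its target and
    the objective is exactly zero."""
    from dctx.scenarios import ScenarioBatch
    proj = Projection(U=np.eye(2))
    g = TopDownNet(latent_dim=2, context_dim=2, n_units=2, hidden=2,
                   rng=np.random.default_rng(0))
    b = np.array([[1.0, 2.0]])
    target = np.array([[2.0, 2.0]])
    required_a = target / relu(b) - 1.0  # [[1, 0]]: amplify neuron 0 only
    g.apical = lambda mu, c: np.broadcast_to(required_a, (len(mu), 2)).copy()
    mu_hat, tgt = {}, {}
    for s in SCENARIO_TAGS:
        batch = ScenarioBatch(scenario=s, b=b, mu_naive=relu(b) @ proj.U,
                              c=np.array([[1.0, 0.0]]), target_mu=target,
                              context_class=np.array([0]),
                              input_label=np.array([0]),
                              pair=np.array([[0, 1]]))
        mu_hat[s] = predict_scenario(proj, g, batch, "hadamard")
        tgt[s] = batch.target_mu
    assert scenario_loss(mu_hat, tgt) == 0.0


def test_topdown_gradient_matches_finite_differences(tiny_world):
    """Autodiff of the five-scenario objective w.r.t. the top-down
    parameters agrees with central finite differences on a tiny net."""
    enc, proj, triplets = tiny_world
    ctx = OracleContext(3)
    g = TopDownNet(latent_dim=enc.latent_dim, context_dim=3,
                   n_units=enc.n_units, hidden=4,
                   rng=np.random.default_rng(4))
    batches = {s: make_scenario_batch(enc, proj, triplets, s, ctx, 3, seed=6)
               for s in SCENARIO_TAGS}

    def loss_fn():
        mu_hat = {s: predict_scenario(proj, g, b) for s, b in batches.items()}
        return scenario_loss(mu_hat, {s: b.target_mu
                                      for s, b in batches.items()})

    for p in g.params:
        p.zero_grad()
    for s, batch in batches.items():
        a = g.apical(batch.mu_naive, batch.c)
        sb = relu(batch.b)
        h = sb * (1.0 + relu(a))
        d = h @ proj.U.T - batch.target_mu
        ga = ((2.0 * d / len(batch.b)) @ proj.U) * sb * (a > 0)
        g.net.backward(ga)
    eps = 1e-6
    rng = np.random.default_rng(5)
    for p in g.params:
        flat = p.v.reshape(-1)
        for idx in rng.choice(flat.size, size=min(12, flat.size), replace=False):
            old = flat[idx]
            flat[idx] = old + eps
            lp = loss_fn()
            flat[idx] = old - eps
            lm = loss_fn()
            flat[idx] = old
            num = (lp - lm) / (2 * eps)
            # atol allows for finite-difference steps that cross ReLU kinks
            assert np.isclose(p.g.reshape(-1)[idx], num, rtol=1e-4, atol=1e-5)


def test_train_topdown_freezes_upstream_and_is_deterministic(tiny_world):
    enc, proj, triplets = tiny_world
    ctx = OracleContext(3)

    def fresh_g():
        return TopDownNet(latent_dim=enc.latent_dim, context_dim=3,
                          n_units=enc.n_units, hidden=16,
                          rng=np.random.default_rng(7))

    s1 = train_topdown(enc, proj, fresh_g(), triplets, ctx, steps=40, seed=8)
    assert s1.loss_history[-1] < s1.loss_history[0]
    assert s1.backbone_digest_before == s1.backbone_digest_after
    # every scenario contributes a loss term at every step
    assert all(len(v) == 40 for v in s1.per_scenario_loss.values())
    s2 = train_topdown(enc, proj, fresh_g(), triplets, ctx, steps=40, seed=8)
    assert s1.loss_history == s2.loss_history
    enc.frozen = False
    with pytest.raises(ValueError):
        train_topdown(enc, proj, fresh_g(), triplets, ctx, steps=1, seed=0)
    enc.frozen = True


def test_evaluate_scenarios_table_shape_and_determinism(tiny_world):
    enc, proj, triplets = tiny_world
    ctx = OracleContext(3)
    g = TopDownNet(latent_dim=enc.latent_dim, context_dim=3,
                   n_units=enc.n_units, hidden=16,
                   rng=np.random.default_rng(9))
    from dctx.model import train_readout
    X, y = glyphs.stack(glyphs.make_dataset(glyphs.make_glyph_alphabet(3, 0),
                                            40, 0))
    ro = train_readout(enc, enc.latent(X), y, 3, epochs=20, seed=10)
    t1 = evaluate_scenarios(enc, proj, g, ro, triplets, ctx, seed=11)
    t2 = evaluate_scenarios(enc, proj, g, ro, triplets, ctx, seed=11)
    assert list(t1.scenario) == ["ambig_baseline", *SCENARIO_TAGS]
    assert t1.accuracy.between(0, 1).all()
    assert t1.equals(t2)
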