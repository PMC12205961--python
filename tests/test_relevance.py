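"""Relevance propagation, relevance sets, separability, amplitudes,
masking and representation metrics."""

import numpy as np
import pytest

from dctx.model import CompartmentState, Projection, Readout
from dctx.relevance import (RelevanceMap, RelevanceSet, amplitude_by_subset,
                            cosine_distance_profile, histogram_mutual_info,
                            lrp_relevance, mutual_info_apical_basal,
                            relevance_sets, separability, silhouette_by_pair,
                            tsne_projection)


def _linear_readout(n, C, rng):
    ro = Readout(n, C, hidden=n, rng=rng, bias=False)
    # collapse to a single linear map: first layer identity, second the map
    ro.net.layers[0].W.v[...] = np.eye(n)
    return ro


# ---------------------------------------------------------------------------
# relevance propagation
# ---------------------------------------------------------------------------

def test_lrp_one_layer_closed_form():
    """For a single linear readout with weight row w, relevance is h * w."""
    rng = np.random.default_rng(0)
    n, C = 6, 3
    ro = _linear_readout(n, C, rng)
    h = np.abs(rng.normal(size=(1, n))) + 0.1
    m = lrp_relevance(ro, h, class_id=1)
    w = ro.net.layers[1].W.v[:, 1]
    assert np.allclose(m.scores[0], h[0] * w, rtol=1e-4, atol=1e-8)
    # conservation up to the epsilon stabilizer
    assert np.allclose(m.scores.sum(axis=1), m.logits, rtol=1e-4)


def test_lrp_conservation_on_random_mlp_readout():
    """Relevance sums track the class logit even on an untrained net;
    the epsilon stabilizer only leaks where pre-activations nearly
    cancel, so the typical error is far below the worst case."""
    rng = np.random.default_rng(1)
    ro = Readout(8, 5, hidden=12, rng=rng, bias=False)
    h = rng.normal(size=(40, 8))
    rels = []
    for c in range(5):
        m = lrp_relevance(ro, h, c)
        nz = np.abs(m.logits) > 1e-9
        rels.extend(np.abs(m.scores.sum(axis=1) - m.logits)[nz]
                    / np.abs(m.logits)[nz])
    assert np.max(rels) < 1e-2
    assert np.median(rels) < 1e-4


def test_lrp_through_projection_and_edge_cases():
    rng = np.random.default_rng(2)
    proj = Projection(U=rng.normal(size=(4, 10)))
    ro = Readout(4, 3, hidden=6, rng=rng, bias=False)
    h = rng.normal(size=(7, 10))
    m = lrp_relevance(ro, h, 0, proj=proj)
    assert m.scores.shape == (7, 10)
    assert np.allclose(m.scores.sum(axis=1), m.logits, rtol=1e-3, atol=1e-8)
    z = lrp_relevance(ro, np.zeros((2, 10)), 0, proj=proj)
    assert np.array_equal(z.scores, np.zeros((2, 10)))
    with pytest.raises(ValueError):
        lrp_relevance(ro, h, 99, proj=proj)
    biased = Readout(10, 3, hidden=6, rng=rng, bias=True)
    with pytest.raises(ValueError):
        lrp_relevance(biased, h, 0)


# ---------------------------------------------------------------------------
# relevance sets
# ---------------------------------------------------------------------------

def _map_from_scores(scores, class_id=0):
    scores = np.atleast_2d(scores)
    return RelevanceMap(scores=scores, class_id=class_id,
                        logits=scores.sum(axis=1))


def test_relevance_sets_degenerate_and_uniform_cases():
    one_hot = np.zeros(20)
    one_hot[13] = 5.0
    (s,) = relevance_sets([_map_from_scores(one_hot)])
    assert s.members == (13,)
    uniform = np.ones(100)
    (s,) = relevance_sets([_map_from_scores(uniform)], coverage=0.95)
    assert len(s.members) == 95
    with pytest.raises(ValueError):
        relevance_sets([_map_from_scores(uniform)], coverage=0.0)


def test_relevance_sets_match_bruteforce_minimal_prefix():
    rng = np.random.default_rng(3)
    for trial in range(20):
        n = int(rng.integers(4, 65))
        r = rng.normal(size=n)
        (s,) = relevance_sets([_map_from_scores(r)], coverage=0.95)
        # brute force: grow the descending-sorted prefix until coverage
        order = sorted(range(n), key=lambda i: (-r[i], i))
        pos_total = np.clip(r, 0, None).sum()
        got, cum = [], 0.0
        for i in order:
            got.append(i)
            cum += max(r[i], 0.0)
            if cum >= 0.95 * pos_total - 1e-12:
                break
        assert list(s.members) == got
        # minimality: dropping the last member falls below coverage
        if len(s.members) > 1:
            kept = np.clip(r[list(s.members[:-1])], 0, None).sum()
            assert kept < 0.95 * pos_total


def test_separability_formula_and_matrix_invariants():
    mk = lambda cid, m: RelevanceSet(class_id=cid, members=tuple(m),
                                     coverage=0.95)
    sets = [mk(0, (1, 2, 3)), mk(1, (1, 2, 3)), mk(2, (4, 5)),
            mk(3, (4, 6))]
    sep = separability(sets).values
    assert sep[0, 1] == 0.0                       # identical sets
    assert sep[0, 2] == 1.0                       # disjoint non-empty sets
    assert np.isclose(sep[2, 3], 2.0 / 3.0)       # |∩|=1, |∪|=3
    # direct formula recheck for every entry
    for i in range(4):
        for j in range(4):
            si, sj = set(sets[i].members), set(sets[j].members)
            expect = 0.0 if i == j else 1 - len(si & sj) / len(si | sj)
            assert np.isclose(sep[i, j], expect)
    assert np.array_equal(sep, sep.T)
    assert np.all(np.diag(sep) == 0)
    assert sep.min() >= 0 and sep.max() <= 1
    with pytest.warns(UserWarning):
        both_empty = separability([mk(0, ()), mk(1, ())]).values
    assert both_empty[0, 1] == 0.0


# ---------------------------------------------------------------------------
# amplitudes and masking limits
# ---------------------------------------------------------------------------

def _state(a, b):
    from dctx.nnops import relu
    h = relu(b) * (1 + relu(a))
    return CompartmentState(b=b, a=a, h=h, mu=h)


def test_amplitude_normalization_properties():
    rng = np.random.default_rng(4)
    b = rng.normal(size=(30, 10))
    zero = {"s": _state(np.full((30, 10), -1.0), b)}
    tab = amplitude_by_subset(zero, {"first": range(5)}, "apical")
    assert (tab.amplitude == 0).all()
    uni = {"s": _state(np.ones((30, 10)), b)}
    tab = amplitude_by_subset(uni, {"first": range(5), "rest": range(5, 10)},
                              "apical")
    assert np.allclose(tab.amplitude, 1.0)
    with pytest.raises(ValueError):
        amplitude_by_subset(uni, {"bad": [99]}, "apical")


def test_mask_ablation_limits_are_exact(task1, model1, relevance_bundle):
    """k=0 reproduces unmasked accuracy; k=n reverts to the unmodulated
    baseline for both masking conditions."""
    from dctx.relevance import mask_apical_ablation
    from dctx.scenarios import TripletTensors, _build_batch
    enc, proj, g = model1.encoder, model1.proj, model1.g
    tt = TripletTensors(enc, proj, task1.triplets_test)
    batch = _build_batch(tt, "ambig_match", model1.context, np.arange(tt.n),
                         np.random.default_rng(0))
    n = enc.n_units
    tab = mask_apical_ablation(proj, g, model1.readout, batch,
                               relevance_bundle["order"], [0, n],
                               n_random_draws=3, seed=1)
    k0 = tab[tab["size"] == 0]
    assert k0.accuracy.nunique() == 1  # both conditions identical at k=0
    from dctx.nnops import relu
    from dctx.model import project_mu
    unmasked = float(np.mean(model1.readout.predict(
        project_mu(proj, relu(batch.b) * (1 + relu(g.apical(batch.mu_naive,
                                                            batch.c)))))
        == batch.context_class))
    assert np.allclose(k0.accuracy, unmasked)
    kn = tab[tab["size"] == n]
    baseline = float(np.mean(model1.readout.predict(
        project_mu(proj, relu(batch.b))) == batch.context_class))
    assert np.allclose(kn.accuracy, baseline)
    assert (kn.sd == 0).all()
    with pytest.raises(ValueError):
        mask_apical_ablation(proj, g, model1.readout, batch,
                             relevance_bundle["order"], [n + 1])


# ---------------------------------------------------------------------------
# representation metrics
# ---------------------------------------------------------------------------

def test_silhouette_far_and_identical_clusters():
    rng = np.random.default_rng(5)
    far = np.concatenate([rng.normal(0, 0.1, size=(30, 3)),
                          rng.normal(50, 0.1, size=(30, 3))])
    labels = np.array([0] * 30 + [1] * 30)
    tab = silhouette_by_pair(far, labels, [(0, 1)])
    assert tab.silhouette.iloc[0] > 0.95
    same = np.concatenate([rng.normal(0, 1, size=(40, 3)),
                           rng.normal(0, 1, size=(40, 3))])
    labels = np.array([0] * 40 + [1] * 40)
    tab = silhouette_by_pair(same, labels, [(0, 1)])
    assert abs(tab.silhouette.iloc[0]) < 0.15
    with pytest.raises(ValueError):
        silhouette_by_pair(far, np.zeros(60, dtype=int), [(0, 1)])


def test_cosine_distance_profile_formula():
    rng = np.random.default_rng(6)
    v = np.abs(rng.normal(size=8)) + 0.1
    states = {"x": CompartmentState(b=np.tile(v, (3, 1)),
                                    a=np.tile(-v, (3, 1)),
                                    h=np.tile(v, (3, 1)),
                                    mu=np.tile(v, (3, 1)))}
    with pytest.warns(UserWarning):
        # relu(-v) = 0: the zero-norm apical vector is defined as distance 1
        tab = cosine_distance_profile(v, states)
    by = dict(zip(tab.signal, tab.distance))
    assert np.isclose(by["basal"], 0.0, atol=1e-12)  # (v, v) -> 0
    assert np.isclose(by["rate"], 0.0, atol=1e-12)
    assert by["apical"] == 1.0
    # (v, -v) -> 2 on raw firing rates
    states2 = {"x": CompartmentState(b=np.tile(v, (2, 1)),
                                     a=np.tile(v, (2, 1)),
                                     h=np.tile(-v, (2, 1)),
                                     mu=np.tile(v, (2, 1)))}
    tab2 = cosine_distance_profile(v, states2)
    assert np.isclose(dict(zip(tab2.signal, tab2.distance))["rate"], 2.0)
    # random pairs match a direct recomputation
    X = np.abs(rng.normal(size=(10, 8))) + 0.1
    ref = np.abs(rng.normal(size=8)) + 0.1
    st = {"r": CompartmentState(b=X, a=X, h=X, mu=X)}
    tab3 = cosine_distance_profile(ref, st)
    got = dict(zip(tab3.signal, tab3.distance))["rate"]
    direct = np.mean([1 - ref @ x / (np.linalg.norm(ref) * np.linalg.norm(x))
                      for x in X])
    assert np.isclose(got, direct)


def test_mutual_information_limits_and_monotonicity():
    rng = np.random.default_rng(7)
    x = rng.normal(size=5000)
    indep = histogram_mutual_info(x, rng.normal(size=5000), n_bins=16)
    ident = histogram_mutual_info(x, x, n_bins=16)
    # MI(x, x) equals the entropy of the binned variable
    joint, edges = np.histogram(x, bins=16), None
    p = joint[0] / joint[0].sum()
    entropy = -np.sum(p[p > 0] * np.log(p[p > 0]))
    assert np.isclose(ident, entropy, rtol=1e-6)
    assert indep < 0.1 * ident
    # MI grows with correlation strength
    mis = []
    for rho in (0.0, 0.5, 0.9):
        y = rho * x + np.sqrt(1 - rho ** 2) * rng.normal(size=5000)
        mis.append(histogram_mutual_info(x, y, n_bins=16))
    assert mis[0] < mis[1] < mis[2]
    with pytest.raises(ValueError):
        histogram_mutual_info(x, x, n_bins=1)


def test_mutual_info_scenario_table_nonnegative():
    rng = np.random.default_rng(8)
    st = {"s1": CompartmentState(b=rng.normal(size=(50, 30)),
                                 a=rng.normal(size=(50, 30)),
                                 h=np.zeros((50, 30)), mu=np.zeros((50, 4)))}
    tab = mutual_info_apical_basal(st, n_bins=6)
    assert (tab.mutual_information >= 0).all()


def test_tsne_wrapper_determinism_and_cluster_recovery():
    rng = np.random.default_rng(9)
    X = np.concatenate([rng.normal(0, 0.3, size=(40, 6)),
                        rng.normal(8, 0.3, size=(40, 6))])
    e1 = tsne_projection(X, seed=0)
    e2 = tsne_projection(X, seed=0)
    assert np.array_equal(e1, e2)
    from sklearn.cluster import KMeans
    km = KMeans(n_clusters=2, n_init=10, random_state=0).fit_predict(e1)
    labels = np.array([0] * 40 + [1] * 40)
    agree = max(np.mean(km == labels), np.mean(km != labels))
    assert agree >= 0.9
    with pytest.raises(ValueError):
        tsne_projection(X[:5], seed=0)
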