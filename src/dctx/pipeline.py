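"""End-to-end pipeline driver: dataset -> generator -> backbone ->
readouts -> [GRU] -> top-down training -> evaluation -> analyses.

Every stage writes its artifact under the run directory together with a
stage key (a hash of the stage-relevant configuration and its upstream
keys). Re-running with an unchanged config reuses cached artifacts
bit-exactly; changing any upstream setting invalidates all downstream
stages. The final manifest records config snapshot, artifact checksums
and the package version."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import ambiguous as ag
from . import glyphs, idxio
from .checkpoints import file_digest, load_model, save_model
from .config import RunConfig
from .model import (TopDownNet, extended_categories, pair_category_index,
                    pretrain_backbone, train_context_gru, train_readout)
from .nnops import relu
from .relevance import (amplitude_by_subset, lrp_relevance,
                        mask_apical_ablation, mutual_info_apical_basal,
                        relevance_sets, separability, silhouette_by_pair)
from .scenarios import (SCENARIO_TAGS, OracleContext, SoftenedContext,
                        TemporalContext, TripletTensors, _build_batch,
                        evaluate_scenarios, train_topdown)
from .experiments import make_sum_sequences
from .model import CompartmentState, project_mu

__all__ = ["run_pipeline", "RunManifest"]


class RunManifest(dict):
    """Config snapshot, stage checksums and dataset fingerprints."""


def _stage_key(name: str, payload: dict, upstream: list[str]) -> str:
    blob = json.dumps({"stage": name, "cfg": payload, "up": upstream},
                      sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()


class _Cache:
    def __init__(self, out: Path) -> None:
        self.path = out / "stage_keys.json"
        self.keys = json.loads(self.path.read_text()) if self.path.exists() else {}

    def fresh(self, name: str, key: str, artifacts: list[Path]) -> bool:
        return self.keys.get(name) == key and all(a.exists() for a in artifacts)

    def record(self, name: str, key: str) -> None:
        self.keys[name] = key
        self.path.write_text(json.dumps(self.keys, indent=1, sort_keys=True))


def run_pipeline(cfg: RunConfig) -> RunManifest:
    cfg.validate()
    out = Path(cfg.out_dir)
    for sub in ("dataset", "checkpoints", "logs", "results"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    cache = _Cache(out)
    c = asdict(cfg)
    seed = cfg.seed

    # ---- stage 1: dataset ------------------------------------------------
    ds_cfg = {k: c[k] for k in ("dataset_kind", "n_classes",
                                "n_train_per_class", "n_test_per_class",
                                "idx_paths", "seed")}
    ds_key = _stage_key("dataset", ds_cfg, [])
    ds = out / "dataset"
    ds_files = [ds / f for f in ("train-images.idx", "train-labels.idx",
                                 "train-sidecar.json", "test-images.idx",
                                 "test-labels.idx", "test-sidecar.json")]
    if not cache.fresh("dataset", ds_key, ds_files):
        if cfg.dataset_kind == "fixtures":
            specs = glyphs.make_glyph_alphabet(cfg.n_classes, seed)
            train = glyphs.make_dataset(specs, cfg.n_train_per_class, seed)
            test = glyphs.make_dataset(specs, cfg.n_test_per_class,
                                       seed + 500_009)
        else:
            p = cfg.idx_paths
            train = idxio.load_idx_dataset(p["train_images"],
                                           p["train_labels"],
                                           p.get("train_sidecar"))
            test = idxio.load_idx_dataset(p["test_images"], p["test_labels"],
                                          p.get("test_sidecar"))
        idxio.save_dataset(*ds_files[0:3], train, params=ds_cfg)
        idxio.save_dataset(*ds_files[3:6], test, params=ds_cfg)
        cache.record("dataset", ds_key)
    train_images = idxio.load_idx_dataset(*ds_files[0:3])
    test_images = idxio.load_idx_dataset(*ds_files[3:6])
    n_classes = max(im.label for im in train_images) + 1

    # ---- stage 2: conditional generator + ambiguity classifier -----------
    gen_cfg = {k: c[k] for k in ("cvae_latent", "cvae_epochs",
                                 "classifier_epochs", "seed")}
    gen_key = _stage_key("generator", gen_cfg, [ds_key])
    gen_path = out / "checkpoints" / "cvae.npz"
    clf_path = out / "checkpoints" / "classifier.npz"
    if not cache.fresh("generator", gen_key, [gen_path, clf_path]):
        gen = ag.train_cvae(train_images, latent_dim=cfg.cvae_latent,
                            epochs=cfg.cvae_epochs, seed=seed + 1)
        clf = ag.train_ambiguity_classifier(train_images,
                                            epochs=cfg.classifier_epochs,
                                            seed=seed + 2)
        save_model(gen_path, gen, seed=seed + 1)
        save_model(clf_path, clf, seed=seed + 2)
        cache.record("generator", gen_key)
    gen = load_model(gen_path)
    filt = ag.AmbiguityFilter(classifier=load_model(clf_path),
                              center=cfg.ambiguity_center,
                              half_width=cfg.ambiguity_half_width)

    # ---- stage 3: ambiguous datasets + triplets ---------------------------
    amb_cfg = {k: c[k] for k in ("ambiguity_center", "ambiguity_half_width",
                                 "n_ambig_train_per_pair",
                                 "n_ambig_test_per_pair", "seed")}
    amb_key = _stage_key("ambiguous", amb_cfg, [ds_key, gen_key])
    amb_files = [ds / f for f in ("ambig-train-images.idx",
                                  "ambig-train-labels.idx",
                                  "ambig-train-sidecar.json",
                                  "ambig-test-images.idx",
                                  "ambig-test-labels.idx",
                                  "ambig-test-sidecar.json",
                                  "triplets-train.json",
                                  "triplets-test.json")]
    pairs = list(combinations(range(n_classes), 2))
    if not cache.fresh("ambiguous", amb_key, amb_files):
        amb_train = ag.make_ambiguous_dataset(gen, filt, pairs,
                                              cfg.n_ambig_train_per_pair,
                                              seed=seed + 3)
        amb_test = ag.make_ambiguous_dataset(gen, filt, pairs,
                                             cfg.n_ambig_test_per_pair,
                                             seed=seed + 4)
        idxio.save_dataset(*amb_files[0:3], amb_train, params=amb_cfg)
        idxio.save_dataset(*amb_files[3:6], amb_test, params=amb_cfg)
        tr = ag.build_triplets(train_images, amb_train, pairing_seed=seed + 5)
        te = ag.build_triplets(test_images, amb_test, pairing_seed=seed + 6)
        idxio.save_triplet_index(amb_files[6], tr, train_images, amb_train)
        idxio.save_triplet_index(amb_files[7], te, test_images, amb_test)
        cache.record("ambiguous", amb_key)
    amb_train = idxio.load_idx_dataset(*amb_files[0:3])
    amb_test = idxio.load_idx_dataset(*amb_files[3:6])
    triplets_train = idxio.load_triplet_index(amb_files[6], train_images,
                                              amb_train)
    triplets_test = idxio.load_triplet_index(amb_files[7], test_images,
                                             amb_test)

    # ---- stage 4: backbone -------------------------------------------------
    bb_cfg = {k: c[k] for k in ("latent_dim", "n_units", "backbone_epochs",
                                "seed")}
    bb_key = _stage_key("backbone", bb_cfg, [ds_key])
    bb_path = out / "checkpoints" / "backbone.npz"
    if not cache.fresh("backbone", bb_key, [bb_path]):
        encoder = pretrain_backbone(train_images, epochs=cfg.backbone_epochs,
                                    seed=seed + 10, n_units=cfg.n_units,
                                    latent_dim=cfg.latent_dim)
        save_model(bb_path, encoder, seed=seed + 10)
        cache.record("backbone", bb_key)
    encoder = load_model(bb_path)
    proj = encoder.projection

    # ---- stage 5: readouts -------------------------------------------------
    ro_cfg = {k: c[k] for k in ("readout_epochs", "seed")}
    ro_key = _stage_key("readout", ro_cfg, [bb_key, amb_key])
    ro_path = out / "checkpoints" / "readout.npz"
    ro_ext_path = out / "checkpoints" / "readout_ext.npz"
    if not cache.fresh("readout", ro_key, [ro_path, ro_ext_path]):
        X_un, y_un = glyphs.stack(train_images)
        mu_un = encoder.latent(X_un)
        readout = train_readout(encoder, mu_un, y_un, n_classes,
                                epochs=cfg.readout_epochs, seed=seed + 11)
        X_amb, _ = glyphs.stack(amb_train)
        mu_amb = encoder.latent(X_amb)
        y_amb = np.array([pair_category_index(n_classes, im.ambiguity[0],
                                              im.ambiguity[1])
                          for im in amb_train])
        readout_ext = train_readout(
            encoder, np.concatenate([mu_un, mu_amb]),
            np.concatenate([y_un, y_amb]),
            len(extended_categories(n_classes)),
            epochs=cfg.readout_epochs, seed=seed + 12)
        save_model(ro_path, readout, seed=seed + 11)
        save_model(ro_ext_path, readout_ext, seed=seed + 12)
        cache.record("readout", ro_key)
    readout = load_model(ro_path)
    readout_ext = load_model(ro_ext_path)

    # ---- stage 6: context source (+ GRU when temporal) ---------------------
    gru_key = ""
    gru_path = out / "checkpoints" / "gru.npz"
    tt_train = TripletTensors(encoder, proj, triplets_train)
    if cfg.context == "temporal":
        gru_cfg = {k: c[k] for k in ("gru_epochs", "n_sequences", "seed")}
        gru_key = _stage_key("gru", gru_cfg, [bb_key])
        if not cache.fresh("gru", gru_key, [gru_path]):
            seq, sums = make_sum_sequences(encoder, proj, train_images,
                                           cfg.n_sequences, seed + 20)
            gru = train_context_gru(encoder, seq, sums,
                                    epochs=cfg.gru_epochs, seed=seed + 21)
            save_model(gru_path, gru, seed=seed + 21)
            cache.record("gru", gru_key)
        gru = load_model(gru_path)
        context = TemporalContext(gru, tt_train.latents_by_class(), n_classes)
    elif cfg.context == "softened":
        context = SoftenedContext(n_classes, cfg.context_certainty)
    else:
        context = OracleContext(n_classes)

    # ---- stage 7: top-down training ----------------------------------------
    td_cfg = {k: c[k] for k in ("g_hidden", "rule", "context",
                                "context_certainty", "topdown_steps", "lr",
                                "contra_target", "seed")}
    td_key = _stage_key("topdown", td_cfg, [bb_key, ro_key, amb_key, gru_key])
    td_path = out / "checkpoints" / "topdown.npz"
    log_path = out / "logs" / "topdown.jsonl"
    if not cache.fresh("topdown", td_key, [td_path, log_path]):
        g = TopDownNet(latent_dim=encoder.latent_dim, context_dim=context.dim,
                       n_units=encoder.n_units, hidden=cfg.g_hidden,
                       rng=np.random.default_rng(seed + 13), rule=cfg.rule)
        state = train_topdown(encoder, proj, g, triplets_train, context,
                              steps=cfg.topdown_steps, lr=cfg.lr,
                              seed=seed + 14, rule=cfg.rule,
                              contra_target=cfg.contra_target,
                              readout=readout)
        assert state.backbone_digest_before == state.backbone_digest_after
        with open(log_path, "w") as fh:
            for i, loss in enumerate(state.loss_history):
                rec = {"step": i, "loss": loss}
                rec.update({s: state.per_scenario_loss[s][i]
                            for s in SCENARIO_TAGS})
                fh.write(json.dumps(rec) + "\n")
        save_model(td_path, g, seed=seed + 14)
        cache.record("topdown", td_key)
    g = load_model(td_path)

    # ---- stage 8: evaluation + analyses ------------------------------------
    res = out / "results"
    table = evaluate_scenarios(encoder, proj, g, readout, triplets_test,
                               context, rule=cfg.rule, seed=seed + 30,
                               scoring=cfg.scoring,
                               contra_target=cfg.contra_target)
    table.to_csv(res / "scenario_accuracy.tsv", sep="\t", index=False)

    analysis_meta = _run_analyses(cfg, encoder, proj, g, readout, readout_ext,
                                  train_images, amb_train, triplets_test,
                                  context, res, seed)

    manifest = RunManifest(
        package_version=__version__,
        config=c,
        stage_keys=dict(cache.keys),
        checksums={p.name: file_digest(p)
                   for p in sorted((out / "checkpoints").glob("*.npz"))},
        dataset_fingerprints={f.name: file_digest(f)
                              for f in ds_files + amb_files},
        analysis=analysis_meta,
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return manifest


def _run_analyses(cfg, encoder, proj, g, readout, readout_ext, train_images,
                  amb_train, triplets_test, context, res: Path,
                  seed: int) -> dict:
    """Relevance sets, separability, amplitudes, masking, silhouette, MI."""
    n_classes = max(im.label for im in train_images) + 1
    cats = extended_categories(n_classes)

    # per-category relevance over that category's unmodulated firing rates
    X_un, y_un = glyphs.stack(train_images)
    h_un = relu(encoder.basal(X_un))
    X_amb, _ = glyphs.stack(amb_train)
    h_amb = relu(encoder.basal(X_amb))
    amb_cat = np.array([pair_category_index(n_classes, im.ambiguity[0],
                                            im.ambiguity[1])
                        for im in amb_train])
    maps = []
    for ci, cat in enumerate(cats):
        h = h_un[y_un == cat[0]] if len(cat) == 1 else h_amb[amb_cat == ci]
        if len(h) == 0:
            h = np.zeros((1, encoder.n_units))
        maps.append(lrp_relevance(readout_ext, h, ci, proj=proj))
    sets = relevance_sets(maps, coverage=cfg.coverage)
    sep = separability(sets)
    pd.DataFrame(sep.values).to_csv(res / "separability.tsv", sep="\t",
                                    index=False)
    pd.DataFrame({
        "category": ["/".join(map(str, c)) for c in cats],
        "set_size": [len(s.members) for s in sets],
        "members": [" ".join(map(str, s.members)) for s in sets],
    }).to_csv(res / "relevance_sets.tsv", sep="\t", index=False)

    tt = TripletTensors(encoder, proj, triplets_test)
    idx = np.arange(tt.n)
    states = {}
    batches = {}
    for s in SCENARIO_TAGS:
        batch = _build_batch(tt, s, context, idx,
                             np.random.default_rng(seed + 41), cfg.contra_target)
        a = g.apical(batch.mu_naive, batch.c)
        h = relu(batch.b) * (1.0 + relu(a)) if cfg.rule == "hadamard" \
            else relu(batch.b) + relu(a)
        states[s] = CompartmentState(b=batch.b, a=a, h=h,
                                     mu=project_mu(proj, h))
        batches[s] = batch

    # amplitudes for the most frequent pair, by role subsets
    pair_counts = {}
    for t in triplets_test:
        pair_counts[(t.y0, t.y1)] = pair_counts.get((t.y0, t.y1), 0) + 1
    (pa, pb) = max(pair_counts, key=pair_counts.get)
    role_sets = {
        f"class_{pa}": sets[pa].members,
        f"class_{pb}": sets[pb].members,
        "ambiguous_pair": sets[pair_category_index(n_classes, pa, pb)].members,
    }
    used = set().union(*role_sets.values()) if role_sets else set()
    role_sets["other"] = tuple(i for i in range(encoder.n_units)
                               if i not in used)
    amp = pd.concat([amplitude_by_subset(states, role_sets, comp)
                     for comp in ("apical", "basal")], ignore_index=True)
    amp.to_csv(res / "amplitude.tsv", sep="\t", index=False)

    # masking ablation on the matched-context ambiguous batch
    order = {ci: tuple(np.argsort(-m.scores.mean(axis=0), kind="stable"))
             for ci, m in enumerate(maps) if ci < n_classes}
    mask_sizes = [k for k in cfg.mask_sizes if k <= encoder.n_units]
    mask = mask_apical_ablation(proj, g, readout, batches["ambig_match"],
                                order, mask_sizes,
                                n_random_draws=cfg.n_random_draws,
                                seed=seed + 42, rule=cfg.rule)
    mask.to_csv(res / "masking.tsv", sep="\t", index=False)

    # silhouette per pair: ambiguous latents before/after modulation,
    # grouped by the matching context class
    rows = []
    bm = batches["ambig_match"]
    mu_mod = states["ambig_match"].mu
    for (i, j) in combinations(range(n_classes), 2):
        m = ((bm.pair[:, 0] == i) & (bm.pair[:, 1] == j))
        labels = bm.context_class[m]
        if np.sum(labels == i) < 2 or np.sum(labels == j) < 2:
            continue
        for which, lat in (("unmodulated", tt.mua[m]), ("modulated", mu_mod[m])):
            df = silhouette_by_pair(lat, labels, [(i, j)])
            rows.append((i, j, which, float(df.silhouette.iloc[0])))
    pd.DataFrame(rows, columns=["class_a", "class_b", "latent",
                                "silhouette"]).to_csv(
        res / "silhouette.tsv", sep="\t", index=False)

    mutual_info_apical_basal(states).to_csv(res / "mutual_information.tsv",
                                            sep="\t", index=False)
    return {"amplitude_pair": [int(pa), int(pb)],
            "n_test_triplets": int(tt.n),
            "set_sizes": [len(s.members) for s in sets]}
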