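"""Checkpoint (de)serialization.

Models are stored as a single ``.npz`` container with hierarchical
(slash-separated) array keys plus an embedded JSON header recording the
model kind, architecture hyperparameters, freeze status and training
seed. Parameter order is the class's own ``params`` list, which is
construction-deterministic."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .ambiguous import ConditionalGenerator, PixelClassifier
from .model import BackboneEncoder, ContextGRU, Readout, TopDownNet

__all__ = ["save_model", "load_model", "file_digest"]


def _meta_of(model) -> dict:
    if isinstance(model, BackboneEncoder):
        return {"kind": "backbone", "n_units": model.n_units,
                "latent_dim": model.latent_dim,
                "hidden": model.enc1.W.v.shape[1], "frozen": model.frozen}
    if isinstance(model, ConditionalGenerator):
        return {"kind": "cvae", "latent_dim": model.latent_dim,
                "n_classes": model.n_classes,
                "hidden": model.dec.layers[0].W.v.shape[1],
                "trained": model.trained}
    if isinstance(model, PixelClassifier):
        return {"kind": "pixel_classifier", "n_classes": model.n_classes,
                "hidden": model.net.layers[0].W.v.shape[1]}
    if isinstance(model, Readout):
        return {"kind": "readout", "n_classes": model.n_classes,
                "latent_dim": model.net.layers[0].W.v.shape[0],
                "hidden": model.net.layers[0].W.v.shape[1],
                "bias": model.net.layers[0].b is not None}
    if isinstance(model, TopDownNet):
        return {"kind": "topdown", "latent_dim": model.latent_dim,
                "context_dim": model.context_dim, "n_units": model.n_units,
                "hidden": model.net.layers[0].W.v.shape[1],
                "rule": model.rule}
    if isinstance(model, ContextGRU):
        return {"kind": "gru", "input_dim": model.input_dim,
                "hidden_size": model.hidden_size,
                "n_classes": model.head.W.v.shape[1],
                "trained": model.trained}
    raise TypeError(f"unsupported model type {type(model).__name__}")


def save_model(path, model, seed: int | None = None) -> None:
    meta = _meta_of(model)
    if seed is not None:
        meta["seed"] = seed
    arrays = {f"params/{i:03d}": p.v for i, p in enumerate(model.params)}
    arrays["meta/json"] = np.array(json.dumps(meta))
    np.savez(path, **arrays)


def _construct(meta: dict):
    rng = np.random.default_rng(0)  # placeholder init, overwritten below
    kind = meta["kind"]
    if kind == "backbone":
        m = BackboneEncoder(meta["n_units"], meta["latent_dim"],
                            meta["hidden"], rng)
        m.frozen = meta["frozen"]
        return m
    if kind == "cvae":
        m = ConditionalGenerator(meta["latent_dim"], meta["n_classes"],
                                 meta["hidden"], rng)
        m.trained = meta["trained"]
        return m
    if kind == "pixel_classifier":
        return PixelClassifier(meta["n_classes"], meta["hidden"], rng)
    if kind == "readout":
        return Readout(meta["latent_dim"], meta["n_classes"], meta["hidden"],
                       rng, bias=meta["bias"])
    if kind == "topdown":
        return TopDownNet(meta["latent_dim"], meta["context_dim"],
                          meta["n_units"], meta["hidden"], rng,
                          rule=meta["rule"])
    if kind == "gru":
        m = ContextGRU(meta["input_dim"], meta["n_classes"],
                       meta["hidden_size"], rng)
        m.trained = meta["trained"]
        return m
    raise ValueError(f"unknown checkpoint kind {kind!r}")


def load_model(path):
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta/json"]))
        model = _construct(meta)
        keys = sorted(k for k in data.files if k.startswith("params/"))
        params = model.params
        if len(keys) != len(params):
            raise ValueError(f"{path}: parameter count mismatch")
        for key, p in zip(keys, params):
            arr = data[key]
            if arr.shape != p.v.shape:
                raise ValueError(f"{path}: shape mismatch for {key}")
            p.v[...] = arr
    return model


def file_digest(path) -> str:
    import hashlib
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
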