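"""Run configuration: a JSON-serializable record that fully determines
a pipeline run (two runs with equal configs produce identical outputs).
The single top-level seed fans out to per-stage seeds by fixed offsets
inside the stage functions."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid run configuration."""


_RULES = ("hadamard", "additive", "single_compartment")
_CONTEXTS = ("oracle", "softened", "temporal")
_SCORING = ("designated_parent", "either_parent")


@dataclass
class RunConfig:
    # dataset
    dataset_kind: str = "fixtures"          # "fixtures" | "idx"
    n_classes: int = 4
    n_train_per_class: int = 150
    n_test_per_class: int = 40
    idx_paths: dict = field(default_factory=dict)  # for dataset_kind="idx"
    # generator / filter
    cvae_latent: int = 8
    cvae_epochs: int = 150
    classifier_epochs: int = 25
    ambiguity_center: float = 0.5
    ambiguity_half_width: float = 0.05
    n_ambig_train_per_pair: int = 40
    n_ambig_test_per_pair: int = 15
    # model
    latent_dim: int = 16
    n_units: int = 128
    g_hidden: int = 128
    rule: str = "hadamard"
    # context
    context: str = "oracle"                 # "oracle" | "softened" | "temporal"
    context_certainty: float = 1.0          # used when context == "softened"
    gru_epochs: int = 40
    n_sequences: int = 4000
    # training
    backbone_epochs: int = 50
    readout_epochs: int = 40
    topdown_steps: int = 2500
    lr: float = 1e-3
    contra_target: str = "input"            # "input" | "context"
    scoring: str = "designated_parent"
    # analysis
    coverage: float = 0.95
    mask_sizes: tuple = (0, 8, 16, 32, 64, 128)
    n_random_draws: int = 5
    # bookkeeping
    seed: int = 0
    out_dir: str = "runs/default"

    def validate(self) -> "RunConfig":
        if self.dataset_kind not in ("fixtures", "idx"):
            raise ConfigError(f"unknown dataset kind {self.dataset_kind!r}")
        if self.dataset_kind == "idx":
            needed = {"train_images", "train_labels", "test_images",
                      "test_labels"}
            missing = needed - set(self.idx_paths)
            if missing:
                raise ConfigError(f"idx dataset needs paths: {sorted(missing)}")
            for key, p in self.idx_paths.items():
                if not Path(p).exists():
                    raise ConfigError(f"idx path for {key!r} does not exist: {p}")
        if not (3 <= self.n_classes <= 36):
            raise ConfigError("n_classes must lie in [3, 36] (irrelevant-"
                              "context scenarios need a third class)")
        if self.rule not in _RULES:
            raise ConfigError(f"rule must be one of {_RULES}")
        if self.context not in _CONTEXTS:
            raise ConfigError(f"context must be one of {_CONTEXTS}")
        if self.scoring not in _SCORING:
            raise ConfigError(f"scoring must be one of {_SCORING}")
        if self.contra_target not in ("input", "context"):
            raise ConfigError("contra_target must be 'input' or 'context'")
        if not (0.0 < self.coverage <= 1.0):
            raise ConfigError("coverage must lie in (0, 1]")
        if any(k < 0 or k > self.n_units for k in self.mask_sizes):
            raise ConfigError("mask sizes must lie in [0, n_units]")
        return self

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        if "mask_sizes" in data:
            data["mask_sizes"] = tuple(data["mask_sizes"])
        return cls(**data).validate()
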