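"""Run configuration: one YAML file drives the whole pipeline.

Sections: ``sim`` (synthetic campaign), ``data`` (windowing/split),
``features`` (selection settings and baseline choice), ``model`` (ModelSpec
fields), ``train`` (TrainConfig fields), ``eval`` (outputs), plus a global
``seed`` that every section inherits unless it sets its own.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .data import SplitSpec
from .models import ModelSpec, TrainConfig
from .synth import SimConfig, default_style_bank


@dataclass
class RunConfig:
    seed: int = 0
    log_level: str = "INFO"
    # sim
    n_classes: int = 6
    n_subjects: int = 8
    duration_s: float = 60.0
    sample_rate_hz: float = 50.0
    # data
    T: int = 150
    overlap_fraction: float = 0.0
    standardization_scope: str = "recording"
    split_mode: str = "segment_random"
    test_fraction: float = 0.2
    val_fraction: float = 0.15
    # features
    run_features: bool = False
    fdr_q: float = 0.05
    top_k: int = 180
    baselines: tuple = ("naive_bayes",)
    # model
    run_deep: bool = True
    arch: str = "lstm_att"
    hidden_size: int | None = 64
    embed_size: int = 64
    dropout_rate: float = 0.2
    # train
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 20
    early_stop_patience: int = 5
    # eval
    n_attention_traces: int = 2
    export_tsne: bool = False

    _KNOWN = None  # filled after class creation

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        flat = {}
        for key, value in raw.items():
            if isinstance(value, dict):  # sectioned layout
                for k, v in value.items():
                    flat[k] = v
            else:
                flat[key] = value
        known = {f for f in cls.__dataclass_fields__}
        for k in flat:
            if k not in known:
                raise ValueError(f"unknown config key {k!r}")
        if "baselines" in flat:
            flat["baselines"] = tuple(flat["baselines"])
        return cls(**flat)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["baselines"] = list(d["baselines"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    # -- section views ------------------------------------------------------

    def sim_config(self) -> SimConfig:
        return SimConfig(
            styles=default_style_bank(self.n_classes),
            n_subjects=self.n_subjects,
            duration_s=self.duration_s,
            sample_rate_hz=self.sample_rate_hz,
            seed=self.seed,
        )

    def split_spec(self) -> SplitSpec:
        return SplitSpec(
            mode=self.split_mode, test_fraction=self.test_fraction,
            seed=self.seed,
        )

    def model_spec(self) -> ModelSpec:
        return ModelSpec(
            arch=self.arch,
            T=self.T,
            D=6,
            n_classes=self.n_classes,
            hidden_size=self.hidden_size,
            embed_size=self.embed_size,
            dropout_rate=self.dropout_rate,
            seed=self.seed,
        )

    def train_config(self) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            early_stop_patience=self.early_stop_patience,
            seed=self.seed,
        )
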