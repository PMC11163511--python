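"""Model presets and YAML run configuration.

Two presets are shipped: ``full`` mirrors the reference architecture
(ResNetV2-50-like widths 64/256/512/1024, ViT-Base-like bridge with
D=768, L=12, h=12 over a 14x14 bottleneck) and ``tiny`` is a
CPU-friendly reduction (widths 8/16/32/64, D=64, L=2, h=4) used for
tests and smoke training.  A run config is a YAML file with optional
``model`` / ``train`` / ``augmentation`` override sections applied on
top of a preset; unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any

import yaml

from .bridge import BridgeConfig
from .data.augment import AugmentationConfig
from .encoder import EncoderConfig
from .model import ModelConfig
from .training import TrainConfig


def full_model_config(ref_input_size: tuple[int, int] = (224, 224)) -> ModelConfig:
    return ModelConfig(
        encoder=EncoderConfig(stage_channels=(64, 256, 512, 1024),
                              units_per_block=(3, 4, 6), gn_groups=32,
                              bottleneck_expansion=4),
        bridge=BridgeConfig(patch_size=1, hidden_dim=768, n_layers=12,
                            n_heads=12, mlp_ratio=4.0),
        decoder_channels=(64, 128, 256, 512),
        ref_input_size=ref_input_size)


def tiny_model_config(ref_input_size: tuple[int, int] = (96, 96)) -> ModelConfig:
    return ModelConfig(
        encoder=EncoderConfig(stage_channels=(8, 16, 32, 64),
                              units_per_block=(1, 1, 1), gn_groups=4,
                              bottleneck_expansion=2),
        bridge=BridgeConfig(patch_size=1, hidden_dim=64, n_layers=2,
                            n_heads=4, mlp_ratio=2.0),
        decoder_channels=(8, 16, 32, 64),
        ref_input_size=ref_input_size)


MODEL_PRESETS = {"full": full_model_config, "tiny": tiny_model_config}


@dataclasses.dataclass
class RunConfig:
    preset: str = "tiny"
    seed: int = 0
    data_root: str | None = None
    val_root: str | None = None
    out_dir: str | None = None
    model: ModelConfig = None  # type: ignore[assignment]
    train: TrainConfig = dataclasses.field(default_factory=TrainConfig)
    augmentation: AugmentationConfig | None = None

    def __post_init__(self):
        if self.preset not in MODEL_PRESETS:
            raise ValueError(
                f"unknown preset '{self.preset}'; choose from "
                f"{sorted(MODEL_PRESETS)}")
        if self.model is None:
            self.model = MODEL_PRESETS[self.preset]()


_SECTIONS = {"preset", "seed", "data_root", "val_root", "out_dir",
             "model", "train", "augmentation"}


def _apply_overrides(obj, overrides: dict[str, Any], section: str):
    valid = {f.name for f in dataclasses.fields(obj)}
    unknown = set(overrides) - valid
    if unknown:
        raise ValueError(
            f"unknown {section} config keys {sorted(unknown)}; "
            f"valid keys: {sorted(valid)}")
    listy = {k: tuple(v) if isinstance(v, list) else v
             for k, v in overrides.items()}
    return dataclasses.replace(obj, **listy)


def load_run_config(path: str | Path | None = None,
                    overrides: dict[str, Any] | None = None) -> RunConfig:
    """Build a RunConfig from a YAML file plus flag-style overrides.

    Flag overrides take precedence over the file; both are validated
    against the dataclass fields.
    """
    raw: dict[str, Any] = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"run config {path} must be a YAML mapping")
        raw.update(loaded)
    for key, value in (overrides or {}).items():
        if isinstance(value, dict) and isinstance(raw.get(key), dict):
            raw[key].update(value)
        elif value is not None:
            raw[key] = value
    unknown = set(raw) - _SECTIONS
    if unknown:
        raise ValueError(f"unknown run config sections {sorted(unknown)}; "
                         f"valid sections: {sorted(_SECTIONS)}")

    cfg = RunConfig(preset=raw.get("preset", "tiny"),
                    seed=int(raw.get("seed", 0)),
                    data_root=raw.get("data_root"),
                    val_root=raw.get("val_root"),
                    out_dir=raw.get("out_dir"))
    if "model" in raw and raw["model"]:
        model_over = dict(raw["model"])
        if "encoder" in model_over:
            cfg.model = dataclasses.replace(
                cfg.model, encoder=_apply_overrides(
                    cfg.model.encoder, model_over.pop("encoder"), "encoder"))
        if "bridge" in model_over:
            cfg.model = dataclasses.replace(
                cfg.model, bridge=_apply_overrides(
                    cfg.model.bridge, model_over.pop("bridge"), "bridge"))
        cfg.model = _apply_overrides(cfg.model, model_over, "model")
    if "train" in raw and raw["train"]:
        cfg.train = _apply_overrides(cfg.train, raw["train"], "train")
    cfg.train = dataclasses.replace(cfg.train, seed=cfg.seed)
    if raw.get("augmentation"):
        aug = raw["augmentation"]
        cfg.augmentation = _apply_overrides(
            AugmentationConfig(), aug, "augmentation")
    return cfg


def dump_run_config(cfg: RunConfig, path: str | Path) -> None:
    blob = {
        "preset": cfg.preset,
        "seed": cfg.seed,
        "data_root": cfg.data_root,
        "val_root": cfg.val_root,
        "out_dir": cfg.out_dir,
        "model": cfg.model.to_dict(),
        "train": cfg.train.to_dict(),
        "augmentation": dataclasses.asdict(cfg.augmentation)
        if cfg.augmentation else None,
    }
    Path(path).write_text(yaml.safe_dump(blob, sort_keys=False, default_flow_style=None))
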