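"""Declarative run configuration: strict schema, YAML round-trip, dotted overrides.

A run is fully described by a :class:`RunConfig` loaded from YAML. Validation is
strict — an unknown key anywhere fails with the offending dotted path named,
because a silently ignored typo in a training config wastes a training run.
Command-line overrides use ``key.subkey=value`` with YAML-scalar value parsing,
applied after file values.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Any, Literal, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator


class StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class ConfigError(ValueError):
    """Raised for malformed configurations; message names the dotted path."""


class DataConfig(StrictModel):
    mode: Literal[
        "csv_manifest", "paired_folders", "suffix_convention", "presplit_folders"
    ] = "paired_folders"
    data_path: str = "."
    source_key: str = "source_path"
    target_key: str = "target_path"
    exclusion_key: Optional[str] = None
    weight_key: Optional[str] = None
    source_suffix: str = "_IM"
    target_suffix: str = "_GT"
    exclusion_suffix: str = "_EM"
    val_fraction: float = Field(default=0.2, ge=0.0, lt=1.0)
    portion_fraction: float = Field(default=1.0, gt=0.0, le=1.0)
    reload_every: int = Field(default=1, ge=1)
    cache_dir: Optional[str] = None


class TransformSpec(StrictModel):
    name: str
    params: dict[str, Any] = Field(default_factory=dict)
    deterministic: bool = True
    apply_to: Literal["source", "target", "both"] = "both"


class PatchSpec(StrictModel):
    patch_size: list[int] = Field(default_factory=lambda: [32, 32])
    patches_per_image: int = Field(default=1, ge=1)
    weighting: Literal["uniform", "foreground_weighted"] = "uniform"
    fg_ratio: float = Field(default=0.5, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _check(self):
        if any(p < 1 for p in self.patch_size):
            raise ValueError("patch_size entries must be >= 1")
        return self


class EmbedSegParams(StrictModel):
    center_mode: Literal["medoid", "centroid"] = "medoid"
    fg_threshold: float = 0.5
    seed_threshold: float = 0.9
    min_size: int = 2
    bg_margin: int = 8
    w_instance: float = 1.0
    w_sigma: float = 10.0
    w_seed: float = 1.0
    per_axis_sigma: bool = False


class FrameworkConfig(StrictModel):
    kind: Literal["fcn", "pix2pix", "cyclegan", "embedseg"] = "fcn"
    recon_loss: Literal["mae", "mse", "smooth_mae"] = "mae"
    adv_weight: float = Field(default=1.0, ge=0.0)
    recon_weight: float = Field(default=100.0, ge=0.0)
    cycle_weight: float = Field(default=10.0, ge=0.0)
    identity_weight: float = Field(default=5.0, ge=0.0)
    gan_objective: Literal["lsgan", "vanilla"] = "lsgan"
    generator_init: Optional[str] = None
    embedseg: EmbedSegParams = Field(default_factory=EmbedSegParams)
    task: Literal["regression", "segmentation", "instance"] = "regression"


class NetworkSpec(StrictModel):
    name: str = "unet_2d"
    dim: Literal[2, 3] = 2
    in_channels: int = Field(default=1, ge=1)
    out_channels: int = Field(default=1, ge=1)
    depth: int = Field(default=3, ge=1)
    base_filters: int = Field(default=16, ge=1)
    down_factors: Optional[list[list[int]]] = None
    norm: Literal["batch", "instance", "none"] = "instance"
    final_activation: Literal["none", "tanh", "sigmoid"] = "none"
    kwargs: dict[str, Any] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check(self):
        if self.down_factors is not None:
            for fs in self.down_factors:
                if len(fs) != self.dim:
                    raise ValueError(
                        "each down_factors entry needs one factor per spatial axis"
                    )
        return self


class TrainerConfig(StrictModel):
    max_epochs: int = Field(default=1, ge=1)
    steps_per_epoch: Optional[int] = Field(default=None, ge=1)
    seed: int = Field(default=42, ge=0)
    precision: Literal["32", "16-mixed"] = "32"
    batch_size: int = Field(default=4, ge=1)
    learning_rate: Union[float, dict[str, float]] = 1e-3
    swa_enabled: bool = False
    early_stop: Optional[int] = Field(default=None, ge=1)
    checkpoint_every: int = Field(default=1, ge=1)
    output_dir: str = "runs"

    @model_validator(mode="after")
    def _check(self):
        lrs = (
            self.learning_rate.values()
            if isinstance(self.learning_rate, dict)
            else [self.learning_rate]
        )
        if any(lr <= 0 for lr in lrs):
            raise ValueError("learning rates must be > 0")
        return self

    def lr_for(self, group: str, default: float) -> float:
        if isinstance(self.learning_rate, dict):
            return float(self.learning_rate.get(group, default))
        return float(self.learning_rate)


class InferenceSpec(StrictModel):
    window_size: Optional[list[int]] = None
    overlap: float = Field(default=0.25, ge=0.0, le=0.9)
    blend: Literal["gaussian", "uniform"] = "gaussian"
    gaussian_sigma_scale: float = Field(default=0.125, gt=0.0)
    output_dtype: str = "float32"
    un_normalize: bool = False


class RunConfig(StrictModel):
    data: DataConfig = Field(default_factory=DataConfig)
    preprocess: list[TransformSpec] = Field(default_factory=list)
    sampling: PatchSpec = Field(default_factory=PatchSpec)
    framework: FrameworkConfig = Field(default_factory=FrameworkConfig)
    network: NetworkSpec = Field(default_factory=NetworkSpec)
    trainer: TrainerConfig = Field(default_factory=TrainerConfig)
    inference: InferenceSpec = Field(default_factory=InferenceSpec)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(mode="json"), sort_keys=False)


def _known_paths(model_cls, prefix: str = "") -> set[str]:
    """All dotted field paths of a (nested) pydantic model."""
    paths: set[str] = set()
    for name, finfo in model_cls.model_fields.items():
        path = prefix + name
        paths.add(path)
        ann = finfo.annotation
        # unwrap Optional[X]
        for candidate in getattr(ann, "__args__", (ann,)):
            if isinstance(candidate, type) and issubclass(candidate, BaseModel):
                paths |= _known_paths(candidate, path + ".")
    return paths


def _set_dotted(tree: dict, dotted: str, value):
    parts = dotted.split(".")
    node = tree
    for p in parts[:-1]:
        if isinstance(node, list):
            node = node[int(p)]
        else:
            node = node.setdefault(p, {})
        if not isinstance(node, (dict, list)):
            raise ConfigError(f"cannot descend into non-mapping key {dotted!r}")
    last = parts[-1]
    if isinstance(node, list):
        node[int(last)] = value
    else:
        node[last] = value


def parse_overrides(overrides: list[str]) -> dict[str, Any]:
    """Parse ``key.subkey=value`` strings; values go through YAML scalar parsing."""
    parsed: dict[str, Any] = {}
    for ov in overrides:
        ov = ov.lstrip("-")
        if "=" not in ov:
            raise ConfigError(f"override {ov!r} is not of the form key.path=value")
        key, raw = ov.split("=", 1)
        parsed[key.strip()] = yaml.safe_load(raw)
    return parsed


def _format_validation_error(err: ValidationError) -> str:
    lines = []
    for e in err.errors():
        loc = ".".join(str(p) for p in e["loc"])
        if e["type"] == "extra_forbidden":
            lines.append(f"unknown config key {loc!r}")
        else:
            lines.append(f"invalid value for {loc!r}: {e['msg']}")
    return "; ".join(lines)


def load_config(
    path: str | os.PathLike | None = None,
    overrides: list[str] | None = None,
    base: dict | None = None,
) -> RunConfig:
    """Load a RunConfig from a YAML file, then apply dotted overrides.

    Unknown keys — in the file or in an override — fail with the full dotted
    path named. Values are coerced to field types by the schema.
    """
    if base is not None:
        tree = dict(base)
    elif path is not None:
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"config file not found: {p}")
        with open(p) as fh:
            tree = yaml.safe_load(fh) or {}
    else:
        tree = {}
    if not isinstance(tree, dict):
        raise ConfigError("config root must be a mapping")

    known = _known_paths(RunConfig)
    for key, value in parse_overrides(overrides or []).items():
        # list indices (e.g. preprocess.0.params.lo) are dropped when checking
        # against the schema; free-form dict fields (kwargs, params,
        # learning_rate) accept arbitrary leaves one level down
        schema_key = ".".join(p for p in key.split(".") if not p.isdigit())
        if schema_key not in known:
            parent = schema_key.rsplit(".", 1)[0] if "." in schema_key else ""
            if not (parent in known and _is_freeform(parent)):
                raise ConfigError(f"unknown config key {key!r}")
        _set_dotted(tree, key, value)

    try:
        return RunConfig.model_validate(tree)
    except ValidationError as err:
        raise ConfigError(_format_validation_error(err)) from None


def _is_freeform(dotted: str) -> bool:
    leaf = dotted.rsplit(".", 1)[-1]
    return leaf in {"kwargs", "params", "learning_rate"}


def normalize_config(path: str | os.PathLike) -> str:
    """Canonical YAML text of a config file (for round-trip checks)."""
    return load_config(path).to_yaml()
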