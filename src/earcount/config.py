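"""YAML run configuration with strict key checking and seed fan-out.

One global seed is fanned out deterministically to each stochastic stage
(segmentation, augmentation, model init, training, synthesis) by hashing the
stage name, so a single ``seed:`` value makes a whole run reproducible while
keeping the stage streams independent.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import yaml

from .cnn import CnnConfig, TrainConfig
from .counting import PreprocessConfig
from .dataset import AugmentationConfig
from .image_prep import EnhancementConfig
from .segmentation import SegmentationConfig
from .synthetic import SceneConfig

__all__ = ["RunConfig", "load_config", "stage_seed"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed in [0, 2^31) derived from the global seed."""
    return (int(global_seed) * 0x9E3779B1 + zlib.crc32(stage.encode())) % (2**31)


def _build(dc_cls, block: dict, context: str):
    """Instantiate a (frozen) config dataclass from a YAML mapping,
    rejecting unknown keys and converting lists to tuples where needed."""
    if block is None:
        block = {}
    if not isinstance(block, dict):
        raise ValueError(f"config block {context!r} must be a mapping")
    known = {f.name for f in fields(dc_cls)}
    unknown = set(block) - known
    if unknown:
        raise ValueError(
            f"unknown keys {sorted(unknown)} in config block {context!r}; "
            f"allowed: {sorted(known)}"
        )
    kwargs = {k: tuple(v) if isinstance(v, list) else v for k, v in block.items()}
    return dc_cls(**kwargs)


@dataclass(frozen=True)
class RunConfig:
    """All stage configurations plus the global seed."""

    seed: int = 0
    log_level: str = "INFO"
    out_dir: str = "."
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    cnn: CnnConfig = field(default_factory=CnnConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    synth: SceneConfig = field(default_factory=SceneConfig)

    def with_derived_seeds(self) -> "RunConfig":
        """Return a copy whose stage configs carry seeds derived from
        the global seed."""
        return replace(
            self,
            segmentation=replace(
                self.segmentation, seed=stage_seed(self.seed, "segmentation")
            ),
            augmentation=replace(
                self.augmentation, seed=stage_seed(self.seed, "augmentation")
            ),
            train=replace(self.train, seed=stage_seed(self.seed, "train")),
            synth=replace(self.synth, seed=stage_seed(self.seed, "synth")),
        )


_TOP_KEYS = {
    "seed",
    "log_level",
    "out_dir",
    "preprocess",
    "segmentation",
    "augmentation",
    "cnn",
    "train",
    "synth",
}


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML run configuration (all keys optional, unknown keys
    rejected)."""
    if path is None:
        return RunConfig().with_derived_seeds()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(
            f"unknown top-level config keys {sorted(unknown)}; allowed: "
            f"{sorted(_TOP_KEYS)}"
        )

    prep_block = dict(raw.get("preprocess") or {})
    enh_keys = {"clahe_clip", "clahe_tiles", "median_kernel"}
    enh_block = {k: prep_block.pop(k) for k in list(prep_block) if k in enh_keys}
    unknown = set(prep_block) - {"crop", "scale"}
    if unknown:
        raise ValueError(
            f"unknown keys {sorted(unknown)} in config block 'preprocess'"
        )
    preprocess = PreprocessConfig(
        crop=tuple(prep_block["crop"]) if prep_block.get("crop") else None,
        scale=tuple(prep_block["scale"]) if prep_block.get("scale") else None,
        enhancement=_build(EnhancementConfig, enh_block, "preprocess"),
    )

    cfg = RunConfig(
        seed=int(raw.get("seed", 0)),
        log_level=str(raw.get("log_level", "INFO")),
        out_dir=str(raw.get("out_dir", ".")),
        preprocess=preprocess,
        segmentation=_build(SegmentationConfig, raw.get("segmentation"), "segmentation"),
        augmentation=_build(AugmentationConfig, raw.get("augmentation"), "augmentation"),
        cnn=_build(CnnConfig, raw.get("cnn"), "cnn"),
        train=_build(TrainConfig, raw.get("train"), "train"),
        synth=_build(SceneConfig, raw.get("synth"), "synth"),
    )
    return cfg.with_derived_seeds()


def config_to_dict(cfg: RunConfig) -> dict:
    """RunConfig -> plain nested dict (for reproducibility manifests)."""

    def _plain(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: _plain(getattr(obj, f.name)) for f in fields(obj)}
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    return _plain(cfg)
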