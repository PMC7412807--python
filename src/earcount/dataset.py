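"""Four-class labeled patch datasets: loading, augmentation, balancing.

Patches are 100x100 RGB crops labeled by how many ears they contain
(0, 1, 2 or 3; multi-ear patches arise from adhesion of touching ears).
Class imbalance is typical — single-ear blobs dominate raw segmentation
output — so classes are balanced by augmenting each class up to a common
size with random crops, flips, rotations and brightness changes.  The
train/test split is made at the level of *source* patches before
augmentation, so augmented copies of one source never straddle the split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi

from .image_prep import load_image, resize, save_image

__all__ = [
    "LabeledPatch",
    "PatchDataset",
    "AugmentationConfig",
    "CLASS_DIRS",
    "load_labeled_patches",
    "augment_patch",
    "balance_and_split",
    "save_dataset",
]

# directory-name convention for the class-per-directory layout
CLASS_DIRS = {"0_ears": 0, "1_ear": 1, "2_ears": 2, "3_ears": 3}

PATCH_SIZE = (100, 100)


@dataclass(frozen=True)
class LabeledPatch:
    """One labeled classifier input: a patch, its ear count, and provenance."""

    patch: np.ndarray  # 100x100x3 uint8
    label: int  # ears in the patch, 0..3
    source_id: str

    def __post_init__(self) -> None:
        if self.label not in (0, 1, 2, 3):
            raise ValueError(f"label must be in 0..3, got {self.label}")


@dataclass(frozen=True)
class PatchDataset:
    """Balanced train/test patch lists with disjoint source provenance."""

    train: tuple[LabeledPatch, ...]
    test: tuple[LabeledPatch, ...]

    def per_class_counts(self, split: str = "train") -> tuple[int, int, int, int]:
        items = self.train if split == "train" else self.test
        counts = [0, 0, 0, 0]
        for p in items:
            counts[p.label] += 1
        return tuple(counts)


@dataclass(frozen=True)
class AugmentationConfig:
    """Random crop / flip / rotate / brightness augmentation parameters.

    crop_fraction is the retained *area* fraction of the random crop;
    rotation_degrees a symmetric range; brightness_range a multiplicative
    factor interval.  Rotations fill exposed corners by edge replication.
    """

    crop_fraction: float = 0.9
    allow_hflip: bool = True
    allow_vflip: bool = True
    rotation_degrees: float = 30.0
    brightness_range: tuple[float, float] = (0.7, 1.3)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.crop_fraction <= 1.0:
            raise ValueError(f"crop_fraction must be in (0, 1], got {self.crop_fraction}")
        if min(self.brightness_range) <= 0:
            raise ValueError("brightness bounds must be positive")
        if not 0.0 <= self.rotation_degrees <= 180.0:
            raise ValueError("rotation range must be within +/-180 degrees")


def load_labeled_patches(root: str | Path) -> list[LabeledPatch]:
    """Load a class-per-directory patch tree (``0_ears/ ... 3_ears/``).

    Labels come from the directory names; patches are resized to 100x100 if
    needed.  Unknown subdirectories are an error; non-image files inside a
    class directory are skipped with a warning.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} is not a directory")
    subdirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not subdirs:
        raise ValueError(f"dataset root {root} contains no class directories")
    patches: list[LabeledPatch] = []
    for d in subdirs:
        if d.name not in CLASS_DIRS:
            raise ValueError(
                f"unknown class directory {d.name!r}; expected one of {sorted(CLASS_DIRS)}"
            )
        label = CLASS_DIRS[d.name]
        for f in sorted(d.iterdir()):
            if not f.is_file():
                continue
            try:
                img = load_image(f)
            except ValueError:
                warnings.warn(f"skipping non-image file {f}", stacklevel=2)
                continue
            if img.shape[:2] != PATCH_SIZE:
                img = resize(img, *PATCH_SIZE)
            patches.append(LabeledPatch(patch=img, label=label, source_id=str(f)))
    if not patches:
        raise ValueError(f"no patches found under {root}")
    return patches


def augment_patch(
    p: LabeledPatch, cfg: AugmentationConfig, rng: np.random.Generator
) -> LabeledPatch:
    """One random augmentation of a patch; the label never changes.

    Applies, in order: random crop to ``crop_fraction`` of the area (resized
    back), random horizontal/vertical flips, a rotation drawn uniformly from
    the configured range (edge-replicated fill), and a multiplicative
    brightness factor with clipping to [0, 255].  Deterministic given the
    generator state.
    """
    img = p.patch
    h, w = img.shape[:2]

    # draw all random numbers unconditionally so the stream does not depend
    # on which augmentations are enabled
    crop_h = max(int(round(h * np.sqrt(cfg.crop_fraction))), 1)
    crop_w = max(int(round(w * np.sqrt(cfg.crop_fraction))), 1)
    r0 = int(rng.integers(0, h - crop_h + 1))
    c0 = int(rng.integers(0, w - crop_w + 1))
    do_hflip = bool(rng.random() < 0.5) and cfg.allow_hflip
    do_vflip = bool(rng.random() < 0.5) and cfg.allow_vflip
    angle = float(rng.uniform(-cfg.rotation_degrees, cfg.rotation_degrees))
    factor = float(rng.uniform(*cfg.brightness_range))

    if (crop_h, crop_w) != (h, w):
        img = resize(img[r0 : r0 + crop_h, c0 : c0 + crop_w], h, w)
    if do_hflip:
        img = img[:, ::-1]
    if do_vflip:
        img = img[::-1, :]
    if angle != 0.0:
        img = ndi.rotate(
            img.astype(np.float64),
            angle,
            axes=(0, 1),
            reshape=False,
            order=1,
            mode="nearest",
        )
        img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    if factor != 1.0:
        img = np.clip(np.rint(img.astype(np.float64) * factor), 0, 255).astype(np.uint8)
    return replace(p, patch=np.ascontiguousarray(img))


def _take_augmented(
    sources: list[LabeledPatch],
    total: int,
    cfg: AugmentationConfig,
    rng: np.random.Generator,
    include_originals: bool = True,
) -> list[LabeledPatch]:
    """Originals first (up to total), then augmentations sampled with
    replacement from the sources."""
    out: list[LabeledPatch] = []
    if include_originals:
        if len(sources) > total:
            idx = rng.choice(len(sources), size=total, replace=False)
            out.extend(sources[i] for i in sorted(idx))
        else:
            out.extend(sources)
    while len(out) < total:
        src = sources[int(rng.integers(0, len(sources)))]
        out.append(augment_patch(src, cfg, rng))
    return out


def balance_and_split(
    patches: list[LabeledPatch],
    per_class: int = 12000,
    test_per_class: int = 1000,
    cfg: AugmentationConfig | None = None,
) -> PatchDataset:
    """Balance all classes to ``per_class`` patches and hold out a test split.

    For each class, a subset of the *source* patches (proportional to the
    test share, at least one) is reserved for the test split; the splits are
    then filled to ``per_class - test_per_class`` and ``test_per_class``
    respectively with the originals plus random augmentations.  Because the
    reservation happens before augmentation, no source contributes to both
    splits.
    """
    cfg = cfg or AugmentationConfig()
    if not 0 <= test_per_class <= per_class:
        raise ValueError("need 0 <= test_per_class <= per_class")
    by_class: dict[int, list[LabeledPatch]] = {0: [], 1: [], 2: [], 3: []}
    for p in patches:
        by_class[p.label].append(p)
    for label, group in by_class.items():
        if not group:
            raise ValueError(f"class {label} has no source patches")

    rng = np.random.default_rng(cfg.seed)
    train: list[LabeledPatch] = []
    test: list[LabeledPatch] = []
    for label in range(4):
        group = list(by_class[label])
        order = rng.permutation(len(group))
        group = [group[i] for i in order]
        if test_per_class > 0:
            if len(group) < 2:
                raise ValueError(
                    f"class {label} needs >= 2 source patches for a "
                    "source-disjoint test split"
                )
            n_test_src = int(
                np.clip(round(len(group) * test_per_class / per_class), 1, len(group) - 1)
            )
            test_src = group[:n_test_src]
            train_src = group[n_test_src:]
            test.extend(_take_augmented(test_src, test_per_class, cfg, rng))
        else:
            train_src = group
        train.extend(_take_augmented(train_src, per_class - test_per_class, cfg, rng))

    train_ids = {p.source_id for p in train}
    test_ids = {p.source_id for p in test}
    if test_per_class > 0 and train_ids & test_ids:
        raise AssertionError("train/test source overlap — split bookkeeping bug")
    return PatchDataset(train=tuple(train), test=tuple(test))


def save_dataset(ds: PatchDataset, out_dir: str | Path) -> Path:
    """Write the class-per-directory layout plus a manifest.csv."""
    out_dir = Path(out_dir)
    inv = {v: k for k, v in CLASS_DIRS.items()}
    rows = ["path,label,split,source_id"]
    counters: dict[tuple[str, int], int] = {}
    for split, items in (("train", ds.train), ("test", ds.test)):
        for p in items:
            i = counters.get((split, p.label), 0)
            counters[(split, p.label)] = i + 1
            rel = Path(split) / inv[p.label] / f"{i:06d}.png"
            path = out_dir / rel
            path.parent.mkdir(parents=True, exist_ok=True)
            save_image(path, p.patch)
            rows.append(f"{rel},{p.label},{split},{p.source_id}")
    manifest = out_dir / "manifest.csv"
    manifest.write_text("\n".join(rows) + "\n")
    return manifest
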