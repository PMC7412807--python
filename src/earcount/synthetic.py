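"""Synthetic grain-filling canopy scenes with known ear counts.

Real labeled canopy photos are rarely shareable, so the generator emulates
the color structure the counting pipeline exploits: at grain filling, ears
are bright yellowish elongated blobs while leaves/stems are green and the
soil brown.  Scenes are soil-colored rasters with random green leaf strokes
and textured yellow ellipses for ears; a configurable fraction of ears is
placed as fused pairs/triples (overlapping ellipses forming one connected
blob) to exercise the adhesion mechanism that motivates the 0/1/2/3-ear
patch classes.  Every scene carries exact per-blob ground truth (mask,
centroid, multiplicity), and everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .dataset import LabeledPatch
from .image_prep import EnhancementConfig, enhance
from .segmentation import SegmentationConfig, segment_image

__all__ = [
    "SceneConfig",
    "BlobTruth",
    "SceneTruth",
    "generate_scene",
    "generate_patch_dataset",
]


@dataclass(frozen=True)
class SceneConfig:
    """Scene-generator knobs.

    ear_major/ear_minor are full axis-length ranges of the ear ellipses in
    pixels.  ``adhesion`` is the fraction of ears placed inside fused
    multi-ear blobs (group sizes drawn from ``adhesion_sizes``).  ``min_gap``
    is the minimum clearance between distinct blobs so that ground-truth
    blobs stay separable after morphology.  Colors are mean RGB triples with
    per-pixel jitter; the defaults keep the three palettes well separated in
    CIELAB (the "easy" regime); shrinking the ear/leaf contrast emulates the
    early grain-filling stage where segmentation degrades.
    """

    height: int = 700
    width: int = 700
    n_ears: int = 20
    adhesion: float = 0.0
    adhesion_sizes: tuple[int, ...] = (2, 3)
    ear_major: tuple[float, float] = (30.0, 60.0)
    ear_minor: tuple[float, float] = (10.0, 20.0)
    ear_color: tuple[int, int, int] = (212, 196, 88)
    ear_jitter: float = 10.0
    leaf_color: tuple[int, int, int] = (62, 124, 56)
    leaf_jitter: float = 14.0
    soil_color: tuple[int, int, int] = (118, 92, 62)
    soil_jitter: float = 8.0
    n_leaves: int = 40
    noise_sd: float = 3.0
    min_gap: int = 12
    max_attempts: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ears < 0:
            raise ValueError(f"n_ears must be >= 0, got {self.n_ears}")
        if not 0.0 <= self.adhesion <= 1.0:
            raise ValueError(f"adhesion must be in [0, 1], got {self.adhesion}")
        if any(s not in (2, 3) for s in self.adhesion_sizes):
            raise ValueError("adhesion group sizes must be 2 or 3")


@dataclass(frozen=True)
class BlobTruth:
    """Ground truth for one rendered blob."""

    centroid: tuple[float, float]
    multiplicity: int  # ears in this blob, 1..3
    mask: np.ndarray  # HxW bool


@dataclass(frozen=True)
class SceneTruth:
    total_ears: int
    blobs: tuple[BlobTruth, ...]


def _ellipse_mask(
    shape: tuple[int, int], cy: float, cx: float, a: float, b: float, theta: float
) -> np.ndarray:
    """Filled rotated ellipse with semi-axes a (major) and b (minor)."""
    h, w = shape
    r0 = max(int(np.floor(cy - a - 2)), 0)
    r1 = min(int(np.ceil(cy + a + 2)) + 1, h)
    c0 = max(int(np.floor(cx - a - 2)), 0)
    c1 = min(int(np.ceil(cx + a + 2)) + 1, w)
    mask = np.zeros(shape, dtype=bool)
    if r1 <= r0 or c1 <= c0:
        return mask
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dy = yy - cy
    dx = xx - cx
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    mask[r0:r1, c0:c1] = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return mask


def _group_multiplicities(cfg: SceneConfig, rng: np.random.Generator) -> list[int]:
    """Split n_ears into blob multiplicities honoring the adhesion fraction."""
    fused_target = int(round(cfg.adhesion * cfg.n_ears))
    groups: list[int] = []
    remaining = fused_target
    while remaining >= 2:
        choices = [s for s in cfg.adhesion_sizes if s <= remaining]
        if not choices:
            break
        s = int(rng.choice(choices))
        groups.append(s)
        remaining -= s
    singles = cfg.n_ears - sum(groups)
    groups.extend([1] * singles)
    return groups


def _render_blob(
    cfg: SceneConfig, rng: np.random.Generator, multiplicity: int
) -> np.ndarray:
    """A blob mask of 1-3 overlapping ellipses, cropped to its tight bbox."""
    a_axes = rng.uniform(*cfg.ear_major, size=multiplicity) / 2.0
    b_axes = rng.uniform(*cfg.ear_minor, size=multiplicity) / 2.0
    theta = rng.uniform(0, np.pi)
    canvas = int(np.ceil(2 * a_axes.max() + 1.1 * 2 * a_axes.sum() + 8))
    pos = np.array([canvas / 2.0, canvas / 2.0])
    mask = np.zeros((canvas, canvas), dtype=bool)
    # adhered neighbors overlap at an angle (ears cross or splay in nadir
    # view), so each subsequent ellipse branches 20-60 degrees off the
    # previous axis with ~45% center overlap: the blob stays one connected
    # component and keeps one visible lobe per ear
    for m in range(multiplicity):
        mask |= _ellipse_mask(
            (canvas, canvas), pos[0], pos[1], a_axes[m], b_axes[m], theta
        )
        if m + 1 < multiplicity:
            branch = rng.uniform(0.35, 1.05) * (1 if rng.random() < 0.5 else -1)
            theta = theta + branch
            step_dir = np.array([np.sin(theta), np.cos(theta)])
            pos = pos + step_dir * 0.55 * (a_axes[m] + a_axes[m + 1])
    rows, cols = np.nonzero(mask)
    return mask[rows.min() : rows.max() + 1, cols.min() : cols.max() + 1]


def _paint(
    img: np.ndarray,
    mask: np.ndarray,
    color: tuple[int, int, int],
    jitter: float,
    rng: np.random.Generator,
    speckle: float = 0.0,
) -> None:
    n = int(mask.sum())
    if n == 0:
        return
    vals = np.asarray(color, dtype=np.float64) + rng.normal(0, jitter, size=(n, 3))
    if speckle > 0:
        vals *= (1.0 + rng.normal(0, speckle, size=(n, 1)))
    img[mask] = np.clip(vals, 0, 255)


def _leaf_strokes(cfg: SceneConfig, rng: np.random.Generator, img: np.ndarray) -> None:
    h, w = cfg.height, cfg.width
    for _ in range(cfg.n_leaves):
        cy = rng.uniform(0, h)
        cx = rng.uniform(0, w)
        a = rng.uniform(30, 90)
        b = rng.uniform(3, 7)
        theta = rng.uniform(0, np.pi)
        m = _ellipse_mask((h, w), cy, cx, a, b, theta)
        _paint(img, m, cfg.leaf_color, cfg.leaf_jitter, rng)


def generate_scene(cfg: SceneConfig | None = None) -> tuple[np.ndarray, SceneTruth]:
    """Render one canopy scene and its ground truth.

    Blobs are rejection-placed so that, after dilation by ``cfg.min_gap``,
    no two blobs touch; raises RuntimeError if ``cfg.max_attempts``
    placements cannot fit all ears (lower n_ears or enlarge the scene).
    """
    cfg = cfg or SceneConfig()
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.height, cfg.width

    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = cfg.soil_color
    img += rng.normal(0, cfg.soil_jitter, size=(h, w, 3))
    _leaf_strokes(cfg, rng, img)

    occupancy = np.zeros((h, w), dtype=bool)
    gap_se = np.ones((cfg.min_gap, cfg.min_gap), dtype=bool)
    blobs: list[BlobTruth] = []
    attempts = 0
    for mult in _group_multiplicities(cfg, rng):
        placed = False
        while not placed:
            attempts += 1
            if attempts > cfg.max_attempts:
                raise RuntimeError(
                    f"could not place {cfg.n_ears} ears in a {h}x{w} scene after "
                    f"{cfg.max_attempts} attempts; reduce n_ears or enlarge the scene"
                )
            bmask = _render_blob(cfg, rng, mult)
            bh, bw = bmask.shape
            if bh >= h - 2 or bw >= w - 2:
                continue
            r0 = int(rng.integers(1, h - bh - 1))
            c0 = int(rng.integers(1, w - bw - 1))
            full = np.zeros((h, w), dtype=bool)
            full[r0 : r0 + bh, c0 : c0 + bw] = bmask
            grown = ndi.binary_dilation(full, structure=gap_se)
            if (grown & occupancy).any():
                continue
            occupancy |= grown
            _paint(img, full, cfg.ear_color, cfg.ear_jitter, rng, speckle=0.04)
            rows, cols = np.nonzero(full)
            blobs.append(
                BlobTruth(
                    centroid=(float(rows.mean()), float(cols.mean())),
                    multiplicity=mult,
                    mask=full,
                )
            )
            placed = True

    img += rng.normal(0, cfg.noise_sd, size=img.shape)
    out = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return out, SceneTruth(total_ears=cfg.n_ears, blobs=tuple(blobs))


def _label_regions_by_truth(
    regions, truth: SceneTruth, border_pad: int, shape: tuple[int, int]
) -> list[int]:
    """Ground-truth ear count of each segmented region.

    A truth blob is attributed to the region whose (unpadded) bounding box
    contains at least half of the blob's pixels — the same judgment a human
    labeler applies to a segmented patch ("how many ears are in this one?").
    Regions claiming no blob are false positives (label 0); regions whose
    attributed count exceeds 3 fall outside the label space and get -1.
    """
    labels = []
    for reg in regions:
        r0 = max(reg.bbox[0] - border_pad, 0)
        c0 = max(reg.bbox[1] - border_pad, 0)
        r1 = min(r0 + reg.bbox[2], shape[0])
        c1 = min(c0 + reg.bbox[3], shape[1])
        count = 0
        for blob in truth.blobs:
            inside = blob.mask[r0:r1, c0:c1].sum()
            if inside >= 0.5 * blob.mask.sum():
                count += blob.multiplicity
        labels.append(count if count <= 3 else -1)
    return labels


def generate_patch_dataset(
    per_class: int,
    cfg: SceneConfig | None = None,
    bbox_margin: int = 4,
    patch_size: tuple[int, int] = (100, 100),
    enhancement: EnhancementConfig | None = None,
) -> list[LabeledPatch]:
    """Labeled 0/1/2/3-ear patches harvested from the pipeline itself.

    Small scenes (350 px tiles, enhanced with a 4x4 CLAHE grid so the 87-px
    kernel matches a default 700x700 count scene) are run through the actual
    enhancement + K-means segmentation, and every resulting region patch is
    labeled with its ground-truth ear count by blob-overlap attribution.
    Training patches therefore have exactly the count-time distribution:
    tight single ears, fused 2/3-ear blobs, ears merged with bright leaves
    that joined the yellow cluster, and pure leaf/soil false positives
    (label 0).  Scene compositions alternate between triple-rich, pair-rich,
    dense-single, sparse-single and ear-free tiles until every class quota
    is met.  Balanced (``per_class`` each) and reproducible from
    ``cfg.seed``.
    """
    if per_class < 1:
        raise ValueError(f"per_class must be >= 1, got {per_class}")
    cfg = cfg or SceneConfig()
    tile = 350
    enhancement = enhancement or EnhancementConfig(clahe_tiles=(4, 4))
    rng = np.random.default_rng(cfg.seed)

    # scene recipes: (n_ears, adhesion, adhesion_sizes)
    recipes = {
        "triples": (12, 1.0, (3,)),
        "pairs": (12, 1.0, (2,)),
        "singles": (10, 0.0, (2, 3)),
        "sparse": (3, 0.0, (2, 3)),
        "empty": (0, 0.0, (2, 3)),
    }
    quota = {c: per_class for c in range(4)}
    out: list[LabeledPatch] = []
    counters = {c: 0 for c in range(4)}
    max_scenes = 40 * per_class  # generous cap; hit only on misconfiguration
    scenes_done = 0
    while any(v > 0 for v in quota.values()):
        if scenes_done >= max_scenes:
            raise RuntimeError(
                "patch harvest did not fill all class quotas; "
                f"remaining {quota} after {scenes_done} scenes"
            )
        scenes_done += 1
        # steer scene composition toward the neediest ear class
        need = max((1, 2, 3), key=lambda c: quota[c])
        if quota[need] <= 0:
            recipe = "empty"
        else:
            recipe = {1: "singles", 2: "pairs", 3: "triples"}[need]
            if recipe == "singles" and scenes_done % 3 == 0:
                recipe = "sparse"
        n_ears, adhesion, sizes = recipes[recipe]
        tile_cfg = SceneConfig(
            height=tile,
            width=tile,
            n_ears=n_ears,
            adhesion=adhesion,
            adhesion_sizes=sizes,
            ear_major=cfg.ear_major,
            ear_minor=cfg.ear_minor,
            ear_color=cfg.ear_color,
            ear_jitter=cfg.ear_jitter,
            leaf_color=cfg.leaf_color,
            leaf_jitter=cfg.leaf_jitter,
            soil_color=cfg.soil_color,
            soil_jitter=cfg.soil_jitter,
            n_leaves=10,
            noise_sd=cfg.noise_sd,
            min_gap=cfg.min_gap,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        scene, truth = generate_scene(tile_cfg)
        enhanced = enhance(scene, enhancement)
        segcfg = SegmentationConfig(
            seed=int(rng.integers(0, 2**31 - 1)),
            bbox_margin=bbox_margin,
            patch_size=patch_size,
        )
        regions, patches, _ = segment_image(enhanced, segcfg)
        labels = _label_regions_by_truth(
            regions, truth, segcfg.border_pad, (tile, tile)
        )
        for patch, label in zip(patches, labels):
            if label < 0 or quota[label] <= 0:
                continue
            quota[label] -= 1
            out.append(
                LabeledPatch(
                    patch=patch,
                    label=label,
                    source_id=f"synth-{label}-{counters[label]:05d}",
                )
            )
            counters[label] += 1
    out.sort(key=lambda p: p.source_id)
    return out
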