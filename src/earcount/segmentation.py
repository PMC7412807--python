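"""Candidate ear-region extraction by K-means color quantization.

At the grain-filling stage wheat ears are yellow and bright while stems and
leaves stay green and the soil is brown, so three K-means clusters in CIELAB
separate the scene into ear / vegetation / soil without training data.  Two
clusters would force the ear-to-background color transition zone into one of
the sides; three leave it a class of its own.  The cluster with the highest
b* (yellowness) is taken as the ear cluster, its mask is cleaned by a 6x6
morphological opening (specks, awn burrs) and a 3x3 closing (interior
holes), and 8-connected components of the cleaned mask become candidate ear
regions.  Each region's bounding box, expanded by a small margin, is cropped
from the enhanced color image and rescaled to a fixed patch size for the
downstream classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import measure
from sklearn.cluster import KMeans

from .image_prep import resize, rgb_to_lab

__all__ = [
    "SegmentationConfig",
    "QuantizedImage",
    "EarRegion",
    "kmeans_quantize",
    "select_ear_cluster",
    "binarize",
    "morph_clean",
    "extract_regions",
    "region_perimeter",
    "pad_border",
    "crop_patches",
    "segment_image",
]


@dataclass(frozen=True)
class SegmentationConfig:
    """Parameters of the segmentation stage.

    k: number of color clusters (3: ear / stem+leaf / soil).
    open_kernel / close_kernel: rectangular structuring-element sizes for the
        morphological opening and closing, in pixels.
    min_area: components smaller than this many pixels are discarded.
    border_pad: width of the frame added around the image before component
        extraction so ears touching the border remain separable.
    bbox_margin: expansion of each region's bounding box before cropping.
    patch_size: side of the square classifier input patch.
    """

    k: int = 3
    seed: int = 0
    max_iter: int = 100
    tol: float = 1e-4
    open_kernel: tuple[int, int] = (6, 6)
    close_kernel: tuple[int, int] = (3, 3)
    min_area: int = 50
    border_pad: int = 10
    bbox_margin: int = 4
    patch_size: tuple[int, int] = (100, 100)
    min_center_separation: float = 10.0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError(f"k must be >= 2, got {self.k}")
        if min(self.open_kernel) < 1 or min(self.close_kernel) < 1:
            raise ValueError("structuring elements must be at least 1x1")
        if self.min_area < 0:
            raise ValueError(f"min_area must be >= 0, got {self.min_area}")
        if self.border_pad < 0 or self.bbox_margin < 0:
            raise ValueError("border_pad and bbox_margin must be >= 0")


@dataclass(frozen=True)
class QuantizedImage:
    """K-means color quantization result.

    labels: HxW integer cluster index per pixel.
    centers: (k, 3) cluster centers in CIELAB.
    inertia: sum of squared Lab distances of pixels to their centers.
    """

    labels: np.ndarray
    centers: np.ndarray
    inertia: float

    @property
    def k(self) -> int:
        return self.centers.shape[0]


@dataclass(frozen=True)
class EarRegion:
    """One candidate ear blob.

    bbox is (row_min, col_min, height, width), 0-based, half-open; centroid
    is the (row, col) center of mass; area the pixel count; perimeter the
    length of the outer 8-connected boundary contour (diagonal steps weighted
    sqrt(2)).
    """

    bbox: tuple[int, int, int, int]
    centroid: tuple[float, float]
    area: int
    perimeter: float


def kmeans_quantize(img: np.ndarray, cfg: SegmentationConfig) -> QuantizedImage:
    """Cluster the image's pixels in CIELAB with seeded k-means++ Lloyd's.

    A single restart with an explicit seed keeps the segmentation
    bit-reproducible.  Returns per-pixel labels, the final centers and the
    final inertia.
    """
    if cfg.k < 2:
        raise ValueError(f"k must be >= 2, got {cfg.k}")
    lab = rgb_to_lab(img)
    h, w = lab.shape[:2]
    X = lab.reshape(-1, 3)
    km = KMeans(
        n_clusters=cfg.k,
        init="k-means++",
        n_init=1,
        max_iter=cfg.max_iter,
        tol=cfg.tol,
        random_state=cfg.seed,
    ).fit(X)
    return QuantizedImage(
        labels=km.labels_.reshape(h, w).astype(np.int32),
        centers=km.cluster_centers_.copy(),
        inertia=float(km.inertia_),
    )


def select_ear_cluster(q: QuantizedImage) -> int:
    """Index of the yellowest cluster center (max b*; ties -> larger L, then
    lower index).

    Ripe ears are the yellow, bright element of a grain-filling canopy, so
    the center with the largest CIELAB b* is the ear cluster.
    """
    if q.k < 2:
        raise ValueError("need at least 2 cluster centers")
    b = q.centers[:, 2]
    L = q.centers[:, 0]
    # lexicographic argmax over (b*, L, -index)
    order = sorted(range(q.k), key=lambda i: (b[i], L[i], -i))
    return order[-1]


def binarize(q: QuantizedImage, ear_idx: int) -> np.ndarray:
    """Binary ear mask: 1 where the pixel belongs to the ear cluster."""
    if not (0 <= ear_idx < q.k):
        raise ValueError(f"ear cluster index {ear_idx} out of range [0, {q.k})")
    return (q.labels == ear_idx).astype(np.uint8)


def _binary(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"expected a 2-D mask, got shape {mask.shape}")
    return mask.astype(bool)


def morph_clean(mask: np.ndarray, cfg: SegmentationConfig | None = None) -> np.ndarray:
    """Opening (6x6) then closing (3x3) with rectangular elements.

    The mask is padded before the scipy operations and cropped after, so the
    result equals the textbook set-theoretic opening/closing on an infinite
    background (no border artifacts from finite-domain erosion).
    """
    cfg = cfg or SegmentationConfig()
    m = _binary(mask)
    se_open = np.ones(cfg.open_kernel, dtype=bool)
    se_close = np.ones(cfg.close_kernel, dtype=bool)
    pad = max(*cfg.open_kernel, *cfg.close_kernel) + 1
    mp = np.pad(m, pad)
    mp = ndi.binary_opening(mp, structure=se_open)
    mp = ndi.binary_closing(mp, structure=se_close)
    return mp[pad:-pad, pad:-pad].astype(np.uint8)


_TRACE_OFFSETS = np.array(
    [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]
)
_SQRT2 = float(np.sqrt(2.0))


def region_perimeter(region_mask: np.ndarray) -> float:
    """Length of the outer 8-connected boundary contour of a single blob.

    Moore-neighbor tracing from the top-left foreground pixel; axial steps
    count 1, diagonal steps sqrt(2).  A single pixel (no boundary walk) has
    perimeter 0.
    """
    m = np.pad(_binary(region_mask), 1)
    fg = np.argwhere(m)
    if len(fg) == 0:
        return 0.0
    fg = fg[np.lexsort((fg[:, 1], fg[:, 0]))]
    start = (int(fg[0, 0]), int(fg[0, 1]))
    if len(fg) == 1:
        return 0.0
    # radial sweep: scan the 8 neighbors clockwise starting one past the
    # direction of the previous contour pixel; stop (Jacob's criterion) when
    # the start pixel is re-entered with the same outgoing direction
    cur = start
    scan_from = 7  # the pixel left of the raster-first pixel is background
    first_d: int | None = None
    total = 0.0
    for _ in range(4 * m.size + 8):
        for i in range(8):
            d = (scan_from + i) % 8
            ny = cur[0] + _TRACE_OFFSETS[d][0]
            nx = cur[1] + _TRACE_OFFSETS[d][1]
            if m[ny, nx]:
                break
        else:
            return 0.0  # isolated pixel
        if cur == start:
            if first_d is None:
                first_d = d
            elif d == first_d:
                return total
        total += 1.0 if d % 2 == 0 else _SQRT2
        cur = (int(ny), int(nx))
        scan_from = ((d + 4) + 1) % 8
    return total


def extract_regions(
    mask: np.ndarray, cfg: SegmentationConfig | None = None
) -> list[EarRegion]:
    """8-connected components of the mask as EarRegion records.

    Components with area below ``cfg.min_area`` are dropped; survivors are
    ordered by (row_min, col_min) of their bounding boxes.
    """
    cfg = cfg or SegmentationConfig()
    m = _binary(mask)
    labeled = measure.label(m, connectivity=2)
    regions: list[EarRegion] = []
    for rp in measure.regionprops(labeled):
        if rp.area < cfg.min_area:
            continue
        r0, c0, r1, c1 = rp.bbox
        perim = region_perimeter(labeled[r0:r1, c0:c1] == rp.label)
        regions.append(
            EarRegion(
                bbox=(r0, c0, r1 - r0, c1 - c0),
                centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
                area=int(rp.area),
                perimeter=perim,
            )
        )
    regions.sort(key=lambda r: (r.bbox[0], r.bbox[1]))
    return regions


def pad_border(
    img: np.ndarray, width: int, value: tuple[int, int, int] | np.ndarray
) -> np.ndarray:
    """Add a constant-color frame of ``width`` pixels around the image.

    Keeps ears that touch the frame edge from merging with the border during
    cropping; downstream region coordinates live in the padded frame.
    """
    if width < 0:
        raise ValueError(f"pad width must be >= 0, got {width}")
    img = np.asarray(img)
    if width == 0:
        return img.copy()
    value = np.asarray(value, dtype=img.dtype).reshape(1, 1, -1)
    out = np.empty(
        (img.shape[0] + 2 * width, img.shape[1] + 2 * width, img.shape[2]),
        dtype=img.dtype,
    )
    out[:] = value
    out[width:-width, width:-width] = img
    return out


def crop_patches(
    img: np.ndarray,
    regions: list[EarRegion],
    cfg: SegmentationConfig | None = None,
) -> list[np.ndarray]:
    """Crop each region's margin-expanded bbox and rescale to patch_size.

    The expansion is clipped at the image edges; the crop is resized directly
    (aspect not preserved) to the square classifier input.
    """
    cfg = cfg or SegmentationConfig()
    h, w = img.shape[:2]
    ph, pw = cfg.patch_size
    patches = []
    for reg in regions:
        r0, c0, rh, rw = reg.bbox
        r0m = max(r0 - cfg.bbox_margin, 0)
        c0m = max(c0 - cfg.bbox_margin, 0)
        r1m = min(r0 + rh + cfg.bbox_margin, h)
        c1m = min(c0 + rw + cfg.bbox_margin, w)
        crop = img[r0m:r1m, c0m:c1m]
        patches.append(resize(crop, ph, pw))
    return patches


def segment_image(
    img: np.ndarray, cfg: SegmentationConfig | None = None
) -> tuple[list[EarRegion], list[np.ndarray], np.ndarray]:
    """Full segmentation: quantize, pick ear cluster, clean, extract, crop.

    Returns (regions, patches, cleaned mask); region coordinates and the mask
    are in the border-padded frame ((row, col) minus ``cfg.border_pad`` maps
    back to the input frame).  Deterministic for a fixed ``cfg.seed``.
    """
    cfg = cfg or SegmentationConfig()
    q = kmeans_quantize(img, cfg)
    ear_idx = select_ear_cluster(q)

    # degenerate scene guard: if the "ear" center is not separated from every
    # other center (essentially one-color image, clusters split pure noise),
    # there is no distinct ear color class and nothing to count
    others = np.delete(np.arange(q.k), ear_idx)
    sep = np.linalg.norm(q.centers[others] - q.centers[ear_idx], axis=1).max()
    if sep < cfg.min_center_separation:
        empty_mask = np.zeros(
            (img.shape[0] + 2 * cfg.border_pad, img.shape[1] + 2 * cfg.border_pad),
            dtype=np.uint8,
        )
        return [], [], empty_mask

    mask = binarize(q, ear_idx)
    mask = morph_clean(mask, cfg)

    # pad with the most background-like (lowest-b*) cluster color so border
    # ears keep a separating frame
    bg_idx = int(np.argmin(q.centers[:, 2]))
    from .image_prep import lab_to_rgb  # local import to avoid cycle at module load

    bg_rgb = lab_to_rgb(q.centers[bg_idx].reshape(1, 1, 3))[0, 0]
    padded_img = pad_border(img, cfg.border_pad, bg_rgb)
    padded_mask = np.pad(mask, cfg.border_pad)

    regions = extract_regions(padded_mask, cfg)
    patches = crop_patches(padded_img, regions, cfg)
    return regions, patches, padded_mask
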