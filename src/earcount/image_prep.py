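"""Image loading and preprocessing for canopy photographs.

The preprocessing chain prepares a nadir field image for color-based
segmentation: an optional center crop and downscale (phone/UAV frames are
far larger than the working resolution), contrast enhancement of the
lightness channel in CIELAB via CLAHE, and a small median filter to knock
out sensor/transmission noise.  All functions are pure: the input array is
never modified in place.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError
from scipy import ndimage as ndi
from skimage import color as skcolor
from skimage.transform import resize as _sk_resize

__all__ = [
    "EnhancementConfig",
    "load_image",
    "save_image",
    "center_crop",
    "resize",
    "enhance",
    "median_denoise",
    "clahe_channel",
    "rgb_to_lab",
    "lab_to_rgb",
]


@dataclass(frozen=True)
class EnhancementConfig:
    """CLAHE + median-filter parameters.

    clahe_clip is the contrast-limiting threshold in the 256-bin histogram
    convention (2.0 by default); clahe_tiles the contextual tile grid; and
    median_kernel the (odd) side of the median window applied after the
    equalized image is converted back to RGB.
    """

    clahe_clip: float = 2.0
    clahe_tiles: tuple[int, int] = (8, 8)
    median_kernel: int = 3

    def __post_init__(self) -> None:
        if self.clahe_clip <= 0:
            raise ValueError(f"clahe_clip must be positive, got {self.clahe_clip}")
        if self.median_kernel < 1 or self.median_kernel % 2 == 0:
            raise ValueError(
                f"median_kernel must be odd and >= 1, got {self.median_kernel}"
            )
        if min(self.clahe_tiles) < 1:
            raise ValueError(f"clahe_tiles must be >= 1, got {self.clahe_tiles}")


def _check_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 RGB array, got shape {img.shape}")
    return img


def load_image(path: str | Path) -> np.ndarray:
    """Load a PNG or JPEG as an HxWx3 uint8 RGB array.

    Grayscale and RGBA files are converted to plain RGB.  Raises
    ``FileNotFoundError`` for a missing path and ``ValueError`` (naming the
    path) for a file that does not decode as an image.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"no such image file: {path}")
    try:
        with Image.open(path) as im:
            return np.asarray(im.convert("RGB"), dtype=np.uint8)
    except UnidentifiedImageError as exc:
        raise ValueError(f"cannot decode {path} as an image") from exc


def save_image(path: str | Path, img: np.ndarray) -> None:
    """Write an RGB array as PNG (lossless; tests and artifacts rely on it)."""
    img = _check_rgb(img)
    Image.fromarray(np.ascontiguousarray(img.astype(np.uint8))).save(Path(path))


def center_crop(img: np.ndarray, crop_h: int, crop_w: int) -> np.ndarray:
    """Crop a crop_h x crop_w window centered on the frame.

    The top-left corner is at ``(floor((H-crop_h)/2), floor((W-crop_w)/2))``.
    """
    img = _check_rgb(img)
    h, w = img.shape[:2]
    if crop_h < 1 or crop_w < 1:
        raise ValueError(f"crop size must be positive, got {(crop_h, crop_w)}")
    if crop_h > h or crop_w > w:
        raise ValueError(f"crop {(crop_h, crop_w)} exceeds image size {(h, w)}")
    r0 = (h - crop_h) // 2
    c0 = (w - crop_w) // 2
    return img[r0 : r0 + crop_h, c0 : c0 + crop_w].copy()


def resize(img: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Bilinear resize to exactly out_h x out_w (uint8 in, uint8 out)."""
    img = _check_rgb(img)
    if out_h < 1 or out_w < 1:
        raise ValueError(f"target size must be positive, got {(out_h, out_w)}")
    if (out_h, out_w) == img.shape[:2]:
        return img.copy()
    out = _sk_resize(
        img.astype(np.float64),
        (out_h, out_w),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def rgb_to_lab(img: np.ndarray) -> np.ndarray:
    """sRGB (uint8) -> CIELAB under D65, as float (L in [0,100], a/b signed)."""
    img = _check_rgb(img)
    return skcolor.rgb2lab(img.astype(np.float64) / 255.0)


def lab_to_rgb(lab: np.ndarray) -> np.ndarray:
    """CIELAB -> sRGB uint8 with clipping at the gamut boundary."""
    rgb = skcolor.lab2rgb(np.asarray(lab, dtype=np.float64))
    return np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)


def median_denoise(img: np.ndarray, kernel: int = 3) -> np.ndarray:
    """Per-channel median over kernel x kernel windows, edge-replicated borders."""
    img = _check_rgb(img)
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError(f"median kernel must be odd and >= 1, got {kernel}")
    if kernel == 1:
        return img.copy()
    out = np.empty_like(img)
    for c in range(3):
        out[..., c] = ndi.median_filter(img[..., c], size=kernel, mode="nearest")
    return out


def clahe_channel(
    channel: np.ndarray, clip: float = 2.0, tiles: tuple[int, int] = (8, 8)
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization of one uint8 channel.

    Classic tile-based CLAHE: the image is partitioned into a ``tiles`` grid,
    each tile gets a 256-bin histogram clipped at
    ``max(1, clip * tile_pixels / 256)`` with the excess redistributed
    uniformly, and each tile's clipped CDF becomes a lookup table mapped to
    [0, 255].  Pixel values are produced by bilinear interpolation between the
    LUTs of the four surrounding tile centers, which suppresses tile-boundary
    seams.  No global min/max stretching is applied, so a flat image maps to
    (almost) itself.
    """
    chan = np.asarray(channel)
    if chan.ndim != 2:
        raise ValueError(f"expected a 2-D channel, got shape {chan.shape}")
    if chan.dtype != np.uint8:
        raise ValueError("clahe_channel expects uint8 input")
    h, w = chan.shape
    nty, ntx = tiles
    nty, ntx = min(nty, h), min(ntx, w)

    # near-equal tile partition (first `rem` tiles one pixel taller/wider)
    row_edges = np.linspace(0, h, nty + 1).round().astype(int)
    col_edges = np.linspace(0, w, ntx + 1).round().astype(int)

    luts = np.empty((nty, ntx, 256), dtype=np.float64)
    for ti in range(nty):
        for tj in range(ntx):
            tile = chan[row_edges[ti] : row_edges[ti + 1], col_edges[tj] : col_edges[tj + 1]]
            npix = tile.size
            hist = np.bincount(tile.ravel(), minlength=256).astype(np.float64)
            limit = max(clip * npix / 256.0, 1.0)
            excess = np.clip(hist - limit, 0, None).sum()
            hist = np.minimum(hist, limit) + excess / 256.0
            cdf = np.cumsum(hist)
            luts[ti, tj] = cdf * (255.0 / npix)

    centers_y = (row_edges[:-1] + row_edges[1:] - 1) / 2.0
    centers_x = (col_edges[:-1] + col_edges[1:] - 1) / 2.0

    def _coords(n: int, centers: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        pos = np.arange(n, dtype=np.float64)
        hi = np.searchsorted(centers, pos)          # first center >= pos
        lo = np.clip(hi - 1, 0, len(centers) - 1)
        hi = np.clip(hi, 0, len(centers) - 1)
        span = centers[hi] - centers[lo]
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(span > 0, (pos - centers[lo]) / np.where(span == 0, 1, span), 0.0)
        return lo, hi, np.clip(frac, 0.0, 1.0)

    ylo, yhi, wy = _coords(h, centers_y)
    xlo, xhi, wx = _coords(w, centers_x)

    v = chan  # (H, W) uint8 used as LUT index
    wy = wy[:, None]
    wx = wx[None, :]
    out = (
        (1 - wy) * (1 - wx) * luts[ylo[:, None], xlo[None, :], v]
        + (1 - wy) * wx * luts[ylo[:, None], xhi[None, :], v]
        + wy * (1 - wx) * luts[yhi[:, None], xlo[None, :], v]
        + wy * wx * luts[yhi[:, None], xhi[None, :], v]
    )
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def enhance(img: np.ndarray, cfg: EnhancementConfig | None = None) -> np.ndarray:
    """CLAHE on the CIELAB lightness channel, then a median filter.

    The image is converted sRGB -> CIELAB (D65), contrast-limited adaptive
    histogram equalization is applied to L only (tile grid ``cfg.clahe_tiles``,
    clip ``cfg.clahe_clip``), the result is converted back to RGB, and finally
    median-filtered with ``cfg.median_kernel``.  Output has the same
    dimensions and dtype as the input.
    """
    cfg = cfg or EnhancementConfig()
    img = _check_rgb(img)
    lab = rgb_to_lab(img)
    L8 = np.clip(np.rint(lab[..., 0] * 255.0 / 100.0), 0, 255).astype(np.uint8)
    L8_eq = clahe_channel(L8, clip=cfg.clahe_clip, tiles=cfg.clahe_tiles)
    lab_eq = lab.copy()
    lab_eq[..., 0] = L8_eq.astype(np.float64) * 100.0 / 255.0
    out = lab_to_rgb(lab_eq)
    return median_denoise(out, cfg.median_kernel)
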