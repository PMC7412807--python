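"""Brute-force reference implementations used as independent test oracles."""

import numpy as np


def minkowski_opening(mask: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Union of all translates of the structuring element inside the mask."""
    h, w = mask.shape
    sh, sw = se.shape
    out = np.zeros_like(mask, dtype=bool)
    for i in range(h - sh + 1):
        for j in range(w - sw + 1):
            if mask[i : i + sh, j : j + sw].all():
                out[i : i + sh, j : j + sw] = True
    return out


def minkowski_closing(mask: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Complement-opening on a padded domain (infinite-background closing)."""
    pad = max(se.shape)
    grown = np.pad(mask, pad)
    return ~minkowski_opening(~grown, se)[pad:-pad, pad:-pad]


def flood_components(mask: np.ndarray, diag: bool) -> int:
    """Number of connected components by explicit flood fill."""
    offs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if diag:
        offs += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    seen = np.zeros_like(mask, dtype=bool)
    n = 0
    h, w = mask.shape
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                n += 1
                stack = [(r, c)]
                seen[r, c] = True
                while stack:
                    y, x = stack.pop()
                    for dy, dx in offs:
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                            seen[ny, nx] = True
                            stack.append((ny, nx))
    return n


def flood_fill_regions(mask: np.ndarray) -> list[tuple[tuple[int, int, int, int], int]]:
    """8-connected components as [(bbox, area), ...] via explicit flood fill."""
    offs = [(-1, 0), (1, 0), (0, -1), (0, 1), (-1, -1), (-1, 1), (1, -1), (1, 1)]
    seen = np.zeros_like(mask, dtype=bool)
    out = []
    h, w = mask.shape
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                pix = []
                stack = [(r, c)]
                seen[r, c] = True
                while stack:
                    y, x = stack.pop()
                    pix.append((y, x))
                    for dy, dx in offs:
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                            seen[ny, nx] = True
                            stack.append((ny, nx))
                rows = [p[0] for p in pix]
                cols = [p[1] for p in pix]
                bbox = (
                    min(rows),
                    min(cols),
                    max(rows) - min(rows) + 1,
                    max(cols) - min(cols) + 1,
                )
                out.append((bbox, len(pix)))
    return out
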