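"""Image-level ear counting: classify candidate regions, sum the classes.

Each segmented region is classified as containing 0, 1, 2 or 3 ears; the
image's ear count is the sum of these labels.  Class 0 absorbs false
positives of the color segmentation (e.g. sun-glint on leaves that lands in
the yellow cluster) so they contribute nothing to the count, and the 2/3
classes recover ears that adhesion fused into a single blob.  Blobs with
more than three true ears fall outside the label space and are undercounted;
they are rare at field density and are not special-cased.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cnn import ModelState, predict
from .image_prep import EnhancementConfig, center_crop, enhance, load_image, resize
from .segmentation import SegmentationConfig, segment_image

__all__ = [
    "PreprocessConfig",
    "CountResult",
    "preprocess",
    "count_from_labels",
    "count_image",
    "count_batch",
    "results_to_frame",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Optional center crop and downscale, then enhancement.

    ``crop``/``scale`` of None skip the step; field phone/UAV frames
    typically use crop (1400, 1400) and scale (700, 700).
    """

    crop: tuple[int, int] | None = None
    scale: tuple[int, int] | None = None
    enhancement: EnhancementConfig = EnhancementConfig()


def preprocess(img: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Apply the configured crop, downscale and enhancement chain."""
    cfg = cfg or PreprocessConfig()
    if cfg.crop is not None:
        img = center_crop(img, *cfg.crop)
    if cfg.scale is not None:
        img = resize(img, *cfg.scale)
    return enhance(img, cfg.enhancement)


@dataclass(frozen=True)
class CountResult:
    """Per-image counting outcome.

    predicted_count = sum over regions of their class labels
    = sum_j j * per_class_tally[j]; region_count = sum of the tally.
    """

    image_id: str
    predicted_count: int
    region_count: int
    per_class_tally: tuple[int, int, int, int]
    manual_count: int | None = None


def count_from_labels(labels, image_id: str = "") -> CountResult:
    """Aggregate per-region class labels into an image ear count."""
    tally = [0, 0, 0, 0]
    for lbl in labels:
        if lbl not in (0, 1, 2, 3):
            raise ValueError(f"region label must be in 0..3, got {lbl}")
        tally[lbl] += 1
    count = sum(j * tally[j] for j in range(4))
    return CountResult(
        image_id=image_id,
        predicted_count=count,
        region_count=sum(tally),
        per_class_tally=tuple(tally),
    )


def count_image(
    img: np.ndarray,
    model: ModelState,
    segcfg: SegmentationConfig | None = None,
    prepcfg: PreprocessConfig | None = None,
    image_id: str = "",
) -> CountResult:
    """Full pipeline for one image: preprocess, segment, classify, sum."""
    enhanced = preprocess(img, prepcfg)
    regions, patches, _ = segment_image(enhanced, segcfg)
    labels = [lbl for lbl, _ in predict(model, patches)]
    return count_from_labels(labels, image_id=image_id)


def _load_manual_counts(manual_csv: str | Path) -> dict[str, int]:
    df = pd.read_csv(manual_csv)
    cols = {c.lower(): c for c in df.columns}
    id_col = cols.get("image_id", df.columns[0])
    cnt_col = cols.get("manual_count", cols.get("count", df.columns[1]))
    counts: dict[str, int] = {}
    for _, row in df.iterrows():
        key = str(row[id_col])
        if key in counts:
            warnings.warn(
                f"duplicate image id {key!r} in {manual_csv}; last entry wins",
                stacklevel=2,
            )
        counts[key] = int(row[cnt_col])
    return counts


def count_batch(
    paths,
    model: ModelState,
    segcfg: SegmentationConfig | None = None,
    prepcfg: PreprocessConfig | None = None,
    manual_csv: str | Path | None = None,
) -> list[CountResult]:
    """Count every image; attach manual counts by file stem when provided.

    Image ids are the file stems.  An id missing from the manual CSV leaves
    manual_count unset with a warning.
    """
    manual = _load_manual_counts(manual_csv) if manual_csv is not None else {}
    results: list[CountResult] = []
    for path in paths:
        path = Path(path)
        img = load_image(path)
        res = count_image(img, model, segcfg, prepcfg, image_id=path.stem)
        if manual:
            if path.stem in manual:
                res = CountResult(
                    image_id=res.image_id,
                    predicted_count=res.predicted_count,
                    region_count=res.region_count,
                    per_class_tally=res.per_class_tally,
                    manual_count=manual[path.stem],
                )
            else:
                warnings.warn(
                    f"no manual count for image {path.stem!r}", stacklevel=2
                )
        results.append(res)
    return results


def results_to_frame(results: list[CountResult]) -> pd.DataFrame:
    """CountResults -> tidy DataFrame (one row per image)."""
    rows = []
    for r in results:
        rows.append(
            {
                "image_id": r.image_id,
                "region_count": r.region_count,
                "tally_0": r.per_class_tally[0],
                "tally_1": r.per_class_tally[1],
                "tally_2": r.per_class_tally[2],
                "tally_3": r.per_class_tally[3],
                "predicted_count": r.predicted_count,
                "manual_count": r.manual_count,
            }
        )
    return pd.DataFrame(rows)
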