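# Methods

## The counting model

`earcount` estimates the number of wheat ears in a nadir canopy photograph
taken at the grain-filling stage. The method deliberately avoids object
*detection*: it converts counting into patch *classification*.

1. **Enhancement.** The image is converted to CIELAB (D65) and the lightness
   channel is contrast-enhanced with CLAHE (clip 2.0 in the 256-bin
   convention, 8×8 tile grid), then median-filtered (3×3). At grain filling,
   ears are bright and yellow while stems/leaves stay green; boosting local
   lightness contrast sharpens that separation.
2. **Color quantization.** Per-pixel k-means (k = 3, k-means++, single
   seeded restart) in CIELAB splits the scene into ear / vegetation / soil.
   Two clusters would force the ear–background color-transition zone into
   one side; a third cluster absorbs it.
3. **Ear mask.** The cluster whose center has the largest b* (yellowness) is
   the ear cluster (ties: larger L, then lower index). The binary mask is
   cleaned by a 6×6 opening (specks, awn burrs) followed by a 3×3 closing
   (interior holes).
4. **Regions.** 8-connected components with area ≥ `min_area` (50 px at
   700×700) become candidate ear blobs. The image is padded by a 10-px
   background-colored border first so blobs touching the frame keep a
   separating margin. Each blob's bounding box, expanded by 4 px and clipped
   to the frame, is cropped from the enhanced image and rescaled (bilinear,
   aspect not preserved) to 100×100.
5. **Classification.** A small CNN labels each patch 0, 1, 2 or 3 ears.
   Touching ears fuse into one blob ("adhesion"); the 2/3 classes recover
   them, and class 0 absorbs segmentation false positives (e.g. sun-glint on
   leaves), so they add nothing to the count.
6. **Count.** The image's ear count is the sum of patch labels. Blobs with
   more than three true ears are outside the label space and are
   undercounted; at field density they are rare and are not special-cased.

## The classifier

Five blocks of 3×3 same-padded convolution + ReLU + 2×2 stride-2 max-pool
(spatial path 100 → 50 → 25 → 12 → 6 → 3 by floor division), then a flatten
and two fully connected layers, softmax over 4 classes. Training minimizes
softmax cross-entropy with Adam on mini-batches; initialization is
He-normal from an explicit seed. Channel widths, dense width, batch size,
learning rate and step count are configuration, not architecture; the
defaults (16, 32, 64, 128, 256 channels, 256-wide dense, 64-patch batches,
lr 1e-4, 8000 steps) suit a full-size labeled dataset of ~10⁴ patches per
class. "Epochs" are mini-batch steps by default (`epochs_mode: steps`); a
full-pass interpretation is selectable (`passes`). The learning rate is
constant by default; cosine annealing is available (`lr_decay: cosine`)
but gave no measurable benefit at desk scale.

The network is implemented directly in NumPy (im2col + BLAS matrix
products, explicit backward pass). At these sizes a framework is
unnecessary, and the arithmetic stays reproducible from the seeds on a
fixed platform. Note that products computed in different batch layouts may
differ in the last float32 bits, so reproducibility contracts compare runs
with identical batching.

## Desk-scale preset

The test suite and the acceptance script exercise the full pipeline at a
reduced problem size chosen so a laptop-class CPU completes it in minutes:
600 synthetic patches per class (500 train / 100 held out), conv widths
(8, 16, 24, 32, 48), 64-wide dense layer, batch 16, lr 1e-3, 2000 Adam
steps, then 30 synthetic scenes of 5–40 ears with 20% adhesion. These are
the package's own desk-scale study conditions; the full-size defaults
remain available through the configuration.

## Evaluation statistics

Classifier quality comes from the 4×4 confusion matrix: per-class precision
P_i = TP_i/(TP_i+FP_i) and recall R_i = TP_i/(TP_i+FN_i), per-class
F1 = 2P_iR_i/(P_i+R_i), macro F1 (unweighted mean of per-class F1) and
micro F1 (harmonic mean of pooled precision/recall; for single-label data
this equals accuracy). Zero-denominator classes score 0 with a warning.
Percentages are reported rounded half-up to two decimals; raw fractions
are also returned.

Count agreement over n images with manual counts m_i and predicted counts
c_i: R² = 1 − Σ(m_i−c_i)²/Σ(m_i−m̄)², RMSE = √(Σ(m_i−c_i)²/n) in ears,
RRMSE = RMSE/m̄ × 100 in percent, bias = Σ(m_i−c_i)/n in ears, plus the
least-squares slope/intercept of c on m. R² is computed against the
*predictions*, not as a squared correlation: it can be negative for a poor
predictor and differs from corr² off the 1:1 line.

## The synthetic scene generator

The generator emulates only the color-and-shape structure the pipeline
exploits: a brown soil raster with Gaussian jitter, random green elliptical
leaf strokes, and yellow speckled ellipses for ears (major axis 30–60 px,
minor 10–20 px at 700×700). A configurable `adhesion` fraction of ears is
placed as fused groups of 2–3 overlapping ellipses forming one connected
blob; each subsequent ellipse branches 20–60° off the previous axis, the
way adhered neighbors cross or splay in a nadir view, so every ear keeps a
visible lobe. Blobs are rejection-placed with a 12-px clearance so
ground-truth blobs remain separable after morphology; every blob's mask,
centroid and ear multiplicity are recorded, and all drawing is driven by
one seeded generator, so scenes are bit-reproducible.

Labeled training patches are *harvested from the pipeline itself*: small
scenes (350-px tiles whose 4×4 CLAHE grid gives the same 87-px kernel as a
default 700×700 count scene) are run through the actual enhancement and
K-means segmentation, and every region patch is labeled with its
ground-truth ear count — a truth blob is attributed to a region when at
least half of the blob's pixels fall inside the region's bounding box, the
judgment a human labeler applies to a segmented patch. Scene compositions
alternate between triple-rich, pair-rich, dense-single, sparse-single and
ear-free tiles until all four class quotas fill. Training patches
therefore include exactly what the classifier meets at count time: tight
single ears, fused 2/3-ear blobs, ears merged with bright leaves that
joined the yellow cluster, and pure leaf/soil false positives (class 0).
Matching the training distribution to the segmentation output this way is
essential: with idealized tight-crop training patches the classifier
reaches similar patch accuracy but systematically overcounts real scenes,
because composite ear+leaf regions and large leaf phantoms occur only in
pipeline output. Regions spanning more than three ears are discarded
rather than mislabeled.

What the generator does *not* emulate: perspective and occlusion, awns
(available behind a flag in spirit but off — ears are smooth textured
ellipses), specular highlights, shadows, wind blur, and the continuous
color gradation of semi-ripe ears. Passing desk-scale tests therefore
demonstrates that the mechanism (segment → classify → sum, including fused
blobs) is implemented correctly, not that field-photo accuracy transfers.
Reducing the ear/leaf palette separation emulates the early grain-filling
stage and degrades segmentation overlap monotonically, which the suite
asserts as a direction, not a number.

## Numerical and design choices

- **CLAHE** is implemented in-package: per-tile 256-bin histograms clipped
  at `max(1, clip · tile_pixels/256)` with uniform redistribution of the
  excess, CDF lookup tables mapped to [0, 255], and bilinear interpolation
  between the four surrounding tile mappings. No global min/max stretch is
  applied, so a flat image maps to itself (±1 level); library CLAHE
  implementations that rescale the image's own range to full scale would
  break that contract and distort absolute lightness.
- **Lab scaling**: L is carried in [0, 100] internally and quantized to
  8 bits only for the CLAHE lookup.
- **Morphology border convention**: masks are padded before scipy's
  opening/closing and cropped after, which reproduces the set-theoretic
  definition on an infinite background (verified against a brute-force
  Minkowski oracle in the tests).
- **Perimeter** is the length of the outer 8-connected boundary contour
  traced by radial sweep, axial steps 1 and diagonal steps √2 — one
  concrete, testable convention.
- **Degenerate scenes**: if the selected ear center is within 10 Lab units
  of every other center, the quantization collapsed (an essentially
  one-color image) and segmentation returns no regions rather than labeling
  noise partitions as ears.
- **Split hygiene**: train/test splitting happens at the level of source
  patches before augmentation, so augmented copies of one source never
  straddle the split.
- **Augmentation and fused blobs**: random cropping can cut a lobe off a
  2/3-ear blob and silently falsify the label, so count-critical training
  at desk scale uses originals only; when augmentation is used to balance
  classes, a crop fraction of 1.0 with flips/rotation/brightness is the
  count-preserving choice.
- **K-means determinism**: k-means++ with a single restart and explicit
  seed; the paper-facing default k = 3.
- **Ties** in predicted class probabilities resolve to the lowest class
  index (argmax convention).

## Known limitations

- Counts saturate at 3 ears per connected blob by construction.
- The b*-maximum rule assumes ripe (yellowing) ears; on early-stage scenes
  the ear cluster may capture vegetation, degrading counts — by design the
  classifier's 0 class is the only guard.
- Real-photo accuracies depend on a labeled field dataset that is not
  bundled; the synthetic suite validates mechanism, determinism and the
  statistics, not field performance.
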