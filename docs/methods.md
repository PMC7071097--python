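# Methods

This note records the model assumptions, parameter choices, numerical
conventions and known limitations of `retipatch`. It states no empirical
result beyond what the test suite and `scripts/acceptance.py` compute.

## Problem setting

Early diabetic retinopathy shows as sparse, small lesions — bright exudates,
dark microaneurysms and hemorrhages — embedded in a textured, vignetted,
vessel-crossed background. The package frames detection as *patch
classification*: no lesion segmentation or candidate maps, only a dense
overlapping window grid whose cells are labeled healthy/pathological. This
trades pixel-level precision for robustness (a window only needs to *look*
abnormal) and yields a natural spatial localization via the grid.

## Conditioning pipeline

Fixed order, recorded in the output's provenance list: resolution
normalization, color normalization, vessel segmentation, inpainting, green
extraction. The ordering (inpainting after color normalization) is a design
choice; both orders are defensible and the provenance makes the applied one
auditable.

- **Resolution.** Only downscaling is supported (upscaling would fabricate
  detail). A local extremum filter (default 3 px, odd) precedes bilinear
  resampling: max for bright lesions, min for dark ones, so a 1-px lesion
  survives a 2x downscale. Anti-aliasing is deliberately off — the extremum
  filter carries the lesion-preservation burden, and a Gaussian prefilter
  would undo it.
- **Color.** Per-channel affine map inside the FOV to reference mean/std,
  clipped to [0, 1]; a zero-variance channel degrades to a mean shift. When
  no reference is configured, dataset runs use the median per-channel FOV
  statistics of the dataset itself. The map is idempotent up to clipping.
- **Vessel segmentation.** Black top-hat (closing with a disc of radius 6
  minus the image) + Otsu on the in-FOV response. The mask is capped at 30%
  of the FOV by keeping only the strongest responses; vessels occupy far
  less than that in practice, so the cap only guards degenerate inputs.
  The detector is intentionally conservative — it exists to feed inpainting,
  not to be a vessel-segmentation contribution; an externally computed mask
  can be supplied instead.
- **Inpainting.** Vessels are treated as missing data and relaxed to the
  harmonic (discrete-Laplace) fill by Jacobi iteration, tolerance 1e-4,
  capped at 5000 sweeps (thin vessel strokes converge in tens). The
  mean-value property keeps the result inside the observed range — an
  advantage over biharmonic fills, which can overshoot near lesion edges.
- **FOV/optic disc.** When absent, the FOV is estimated by luminance
  thresholding (5% of max) + largest component + hole filling. The optic-disc
  helper (`estimate_od_mask`, matched filter with a uniform disc kernel) is
  explicitly approximate; experiments here use the generator's ground-truth
  masks.

## Patch grid

64 x 64 windows displaced by (32, 32) (50% overlap: every interior pixel is
covered by exactly four windows). Windows must fit entirely inside the
raster; a window is kept iff it touches the FOV and contains no optic-disc
pixel (the disc mimics exudates). A patch is labeled pathological when its
window contains at least `min_lesion_pixels` lesion pixels. The default of
1 is the most sensitive choice; it is exposed in `GridConfig` because any
threshold between 1 and a few dozen pixels is defensible, and it directly
controls the difficulty of the positive class (a window touching a lesion
by one corner pixel is a legitimately hard positive).

## Texture descriptor (LBPV)

P = 8 neighbors on a circle of radius R = 1, bilinear interpolation at the
diagonal sampling points, riu2 coding (patterns with <= 2 circular bit
transitions map to their popcount, the rest to label P + 1 — ten labels for
P = 8). The VAR weight is the population variance of the P neighbors (mean
over the neighbors only, divisor P). Numerical conventions that matter:

- **Ties.** s(x) = 1 for x >= 0; implemented with a 1e-10 tolerance so an
  interpolated neighbor numerically equal to the center counts as >=
  (constant patches then produce the all-ones pattern, label 8).
- **Shift invariance.** Interpolation is applied to the *differences from
  the center*, which is algebraically identical but makes labels and VAR
  exactly shift-invariant whenever inputs and shift are exactly
  representable (integers, dyadic rationals).
- **Borders.** Labels exist only where the full circular neighborhood fits
  (margin ceil(R)); no padding, because padded values would inject
  artificial texture. Image-level label/VAR maps sliced at a window interior
  are therefore bit-identical to the per-patch computation, which is what
  the feature pipeline exploits.
- Histograms are normalized by total VAR mass by default; constant patches
  emit the all-zero vector rather than NaN.

## Morphological descriptor (pattern spectra)

Flat structuring elements: size n maps to a disc of radius n (diameter
2n + 1) and to a digital line of length 2n + 1 at 0/45/90/135 degrees
(Bresenham for the diagonals); odd supports keep SEs centered. Pyramids use
sizes n = 0, 2, ..., 22 (12 levels; level 0 is the identity). Disc
erosions/dilations are computed by chord decomposition (per-row running
min/max over the disc's horizontal chords), which is exactly the flat
erosion by the disc footprint — asserted against the scipy reference in the
tests — at a fraction of the cost for large radii. Border handling is
reflective throughout, which preserves the anti-extensivity/extensivity and
sieving (absorption) properties the spectra rely on.

The signed spectrum entry at +n is the normalized volume lost between
openings of sizes n - s and n; the entry at -n is the dual closing gain; the
center entry is an explicit zero (kept as a harmless constant feature so the
curve reads closings | 0 | openings). Volumes are measured over the patch
window of the *global* pyramids and normalized by the patch's level-0 volume
(the descriptor is local; structures larger than the patch contribute via
their restriction to the window — accepted as part of the construction). The
positive side telescopes to [m(level 0) - m(level nmax)] / m(f), which the
tests assert exactly. A zero-volume patch yields an all-zero spectrum with a
warning. The four angular spectra are averaged by default, keeping the
angular block the same length as the isotropic one; `angular_combine =
"concat"` exposes the 4x-length alternative.

The full default feature vector is LBPV (10) + four one-sided spectra
(11 each) = 54 columns, each mapped to (block, index) in a stored schema.

## Committee and validation protocol

T = round(M/N) (round-half-up) base classifiers; the healthy training
samples are permuted with the configured seed and split into T near-equal
subsets (remainders spread one per subset), so every healthy sample trains
exactly one member. Defaults for the unstated hyperparameters: 200 trees
(random forest), C = 1 and gamma = 1/d (SVMs, Platt-calibrated
probabilities), an RBF-kernel Gaussian process; every base model is an
sklearn Pipeline whose StandardScaler stage z-scores features on the
member's own training subset — this realizes per-block standardization
(blocks are disjoint column ranges) and travels with the persisted model.
Soft voting averages member probabilities; classification uses the strict
rule score > delta (a score exactly at delta is healthy).

Validation is grouped by image: GroupKFold (default K = 5, shuffled by the
run seed) over image ids, so patches of one image never straddle
train/test; leave-one-image-out is available. When delta is optimized, a
validation sub-fold (20% of the training images) is held out per fold, the
committee is trained on the rest, and delta is taken from the validation
ROC at the sensitivity/specificity balance point (minimum |sens - spec|,
ties toward sensitivity; Youden's J as an alternative); delta is chosen per
fold and reported as mean ± std. AUC is the trapezoidal area under the
threshold-swept ROC and equals the Mann-Whitney rank statistic (ties half).

## Synthetic generator

Emulates what the descriptors see, not photorealism: a circular FOV
(radius 0.95 of the half-frame) on a near-black background; a greenish
background with a per-image brightness offset (±0.05), a radial vignette
(30% center-to-rim) and low-frequency mottle; one bright optic disc (radius
14% of the FOV radius); dark quadratic-Bezier vessel strokes from the disc
(these exercise segmentation/inpainting, not vascular realism); exudates as
unions of jittered ellipses clipped between a core and a bounding disc
(irregular edges with controlled area), microaneurysms as discs,
hemorrhages as larger blurred blobs. Lesions are placed with mutual
separation, inside the FOV, off the disc and off the vessels, by bounded
rejection sampling (explicit error on failure). Inside every lesion mask the
green offset is at least half of `lesion_contrast` before Gaussian sensor
noise (sigma 0.01 default) — so `lesion_contrast` is an honest knob for
task difficulty, and `lesion_contrast = 0` makes lesions exactly invisible
while keeping their masks (the chance-level control).

What the generator does **not** model: real retinal texture statistics,
camera optics/compression, lesion clusters and rings, drusen/cotton-wool
confounders, graded lesion boundaries. Passing tests therefore demonstrate
that the pipeline recovers planted contrast structure under the stated
conditions — not clinical performance on real fundus data, which requires
the public annotated databases.

## Experiment problem sizes

The scaled-down screening experiment in the acceptance script and suite
uses 20 synthetic 512 x 512 images (12 with 8 exudates each, 8 healthy — a
pathological/healthy ratio close to the 47/35 of the public exudate
database this protocol mirrors), lesion diameters 6-14 px, contrast 0.5
("high") or 0.0 (control), the full 54-feature descriptor, K = 5
image-grouped folds, and three protocol seeds varying the fold shuffle and
committee permutations over a fixed image set. These sizes were chosen once
as the package's standard small-scale benchmark; about 4000 patches with
roughly a 1:9 pathological:healthy ratio result.

## Known limitations

- The vessel detector and optic-disc heuristic are deliberate stand-ins with
  a contract (conservative mask in, inpainted background out); on real data
  a dedicated segmenter should be plugged in through the mask arguments.
- Harmonic inpainting is smoother than exemplar/sparse methods; wide vessels
  leave low-texture bands that slightly depress local VAR.
- Descriptors are single-scale in LBP (R = 1) by design; multi-scale LBP and
  granulometry by reconstruction are out of scope.
- The committee's T is data-driven; with extreme imbalance (T large) each
  member sees few healthy samples, and with inverted imbalance (M < N) the
  protocol degenerates to a single balanced model with a warning.
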