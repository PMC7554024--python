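# Methods

## Synthetic image model

The generator emulates maximum-intensity-projection fluorescence images
of mitochondrial networks. Objects are rendered on a zero canvas:
*fragments* as small rotated ellipses (semi-axes drawn from the tube
thickness range), *tubules* as random-walk polylines (turning angle sd
0.6 rad) thickened by a disk; *elongated* images use longer walks (24 vs
10 steps) and *mixed* images draw half of each population. Fragment
placement rejects any position whose 1-px dilation touches existing
foreground, so each fragment is guaranteed to be its own 8-connected
component — this is what makes component-count assertions exact. The
ground-truth mask is the exact support of the rendered objects.

The raw image is `quantize8(clip(G_σ(signal) + background + noise))` with
Gaussian optics blur (σ = 1 px default), constant background (20 of 255),
foreground amplitude 160, Poisson shot noise on the noiseless image and
additive Gaussian read noise (sd 2). Because the rendering is additive,
every mask pixel's pre-noise intensity is at least the background level
by construction. Defaults (canvas 1300×1030, 8-bit, moderate SNR) mirror
a realistic wide-field acquisition; tests use smaller canvases with the
same noise law.

What the generator does **not** reproduce: anisotropic PSFs,
out-of-focus haze from 3D structure, autofluorescent tissue background,
intensity falloff across the field, or annotator disagreement in the
ground truth. Passing tests therefore demonstrate correctness of the
pipeline and metrics and learnability of the segmentation task, not
performance on real micrographs — synthetic blobs on clean background
are an easier segmentation problem than live-cell imaging.

Mask perturbations (`dilate`, `erode`, `merge_neighbors` with square
structuring elements of radius = magnitude; seeded `translate` and
`drop_objects`) produce "predictions" with known error modes; magnitude
0 is the identity for every operation.

## Training-data preparation

* **Tiling.** A 2×2 grid of equal square tiles; side = the smallest
  multiple of the network's downsampling factor (2^depth) that covers
  half the larger image dimension, floored at 4× the factor so the
  deepest feature map keeps at least a 4×4 extent. For 1300×1030 images
  and factor 16 this gives four 656×656 tiles with overlaps of 282 px
  (rows) and 12 px (columns). If the side reaches both dimensions the
  grid degenerates to a single reflect-padded tile. Stitching averages
  probabilities on overlaps and is an exact inverse on unmodified tiles.
* **Weight maps.** `w(x) = w_c(x) + w0·exp(−(d1+d2)²/(2σ²))` with
  defaults w0 = 10, σ = 5 px; `w_c` is 0.5/class-frequency (1 for a
  balanced image), and with fewer than two objects the border term is
  zero. Distances are exact Euclidean distance transforms per object;
  cost is one EDT per object, fine at tile scale.
* **Augmentation.** Per copy an affine transform (rotation ±180°, shear
  ±5°, zoom ±10%, shift ±10% of the side, independent horizontal and
  vertical flips, all about the tile center) and optionally an elastic
  displacement field (coarse Gaussian grid, default off) are sampled and
  applied identically to raw (bilinear), mask (nearest — binarity is
  preserved exactly) and weights (bilinear, floored at 1e-8 to stay
  positive). 80 copies per tile by default; an all-zero spec copies
  tiles verbatim. Reflect boundary handling throughout.
* **Split.** Seeded permutation, |train| = round(0.8·N) (3,072/768 at
  the default 3,840 tiles); clamped so neither side is empty.
  Leave-one-out folds operate at whole-image level for cross-validated
  evaluation.

## Network and training

Channels double per level down and halve per level up (base 64; tests
and the acceptance run use depth 2, base 8). Contracting-path and
bottleneck convolutions are conv→batch-norm→ReLU; expanding-path
convolutions are plain conv+ReLU; upsampling is nearest-neighbour 2×
followed by a 3×3 channel-halving convolution; skip tensors are
concatenated before two decoder convolutions; a 1×1 convolution and
sigmoid give per-pixel foreground probability. Convolutions use
same-padding (zeros), so output shape equals input shape at every size
divisible by 2^depth.

Loss is the mean over pixels of `w·BCE(p, y)`, exactly zero for a
perfect prediction and linear in the weights. Optimization is Adam
(default lr 1e-4; the small-model runs use 1e-3, batch 4, 30 epochs).
Batch norm uses momentum 0.1, eps 1e-5, running statistics at inference.
He-normal initialization, data order and initialization all derive from
one seed, and the implementation is pure NumPy, so builds, training runs
and save→load→predict round trips are bit-reproducible. Prediction
normalizes intensities by the dtype maximum (rule recorded in the model
metadata), tiles the image, averages overlaps and thresholds at 0.5
(configurable).

Fine-tuning resumes from the current parameter state using the same
preparation (tiling, weight maps, optional augmentation, 80/20 split)
and appends a provenance entry; zero epochs leaves parameters untouched.

## Classical baselines

Gaussian smoothing, negated Laplacian-of-Gaussian (bright blobs
positive), and a Hessian tubularness score — the magnitude of the most
negative eigenvalue of the scale-σ Hessian, clipped at zero — each
followed by a global threshold (Otsu default; mean, triangle and fixed
available). Automatic thresholds mark pixels strictly above the
threshold; fixed thresholds are inclusive. A constant enhanced image has
no meaningful automatic threshold: all-background is returned with a
warning. All filters use reflective boundaries and are deterministic.

## Accuracy metrics

* **Dice**: both-empty masks score 1.0 (perfect agreement) rather than
  being undefined.
* **Object matching**: components (8-connected by default) are paired
  when they share ≥ 1 pixel (minimum overlap configurable). One-to-one
  pairs are those whose two objects each appear in exactly one pair;
  split/merged objects are excluded from fold-deviation analysis,
  unmatched objects are reported separately.
* **Fold deviation**: `max(g,p)/min(g,p)` per descriptor, averaged over
  one-to-one pairs within an image — giving the images × 5 descriptors
  layout used for statistics. Pairs where a descriptor is zero on either
  side (only eccentricity of perfectly symmetric objects) are skipped;
  an image with no usable pair records a missing value, never zero.
* **Energy distance**: `sqrt(2E|X−Y| − E|X−X'| − E|Y−Y'|)` with
  expectations over all ordered pairs of the empirical samples
  (V-statistic convention, self-pairs included), computed between the
  full ground-truth and predicted descriptor distributions per image;
  normalized per descriptor by the maximum across all methods and
  images, because the five descriptors live on different scales.

### Descriptor conventions

Shared by evaluation and morphometry (`_geometry.py`): area = pixel
count; perimeter = weighted-step boundary length (a filled n×n square
measures 4(n−1); an isolated pixel, whose contour degenerates, is
assigned its outer boundary 4 so perimeters stay positive); ellipse
moments carry the +1/12-pixel variance correction, so a single pixel has
equal axes and eccentricity 0 and thin lines keep a positive minor axis;
aspect ratio = major/minor; solidity = area / convex hull area;
circularity = 4π·area/perimeter², clipped at 1.

## Morphometry

10 morphological features (area, perimeter, minor/major axis length,
eccentricity, aspect ratio, solidity, extent, orientation, circularity)
plus mean/min/max intensity per object. Skeletons come from topological
thinning; the skeleton pixel graph drops diagonal edges replaceable by
two orthogonal steps (otherwise every axis-aligned junction spawns
spurious branches), nodes are pixels of degree ≠ 2, branches are maximal
node-to-node paths with length 1 per axial and √2 per diagonal step, and
components consisting only of degree-2 pixels are counted as cycles, not
branches (a ring: 1 cycle, 0 branches). Thinning shortens branch tips;
length assertions use a declared end-effect tolerance of 2 px.
Summaries report n/mean/median/sd/min/max per feature; empty images and
singleton sds are missing values, not zeros.

## Statistics

Normality is screened with D'Agostino's K² (needs n ≥ 8; smaller samples
go straight to the nonparametric branch). Two groups: t-test if both
pass at α = 0.05, else Mann-Whitney U; three or more: Kruskal-Wallis H
with tie correction, followed when p < 0.05 by Dunn's pairwise z-tests
on joint mean ranks with the tie-corrected variance and Bonferroni
adjustment (Holm/none available). All tests are two-sided with
average-rank ties; every result records the branch chosen. Correlation
matrices (Pearson/Spearman) use pairwise-complete observations and
return missing values for constant features. Simulated type-I error of
both comparison paths at α = 0.05 stays within [0.03, 0.07] over 1,000
null replicates.

## Problem sizes

The bundled runs use 12 synthetic 96×128 images for the count laws
(3,840 tiles after 80× augmentation), 64×64 tiles / depth-2 / 8-filter
models for training demonstrations (30 epochs, ~15 s on one CPU), six
held-out images for method comparison, and 1,000 replicates for test
calibration. These sizes exercise every code path at desk scale; scaling
up is a matter of configuration, not code.

## Known limitations

Single-channel 2D images only; no 3D stacks or multi-class output. The
NumPy network is CPU-bound and meant for small-to-moderate models —
training the full-size default configuration on 656×656 tiles is
possible but slow compared to GPU frameworks. Classical baselines are
single-scale. The synthetic generator's realism limits are listed above;
conclusions about real-data accuracy require real annotated images, for
which the fine-tuning path exists.
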