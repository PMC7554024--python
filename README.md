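# mitoseg

A toolbox for segmenting fluorescently labeled mitochondria in 2D
microscopy images and quantifying their morphology. It is aimed at cell
biologists who need to turn micrographs of mitochondrial networks —
tubular, fragmented, elongated or mixed phenotypes — into per-object
measurements and statistically defensible group comparisons, without
hand-thresholding every image.

The toolbox has three layers:

1. **Segmentation.** A modified U-Net: an encoder–decoder with skip
   connections in which every contracting-path convolution is followed by
   batch normalization before its ReLU, and dropout is removed. Training
   data is prepared by cutting each image into a 2×2 grid of overlapping
   square tiles, computing a per-pixel loss weight map

   `w(x) = w_c(x) + w0 · exp(−(d1(x)+d2(x))² / (2σ²))`

   (w_c balances class frequencies; d1, d2 are distances to the two
   nearest objects, so pixels in the gaps between adjacent mitochondria
   are up-weighted), augmenting every (raw, mask, weights) tile triple 80
   times with shared geometric transforms, and splitting 80/20 into
   training and validation sets. Training minimizes pixel-weighted binary
   cross-entropy with Adam. Whole images of any size are segmented by
   tiled prediction with overlap averaging. Three classical baselines
   (Gaussian, Hessian-eigenvalue, Laplacian-of-Gaussian enhancement, each
   followed by global thresholding) are included for comparison, as are
   leave-one-out cross-validation folds and a fine-tuning entry point.
   The network itself is a compact, fully seeded NumPy implementation
   with manual backpropagation — no GPU or deep-learning framework
   needed.

2. **Accuracy evaluation.** Pixelwise accuracy via the dice coefficient
   `2|P∩T|/(|P|+|T|)`, and morphological accuracy via (a) the average
   fold deviation `max(g,p)/min(g,p)` of five shape descriptors (area,
   eccentricity, aspect ratio, perimeter, solidity) over one-to-one
   matched object pairs — objects split or merged by the prediction are
   excluded — and (b) the energy distance between the ground-truth and
   predicted descriptor distributions per image, normalized per
   descriptor across methods.

3. **Morphometry and statistics.** Per-object tables of 10 morphological
   and 3 intensity features, skeleton branch counts and lengths,
   per-image summaries, and a test battery (D'Agostino K² normality gate,
   t-test / Mann-Whitney U, Kruskal-Wallis + Dunn's post hoc, feature
   correlation).

Because annotated micrographs are rarely shareable, the package ships a
seeded generator of synthetic fluorescence-like images of all four
phenotype classes with exact ground-truth masks, plus controlled mask
perturbations (dilate, erode, translate, drop objects, merge neighbors)
for exercising the metrics.

## Worked example

```python
import numpy as np
from mitoseg import synthetic, pipeline, unet, evaluation

# 12 synthetic fragmented-phenotype images with exact masks
tiles = []
for s in range(12):
    pair = synthetic.generate_image(synthetic.SynthSpec(
        height=64, width=64, phenotype="fragmented", n_objects=8, seed=100 + s))
    wm = pipeline.compute_weight_map(pair.mask.astype(np.uint8))
    tiles.append((unet.normalize_intensity(pair.raw), pair.mask, wm.weights))
train_t, val_t = pipeline.train_val_split(tiles, pipeline.SplitSpec(seed=0))

cfg = unet.ModelConfig(depth=2, base_filters=8, input_side=64,
                       epochs=30, batch_size=4, learning_rate=1e-3, seed=0)
model, history = unet.train(unet.build_model(cfg), train_t, val_t, cfg)
print(f"val dice: {history.epochs[0]['val_dice']:.3f} -> "
      f"{history.epochs[-1]['val_dice']:.3f}")

pair = synthetic.generate_image(synthetic.SynthSpec(
    height=64, width=64, phenotype="fragmented", n_objects=8, seed=900))
pred = unet.predict(model, pair.raw)
print(f"held-out dice: {evaluation.dice_coefficient(pred, pair.mask):.3f}")
```

prints (about a minute on one CPU core):

```
val dice: 0.320 -> 0.971
held-out dice: 0.914
```

The validation dice rises from 0.32 (untrained network) to 0.97, and the
model generalizes to an unseen synthetic image with dice 0.91 — i.e. 91%
pixel overlap with the ground truth. The same workflow is available from
the shell via the `mitoseg` command (`simulate`, `prepare`, `train`,
`finetune`, `predict --method unet|gaussian|hessian|laplacian`,
`evaluate`, `analyze`, `compare`); run `mitoseg --help`.

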