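"""Modified U-Net for mitochondria segmentation.

Encoder-decoder with skip connections: each level applies two 3x3
same-padding convolutions, channels double on the way down and halve on
the way up, and a 1x1 convolution plus sigmoid produces a per-pixel
foreground probability.  The modification relative to the classic U-Net:
every contracting-path convolution is followed by batch normalization
before its ReLU, and there are no dropout layers.  Expanding-path
convolutions are plain conv+ReLU.

Whole images of arbitrary size are segmented by tiling them with the same
overlapping 2x2 grid used for training data (reflect-padding where
needed), averaging probabilities on tile overlaps and thresholding at 0.5
by default.

Training minimizes pixel-weighted binary cross-entropy (the weight maps
of :mod:`mitoseg.pipeline` up-weight gaps between adjacent objects) with
Adam, recording training loss, validation loss and validation dice per
epoch.  Everything is seeded: two runs with the same config and data give
the same parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .pipeline import (AugmentationSpec, SplitSpec, augment, compute_weight_map,
                       extract_tiles, plan_tiles, stitch_tiles, train_val_split)

__all__ = [
    "ModelConfig", "SegmentationModel", "TrainingHistory", "build_model",
    "weighted_loss", "train", "predict", "finetune", "save_model", "load_model",
]

NORMALIZATION_RULE = "divide-by-dtype-max"


@dataclass(frozen=True)
class ModelConfig:
    depth: int = 4
    base_filters: int = 64
    input_side: int = 656
    batch_norm_contracting: bool = True
    dropout: bool = False
    learning_rate: float = 1e-4
    epochs: int = 10
    batch_size: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_filters < 1 or self.depth < 1:
            raise ValueError("need depth >= 1 and base_filters >= 1")
        if self.input_side % (2 ** self.depth) != 0:
            raise ValueError(
                f"input_side {self.input_side} not divisible by 2^depth = {2 ** self.depth}")
        if self.dropout:
            raise ValueError("this architecture replaces dropout with batch normalization")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


@dataclass
class TrainingHistory:
    epochs: list = field(default_factory=list)  # dicts: epoch, train_loss, val_loss, val_dice

    def __len__(self) -> int:
        return len(self.epochs)


class _UNetCore:
    """Layer graph and forward/backward plumbing."""

    def __init__(self, config: ModelConfig):
        rng = np.random.default_rng(config.seed)
        f, d = config.base_filters, config.depth
        bn = config.batch_norm_contracting

        def conv_block(cin, cout, with_bn):
            layers = [nn.Conv2d(cin, cout, 3, rng)]
            if with_bn:
                layers.append(nn.BatchNorm2d(cout))
            layers.append(nn.ReLU())
            layers += [nn.Conv2d(cout, cout, 3, rng)]
            if with_bn:
                layers.append(nn.BatchNorm2d(cout))
            layers.append(nn.ReLU())
            return layers

        self.enc = [conv_block(1 if i == 0 else f * 2 ** (i - 1), f * 2 ** i, bn)
                    for i in range(d)]
        self.pools = [nn.MaxPool2() for _ in range(d)]
        self.bottleneck = conv_block(f * 2 ** (d - 1), f * 2 ** d, bn)
        self.ups = []
        self.upconvs = []
        self.dec = []
        for i in reversed(range(d)):
            self.ups.append(nn.Upsample2())
            self.upconvs.append([nn.Conv2d(f * 2 ** (i + 1), f * 2 ** i, 3, rng), nn.ReLU()])
            self.dec.append([nn.Conv2d(f * 2 ** (i + 1), f * 2 ** i, 3, rng), nn.ReLU(),
                             nn.Conv2d(f * 2 ** i, f * 2 ** i, 3, rng), nn.ReLU()])
        self.final = nn.Conv2d(f, 1, 1, rng)

    def _all_layers(self):
        for block in self.enc:
            yield from block
        yield from self.pools
        yield from self.bottleneck
        yield from self.ups
        for block in self.upconvs:
            yield from block
        for block in self.dec:
            yield from block
        yield self.final

    @property
    def params(self):
        out = []
        for layer in self._all_layers():
            out.extend(layer.params)
        return out

    @staticmethod
    def _run(layers, x, training):
        for layer in layers:
            x = layer.forward(x, training)
        return x

    @staticmethod
    def _run_back(layers, dy):
        for layer in reversed(layers):
            dy = layer.backward(dy)
        return dy

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        """x: (N, 1, H, W) in [0, 1] -> logits (N, 1, H, W)."""
        skips = []
        for block, pool in zip(self.enc, self.pools):
            x = self._run(block, x, training)
            skips.append(x)
            x = pool.forward(x, training)
        x = self._run(self.bottleneck, x, training)
        self._skip_channels = []
        for up, upconv, dec, skip in zip(self.ups, self.upconvs, self.dec,
                                         reversed(skips)):
            x = up.forward(x, training)
            x = self._run(upconv, x, training)
            self._skip_channels.append(skip.shape[1])
            x = np.concatenate([skip, x], axis=1)
            x = self._run(dec, x, training)
        return self.final.forward(x, training)

    def backward(self, dlogits: np.ndarray) -> None:
        dy = self.final.backward(dlogits)
        dskips = []
        for upconv, up, dec, c_skip in zip(reversed(self.upconvs), reversed(self.ups),
                                           reversed(self.dec),
                                           reversed(self._skip_channels)):
            dy = self._run_back(dec, dy)
            dskip, dy = dy[:, :c_skip], dy[:, c_skip:]
            dskips.append(dskip)
            dy = self._run_back(upconv, dy)
            dy = up.backward(dy)
        dy = self._run_back(self.bottleneck, dy)
        # dskips[0] belongs to the shallowest skip; encoder backward runs deep-first
        for block, pool, dskip in zip(reversed(self.enc), reversed(self.pools),
                                      reversed(dskips)):
            dy = pool.backward(dy)
            dy = dy + dskip
            dy = self._run_back(block, dy)

    # -- serialization -------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {}
        for i, layer in enumerate(self._all_layers()):
            if isinstance(layer, nn.Conv2d):
                state[f"l{i}_W"] = layer.W
                state[f"l{i}_b"] = layer.b
            elif isinstance(layer, nn.BatchNorm2d):
                state[f"l{i}_gamma"] = layer.gamma
                state[f"l{i}_beta"] = layer.beta
                state[f"l{i}_rmean"] = layer.running_mean
                state[f"l{i}_rvar"] = layer.running_var
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self._all_layers()):
            if isinstance(layer, nn.Conv2d):
                layer.W[...] = state[f"l{i}_W"]
                layer.b[...] = state[f"l{i}_b"]
            elif isinstance(layer, nn.BatchNorm2d):
                layer.gamma[...] = state[f"l{i}_gamma"]
                layer.beta[...] = state[f"l{i}_beta"]
                layer.running_mean[...] = state[f"l{i}_rmean"]
                layer.running_var[...] = state[f"l{i}_rvar"]


@dataclass
class SegmentationModel:
    core: _UNetCore
    config: ModelConfig
    normalization: str = NORMALIZATION_RULE
    provenance: list = field(default_factory=list)  # training events, oldest first


def build_model(config: ModelConfig) -> SegmentationModel:
    """Construct a freshly initialized model (seeded by config.seed)."""
    return SegmentationModel(core=_UNetCore(config), config=config)


def normalize_intensity(image: np.ndarray) -> np.ndarray:
    """Scale an image to [0, 1] by its dtype range (the model's convention)."""
    if np.issubdtype(image.dtype, np.integer):
        return image.astype(np.float32) / np.iinfo(image.dtype).max
    return np.clip(image.astype(np.float32), 0.0, 1.0)


def weighted_loss(probabilities: np.ndarray, mask: np.ndarray,
                  weights: np.ndarray) -> float:
    """Mean over pixels of ``weights * binary cross-entropy``.

    Exactly zero iff the probabilities equal the binary mask everywhere.
    """
    if probabilities.shape != mask.shape or mask.shape != weights.shape:
        raise ValueError("probabilities, mask and weights must share a shape")
    p = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(mask, dtype=np.float64)
    eps = 1e-12
    bce = np.where(y > 0.5, -np.log(np.clip(p, eps, 1.0)),
                   -np.log(np.clip(1.0 - p, eps, 1.0)))
    return float(np.mean(weights * bce))


def dice_from_probabilities(prob: np.ndarray, mask: np.ndarray,
                            threshold: float = 0.5) -> float:
    pred = prob >= threshold
    truth = mask > 0.5
    denom = pred.sum() + truth.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(pred, truth).sum() / denom)


def _stack(tiles, idx=None):
    sel = tiles if idx is None else [tiles[i] for i in idx]
    raw = np.stack([normalize_intensity(np.asarray(t[0])) if np.issubdtype(
        np.asarray(t[0]).dtype, np.integer) else np.asarray(t[0], np.float32)
        for t in sel])[:, None]
    y = np.stack([np.asarray(t[1], np.float32) for t in sel])[:, None]
    w = np.stack([np.asarray(t[2], np.float32) for t in sel])[:, None]
    return raw.astype(np.float32), y, w


def train(model: SegmentationModel, train_tiles, val_tiles,
          config: ModelConfig | None = None) -> tuple[SegmentationModel, TrainingHistory]:
    """Mini-batch Adam on weighted BCE; returns the model and its history.

    ``train_tiles``/``val_tiles`` are lists of (raw, mask, weights) with the
    raw tile either float in [0, 1] or integer (scaled by dtype range).
    """
    config = config or model.config
    if len(train_tiles) == 0 or len(val_tiles) == 0:
        raise ValueError("training and validation sets must be non-empty")
    side = np.asarray(train_tiles[0][0]).shape[0]
    for t in list(train_tiles) + list(val_tiles):
        if np.asarray(t[0]).shape != (side, side):
            raise ValueError("all tiles must share one square size")
    if side % (2 ** config.depth) != 0:
        raise ValueError(f"tile side {side} not divisible by 2^depth")

    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.core.params, lr=config.learning_rate)
    xv, yv, wv = _stack(val_tiles)
    history = TrainingHistory()
    n = len(train_tiles)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb, wb = _stack(train_tiles, idx)
            logits = model.core.forward(xb, training=True)
            p = nn.sigmoid(logits)
            losses.append(weighted_loss(p, yb, wb))
            opt.zero_grad()
            dlogits = (wb * (p - yb) / p.size).astype(np.float32)
            model.core.backward(dlogits)
            opt.step()
        val_logits = _predict_batched(model, xv)
        pv = nn.sigmoid(val_logits)
        history.epochs.append({
            "epoch": epoch,
            "train_loss": float(np.mean(losses)),
            "val_loss": weighted_loss(pv, yv, wv),
            "val_dice": dice_from_probabilities(pv, yv),
        })
    model.provenance.append({
        "event": "train", "epochs": config.epochs, "n_train": n,
        "n_val": len(val_tiles), "seed": config.seed,
    })
    return model, history


def _predict_batched(model: SegmentationModel, x: np.ndarray,
                     batch: int = 8) -> np.ndarray:
    outs = [model.core.forward(x[i:i + batch], training=False)
            for i in range(0, len(x), batch)]
    return np.concatenate(outs) if outs else np.empty_like(x)


def predict_probabilities(model: SegmentationModel, image: np.ndarray) -> np.ndarray:
    """Tiled forward pass; overlaps averaged; returns per-pixel P(foreground)."""
    x = normalize_intensity(np.asarray(image))
    grid = plan_tiles(x.shape, divisor=2 ** model.config.depth)
    tiles = extract_tiles(x, grid)
    batch = np.stack(tiles)[:, None].astype(np.float32)
    logits = _predict_batched(model, batch)
    probs = [nn.sigmoid(l[0]) for l in logits]
    return stitch_tiles(probs, grid)


def predict(model: SegmentationModel, image: np.ndarray,
            threshold: float = 0.5) -> np.ndarray:
    """Segment an image of any size; returns a boolean mask of the same shape."""
    return predict_probabilities(model, image) >= threshold


def finetune(model: SegmentationModel, new_pairs, config: ModelConfig | None = None,
             w0: float = 10.0, sigma: float = 5.0,
             augmentation: AugmentationSpec | None = None) -> SegmentationModel:
    """Continue optimization from the current parameter state on new pairs.

    Each pair is tiled with the training grid, weight maps are computed,
    optional augmentation applied, and an 80/20 split made before resuming
    training.  With ``epochs=0`` the parameters are untouched; a provenance
    entry is appended either way.
    """
    config = config or model.config
    new_pairs = list(new_pairs)
    if not new_pairs:
        raise ValueError("finetune needs at least one image pair")
    shape = new_pairs[0].raw.shape
    triples = []
    for pair in new_pairs:
        if pair.raw.shape != shape:
            raise ValueError("all fine-tuning images must share one shape")
        grid = plan_tiles(shape, divisor=2 ** config.depth)
        raws = extract_tiles(normalize_intensity(pair.raw), grid)
        masks = extract_tiles(pair.mask.astype(np.float32), grid)
        for rt, mt in zip(raws, masks):
            mb = mt > 0.5
            wm = compute_weight_map(mb, w0=w0, sigma=sigma)
            triples.append((rt, mb, wm.weights))
    if augmentation is not None:
        triples = augment(triples, augmentation)
    if config.epochs > 0:
        if len(triples) > 1:
            tr, va = train_val_split(triples, SplitSpec(seed=config.seed))
        else:
            tr = va = triples
        train(model, tr, va, config)
        model.provenance[-1]["event"] = "finetune"
    else:
        model.provenance.append({"event": "finetune", "epochs": 0,
                                 "n_pairs": len(new_pairs), "seed": config.seed})
    return model


def save_model(model: SegmentationModel, path: str | Path) -> None:
    """Write parameters (.npz) plus a JSON sidecar with config and provenance."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "wb") as fh:
        np.savez(fh, **model.core.state_arrays())
    meta = {
        "config": asdict(model.config),
        "normalization": model.normalization,
        "provenance": model.provenance,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def load_model(path: str | Path) -> SegmentationModel:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    config = ModelConfig(**meta["config"])
    model = build_model(config)
    with np.load(path) as state:
        model.core.load_state_arrays(dict(state))
    model.normalization = meta["normalization"]
    model.provenance = meta["provenance"]
    return model
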