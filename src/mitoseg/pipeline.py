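"""Training-data preparation: tiling, weight maps, augmentation, splits.

A full-size micrograph is cut into a 2x2 grid of equal overlapping square
tiles whose side is the smallest multiple of the network downsampling
factor covering half the larger image dimension; a per-pixel loss weight
map is computed for each mask tile; each (raw, mask, weights) triple is
augmented a fixed number of times with a shared geometric transform; the
augmented set is split 80/20 into training and validation tiles.  A
leave-one-out fold scheme over whole images supports cross-validated
evaluation.

Pixel weights follow the border-aware weighting of the original U-Net:

    w(x) = w_c(x) + w0 * exp(-(d1(x) + d2(x))^2 / (2 sigma^2))

where d1, d2 are the Euclidean distances from x to the nearest and
second-nearest object and w_c balances class frequencies.  With fewer
than two objects the border term vanishes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.transform import AffineTransform, warp

__all__ = [
    "TileGrid", "WeightMap", "AugmentationSpec", "SplitSpec", "CVFold",
    "plan_tiles", "extract_tiles", "stitch_tiles", "compute_weight_map",
    "augment", "train_val_split", "make_loocv_folds",
]


@dataclass(frozen=True)
class TileGrid:
    tile_side: int
    origins: tuple[tuple[int, int], ...]
    parent_shape: tuple[int, int]


@dataclass(frozen=True)
class WeightMap:
    weights: np.ndarray
    w0: float
    sigma: float


@dataclass(frozen=True)
class AugmentationSpec:
    """Geometric augmentation ranges; each copy samples independently."""

    copies_per_tile: int = 80
    rotation_range: float = 180.0   # degrees, +/-
    flip_horizontal: bool = True
    flip_vertical: bool = True
    shift_range: float = 0.1        # fraction of tile side, +/-
    shear_range: float = 5.0        # degrees, +/-
    zoom_range: float = 0.1         # fraction, +/- around 1
    elastic_grid: int = 32          # px spacing of the displacement grid
    elastic_sd: float = 0.0         # px sd of displacements (0 disables)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.copies_per_tile < 1:
            raise ValueError("copies_per_tile must be >= 1")
        for name in ("rotation_range", "shift_range", "shear_range",
                     "zoom_range", "elastic_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class CVFold:
    fold_index: int
    train_images: tuple
    test_image: object


def plan_tiles(parent_shape: tuple[int, int], divisor: int = 16) -> TileGrid:
    """Plan the 2x2 overlapping tile grid for an image shape.

    The tile side is the smallest multiple of ``divisor`` that is at least
    half the larger dimension, so four tiles always cover the image, with a
    floor of ``4 * divisor`` so the network's deepest feature map keeps a
    4x4 extent.  If the side reaches or exceeds both dimensions the grid
    degenerates to a single tile (extraction pads reflectively).
    """
    h, w = parent_shape
    if h <= 0 or w <= 0:
        raise ValueError("parent dimensions must be positive")
    if divisor < 1:
        raise ValueError("divisor must be >= 1")
    half = math.ceil(max(h, w) / 2)
    # floor of 4*divisor keeps the deepest feature map at least 4x4
    side = max(divisor * math.ceil(half / divisor), 4 * divisor)
    if side >= h and side >= w:
        return TileGrid(side, ((0, 0),), (h, w))
    rows = sorted({0, max(0, h - side)})
    cols = sorted({0, max(0, w - side)})
    origins = tuple((r, c) for r in rows for c in cols)
    return TileGrid(side, origins, (h, w))


def _pad_to(image: np.ndarray, grid: TileGrid) -> np.ndarray:
    """Reflect-pad so that every tile of the grid fits inside."""
    h, w = grid.parent_shape
    need_h = max(r + grid.tile_side for r, _ in grid.origins) - h
    need_w = max(c + grid.tile_side for _, c in grid.origins) - w
    if need_h > 0 or need_w > 0:
        image = np.pad(image, ((0, max(0, need_h)), (0, max(0, need_w))), mode="reflect")
    return image


def extract_tiles(image: np.ndarray, grid: TileGrid) -> list[np.ndarray]:
    """Cut the planned tiles out of ``image`` (reflect-padded if needed)."""
    if tuple(image.shape) != grid.parent_shape:
        raise ValueError(f"image shape {image.shape} != planned {grid.parent_shape}")
    padded = _pad_to(image, grid)
    s = grid.tile_side
    return [padded[r:r + s, c:c + s].copy() for r, c in grid.origins]


def stitch_tiles(tiles: list[np.ndarray], grid: TileGrid) -> np.ndarray:
    """Reassemble tiles to the parent shape, averaging overlapping pixels."""
    if len(tiles) != len(grid.origins):
        raise ValueError("tile count does not match grid")
    h, w = grid.parent_shape
    s = grid.tile_side
    ph = max(h, max(r + s for r, _ in grid.origins))
    pw = max(w, max(c + s for _, c in grid.origins))
    acc = np.zeros((ph, pw), dtype=np.float64)
    cnt = np.zeros((ph, pw), dtype=np.float64)
    for tile, (r, c) in zip(tiles, grid.origins):
        if tile.shape != (s, s):
            raise ValueError("tile shape does not match grid tile_side")
        acc[r:r + s, c:c + s] += tile
        cnt[r:r + s, c:c + s] += 1.0
    return (acc / cnt)[:h, :w]


def compute_weight_map(mask: np.ndarray, w0: float = 10.0, sigma: float = 5.0) -> WeightMap:
    """Per-pixel loss weights: class balancing plus inter-object border term."""
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary")
    if w0 < 0 or sigma <= 0:
        raise ValueError("need w0 >= 0 and sigma > 0")
    mask = mask.astype(bool)

    # inverse class frequency, normalized so a balanced image has w_c = 1
    freq_fg = mask.mean()
    wc = np.empty(mask.shape, dtype=np.float64)
    wc[mask] = 0.5 / freq_fg if freq_fg > 0 else 1.0
    wc[~mask] = 0.5 / (1.0 - freq_fg) if freq_fg < 1 else 1.0

    labels, n = ndi.label(mask, structure=np.ones((3, 3)))
    if n >= 2:
        # distance from every pixel to each object; keep the two smallest
        dists = np.stack([
            ndi.distance_transform_edt(labels != i) for i in range(1, n + 1)
        ])
        dists.sort(axis=0)
        d1, d2 = dists[0], dists[1]
        border = w0 * np.exp(-((d1 + d2) ** 2) / (2.0 * sigma ** 2))
        weights = wc + border
    else:
        weights = wc
    return WeightMap(weights=weights, w0=float(w0), sigma=float(sigma))


def _sample_affine(rng: np.random.Generator, spec: AugmentationSpec, side: int):
    """Draw one transform; returns None for the exact identity."""
    rot = rng.uniform(-spec.rotation_range, spec.rotation_range) if spec.rotation_range else 0.0
    shear = rng.uniform(-spec.shear_range, spec.shear_range) if spec.shear_range else 0.0
    zoom = 1.0 + (rng.uniform(-spec.zoom_range, spec.zoom_range) if spec.zoom_range else 0.0)
    tr = rng.uniform(-spec.shift_range, spec.shift_range, size=2) * side if spec.shift_range else np.zeros(2)
    flip_h = spec.flip_horizontal and rng.random() < 0.5
    flip_v = spec.flip_vertical and rng.random() < 0.5
    if spec.elastic_sd > 0:
        gh = max(2, side // spec.elastic_grid + 1)
        disp = rng.normal(0, spec.elastic_sd, size=(2, gh, gh))
    else:
        disp = None
    if (rot == 0 and shear == 0 and zoom == 1.0 and not tr.any()
            and not flip_h and not flip_v and disp is None):
        return None

    center = (side - 1) / 2.0
    # rotate/shear/zoom about the tile center, then shift
    t = (AffineTransform(translation=(-center, -center))
         + AffineTransform(rotation=np.deg2rad(rot), shear=np.deg2rad(shear),
                           scale=(zoom, zoom))
         + AffineTransform(translation=(center + tr[1], center + tr[0])))
    flip = np.diag([-1.0 if flip_h else 1.0, -1.0 if flip_v else 1.0, 1.0])
    flip_t = AffineTransform(matrix=np.array(
        [[flip[0, 0], 0, (side - 1) if flip_h else 0],
         [0, flip[1, 1], (side - 1) if flip_v else 0],
         [0, 0, 1]]))
    return t + flip_t, disp


def _apply_transform(img: np.ndarray, transform, disp, order: int) -> np.ndarray:
    side = img.shape[0]
    if disp is None:
        return warp(img.astype(np.float64), transform.inverse, order=order,
                    mode="reflect", preserve_range=True)
    # elastic field on a coarse grid, upsampled to pixel resolution
    from scipy.ndimage import map_coordinates, zoom as ndzoom
    rows, cols = np.mgrid[0:side, 0:side].astype(np.float64)
    fy = ndzoom(disp[0], side / disp.shape[1], order=3)[:side, :side]
    fx = ndzoom(disp[1], side / disp.shape[2], order=3)[:side, :side]
    affined = warp(img.astype(np.float64), transform.inverse, order=order,
                   mode="reflect", preserve_range=True)
    coords = np.stack([rows + fy, cols + fx])
    return map_coordinates(affined, coords, order=order, mode="reflect")


def augment(triples: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
            spec: AugmentationSpec) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Generate ``copies_per_tile`` geometric variants of each triple.

    The same sampled transform is applied to the raw tile (bilinear), the
    mask (nearest neighbour, so it stays binary) and the weight map
    (bilinear).  With all ranges zero the copies are exact.
    """
    rng = np.random.default_rng(spec.seed)
    out = []
    for raw, mask, weights in triples:
        if raw.shape != mask.shape or raw.shape != weights.shape:
            raise ValueError("raw/mask/weights shapes differ within a triple")
        side = raw.shape[0]
        for _ in range(spec.copies_per_tile):
            t = _sample_affine(rng, spec, side)
            if t is None:
                out.append((raw.copy(), mask.copy(), weights.copy()))
                continue
            transform, disp = t
            a_raw = _apply_transform(raw, transform, disp, order=1)
            a_mask = _apply_transform(mask.astype(np.float64), transform, disp, order=0) > 0.5
            a_w = np.maximum(_apply_transform(weights, transform, disp, order=1), 1e-8)
            out.append((a_raw, a_mask, a_w))
    return out


def train_val_split(items: list, spec: SplitSpec = SplitSpec()) -> tuple[list, list]:
    """Seeded shuffle, then partition with |train| = round(fraction * N)."""
    if len(items) == 0:
        raise ValueError("cannot split an empty list")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(items))
    n_train = int(round(spec.train_fraction * len(items)))
    n_train = min(max(n_train, 1), len(items) - 1) if len(items) > 1 else n_train
    train = [items[i] for i in order[:n_train]]
    val = [items[i] for i in order[n_train:]]
    return train, val


def make_loocv_folds(image_ids: list) -> list[CVFold]:
    """One fold per image: train on all others, test on the held-out one."""
    if len(image_ids) < 2:
        raise ValueError("leave-one-out needs at least 2 images")
    folds = []
    for i, test in enumerate(image_ids):
        train = tuple(x for j, x in enumerate(image_ids) if j != i)
        folds.append(CVFold(fold_index=i, train_images=train, test_image=test))
    return folds
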