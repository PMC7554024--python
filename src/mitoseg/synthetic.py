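"""Seeded synthetic fluorescence-like images of mitochondrial networks.

Generates 2D images that emulate maximum-intensity-projection fluorescence
micrographs of mitochondria in one of four qualitative phenotype classes —
``fragmented`` (many small roundish objects), ``elongated`` (few long
tubules), ``tubular`` (a network of medium tubules) and ``mixed`` (a union
of tubules and fragments) — together with the exact binary ground-truth
mask of the rendered objects.

The rendering model is additive: objects are drawn at full intensity on a
zero canvas, blurred with a Gaussian (optics), a constant background is
added, and shot noise (Poisson) plus read noise (Gaussian) corrupt the
result before clipping and quantization to 8-bit.  Because the noiseless
image is background + a non-negative blurred signal, every mask pixel has
pre-noise intensity >= the background level by construction.

``perturb_mask`` produces controlled corruptions of a ground-truth mask
(dilate, erode, translate, drop_objects, merge_neighbors) used to exercise
the segmentation-accuracy metrics with known deviations.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import ellipse, line

__all__ = ["Phenotype", "SynthSpec", "ImagePair", "generate_image", "perturb_mask"]


class Phenotype(str, enum.Enum):
    elongated = "elongated"
    fragmented = "fragmented"
    tubular = "tubular"
    mixed = "mixed"


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic image.

    Defaults mirror a full-size micrograph (1300 x 1030 px, 8-bit) with a
    moderately dense network; tests use smaller canvases.
    """

    height: int = 1030
    width: int = 1300
    phenotype: Phenotype = Phenotype.tubular
    n_objects: int = 40
    tube_thickness_range: tuple[int, int] = (2, 4)
    blur_sigma: float = 1.0
    noise_level: float = 2.0        # sd of additive Gaussian read noise (8-bit units)
    background_level: float = 20.0  # constant background intensity (8-bit units)
    foreground_level: float = 160.0  # peak object intensity before blur
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("image dimensions must be positive")
        if self.n_objects < 0:
            raise ValueError("n_objects must be >= 0")
        lo, hi = self.tube_thickness_range
        if lo > hi or lo < 1:
            raise ValueError("tube_thickness_range must satisfy 1 <= lower <= upper")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")
        object.__setattr__(self, "phenotype", Phenotype(self.phenotype))


@dataclass
class ImagePair:
    """A raw intensity image and its binary ground-truth mask (same shape)."""

    raw: np.ndarray   # uint8
    mask: np.ndarray  # bool

    def __post_init__(self) -> None:
        if self.raw.shape != self.mask.shape:
            raise ValueError("raw and mask shapes differ")


def _draw_fragment(canvas: np.ndarray, rng: np.random.Generator,
                   thickness: tuple[int, int]) -> np.ndarray:
    """One small ellipse on an otherwise empty stamp."""
    h, w = canvas.shape
    stamp = np.zeros_like(canvas, dtype=bool)
    r0 = rng.uniform(3, h - 4)
    c0 = rng.uniform(3, w - 4)
    a = rng.uniform(thickness[0], thickness[1] + 2)
    b = rng.uniform(thickness[0], thickness[1])
    rot = rng.uniform(0, np.pi)
    rr, cc = ellipse(r0, c0, a, b, shape=canvas.shape, rotation=rot)
    stamp[rr, cc] = True
    return stamp


def _draw_tubule(canvas: np.ndarray, rng: np.random.Generator,
                 thickness: tuple[int, int], n_steps: int, step: float) -> np.ndarray:
    """A thickened random-walk polyline on an otherwise empty stamp."""
    h, w = canvas.shape
    stamp = np.zeros_like(canvas, dtype=bool)
    r = rng.uniform(2, h - 3)
    c = rng.uniform(2, w - 3)
    theta = rng.uniform(0, 2 * np.pi)
    for _ in range(n_steps):
        theta += rng.normal(0, 0.6)
        r2 = float(np.clip(r + step * np.sin(theta), 1, h - 2))
        c2 = float(np.clip(c + step * np.cos(theta), 1, w - 2))
        rr, cc = line(int(round(r)), int(round(c)), int(round(r2)), int(round(c2)))
        stamp[rr, cc] = True
        r, c = r2, c2
    radius = int(rng.integers(thickness[0], thickness[1] + 1)) // 2
    if radius > 0:
        stamp = ndi.binary_dilation(stamp, structure=_disk(radius))
    return stamp


def _disk(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    return (yy * yy + xx * xx) <= radius * radius


def _render_mask(spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    """Place objects; fragmented objects are guaranteed non-touching."""
    mask = np.zeros((spec.height, spec.width), dtype=bool)
    if spec.n_objects == 0:
        return mask

    if spec.phenotype is Phenotype.mixed:
        n_tub = spec.n_objects // 2
        kinds = ["tubule"] * n_tub + ["fragment"] * (spec.n_objects - n_tub)
    elif spec.phenotype is Phenotype.fragmented:
        kinds = ["fragment"] * spec.n_objects
    else:
        kinds = ["tubule"] * spec.n_objects

    # Elongated tubules take longer walks than normal tubular networks.
    n_steps = 24 if spec.phenotype is Phenotype.elongated else 10
    step = max(4.0, min(spec.height, spec.width) / 24)

    # 8-connected separation guard: for fragments, reject placements whose
    # dilation touches existing foreground, so each fragment is its own
    # connected component.
    occupied_dil = np.zeros_like(mask)
    for kind in kinds:
        for _attempt in range(200):
            if kind == "fragment":
                stamp = _draw_fragment(mask, rng, spec.tube_thickness_range)
            else:
                stamp = _draw_tubule(mask, rng, spec.tube_thickness_range,
                                     n_steps=n_steps, step=step)
            if not stamp.any():
                continue
            if kind == "fragment" and (stamp & occupied_dil).any():
                continue
            mask |= stamp
            occupied_dil |= ndi.binary_dilation(stamp, structure=np.ones((3, 3)))
            break
    return mask


def generate_image(spec: SynthSpec) -> ImagePair:
    """Render a seeded synthetic image/mask pair.

    The mask is the exact support of the rendered objects; the raw image is
    ``quantize(clip(blur(signal) + background + noise))`` in 8-bit.  The same
    spec (including seed) always yields a bitwise-identical pair.
    """
    rng = np.random.default_rng(spec.seed)
    mask = _render_mask(spec, rng)

    signal = mask.astype(np.float64) * spec.foreground_level
    if spec.blur_sigma > 0:
        signal = ndi.gaussian_filter(signal, spec.blur_sigma, mode="reflect")
    noiseless = signal + spec.background_level

    shot = rng.poisson(np.clip(noiseless, 0, None)).astype(np.float64) - noiseless
    read = rng.normal(0.0, spec.noise_level, size=noiseless.shape) if spec.noise_level > 0 else 0.0
    raw = np.clip(noiseless + shot + read, 0, 255).astype(np.uint8)
    return ImagePair(raw=raw, mask=mask)


_PERTURB_OPS = ("dilate", "erode", "translate", "drop_objects", "merge_neighbors")


def perturb_mask(mask: np.ndarray, op: str, magnitude: int, seed: int = 0) -> np.ndarray:
    """Apply a controlled corruption to a binary mask.

    Parameters
    ----------
    op:
        ``dilate`` / ``erode`` — morphological operation with a square
        structuring element of radius ``magnitude``;
        ``translate`` — shift by ``magnitude`` pixels in a seeded random
        direction (vacated pixels become background);
        ``drop_objects`` — remove ``magnitude`` randomly chosen connected
        components (8-connected);
        ``merge_neighbors`` — morphological closing with radius
        ``magnitude``, fusing objects closer than ~2*magnitude.
    magnitude:
        Perturbation strength in pixels/objects; 0 is the identity for
        every op.
    """
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary")
    mask = mask.astype(bool)
    if op not in _PERTURB_OPS:
        raise ValueError(f"unknown perturbation {op!r}; expected one of {_PERTURB_OPS}")
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    if magnitude == 0:
        return mask.copy()

    rng = np.random.default_rng(seed)
    size = 2 * magnitude + 1
    if op == "dilate":
        return ndi.binary_dilation(mask, structure=np.ones((size, size)))
    if op == "erode":
        return ndi.binary_erosion(mask, structure=np.ones((size, size)))
    if op == "merge_neighbors":
        return ndi.binary_closing(mask, structure=np.ones((size, size)))
    if op == "translate":
        theta = rng.uniform(0, 2 * np.pi)
        dr = int(round(magnitude * np.sin(theta)))
        dc = int(round(magnitude * np.cos(theta)))
        out = np.zeros_like(mask)
        src = mask[max(0, -dr): mask.shape[0] - max(0, dr),
                   max(0, -dc): mask.shape[1] - max(0, dc)]
        out[max(0, dr): mask.shape[0] + min(0, dr),
            max(0, dc): mask.shape[1] + min(0, dc)] = src
        return out
    # drop_objects
    labels, n = ndi.label(mask, structure=np.ones((3, 3)))
    if n == 0:
        return mask.copy()
    k = min(magnitude, n)
    drop = rng.choice(np.arange(1, n + 1), size=k, replace=False)
    return mask & ~np.isin(labels, drop)
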