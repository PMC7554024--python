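"""Classical feature-enhancement + thresholding segmenters.

The three comparator pipelines enhance the raw image with a single-scale
filter — Gaussian smoothing, a tubularness score from the eigenvalues of
the Hessian, or a (negated) Laplacian-of-Gaussian blob response — and then
binarize the enhanced image with a global threshold (Otsu by default).
They are deterministic baselines: identical inputs give identical masks.

Boundary handling for all filters is reflective.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import hessian_matrix, hessian_matrix_eigvals
from skimage.filters import threshold_mean, threshold_otsu, threshold_triangle

__all__ = ["Enhancer", "ThresholdMethod", "EnhancerSpec", "enhance",
           "threshold_segment", "segment"]


class Enhancer(str, enum.Enum):
    gaussian = "gaussian"
    hessian = "hessian"
    laplacian = "laplacian"


class ThresholdMethod(str, enum.Enum):
    otsu = "otsu"
    mean = "mean"
    triangle = "triangle"
    fixed = "fixed"


@dataclass(frozen=True)
class EnhancerSpec:
    method: Enhancer = Enhancer.gaussian
    sigma: float = 2.0
    threshold_method: ThresholdMethod = ThresholdMethod.otsu
    fixed_threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        object.__setattr__(self, "method", Enhancer(self.method))
        object.__setattr__(self, "threshold_method", ThresholdMethod(self.threshold_method))


def enhance(image: np.ndarray, spec: EnhancerSpec) -> np.ndarray:
    """Real-valued feature response at scale ``spec.sigma`` (same shape)."""
    img = np.asarray(image, dtype=np.float64)
    if spec.method is Enhancer.gaussian:
        return ndi.gaussian_filter(img, spec.sigma, mode="reflect")
    if spec.method is Enhancer.laplacian:
        # bright blobs/ridges give positive response under the sign flip
        return -ndi.gaussian_laplace(img, spec.sigma, mode="reflect")
    # hessian tubularness: magnitude of the most negative eigenvalue of the
    # scale-sigma Hessian (bright ridges curve downward across the ridge)
    helems = hessian_matrix(img, sigma=spec.sigma, mode="reflect",
                            use_gaussian_derivatives=True)
    eigs = hessian_matrix_eigvals(helems)  # sorted descending: eigs[-1] smallest
    return np.maximum(-eigs[-1], 0.0)


def threshold_segment(feature_grid: np.ndarray, spec: EnhancerSpec) -> np.ndarray:
    """Binarize an enhanced image with a global threshold.

    Automatic methods (otsu/mean/triangle) mark pixels strictly above the
    computed threshold; a fixed threshold is inclusive, so a threshold at
    the grid minimum selects everything.  A constant grid cannot be split
    by an automatic threshold: all-background is returned with a warning.
    """
    grid = np.asarray(feature_grid, dtype=np.float64)
    if not np.isfinite(grid).all():
        raise ValueError("feature grid must be finite")
    m = spec.threshold_method
    if m is ThresholdMethod.fixed:
        return grid >= spec.fixed_threshold
    if grid.max() == grid.min():
        warnings.warn("constant feature grid: threshold undefined, returning background")
        return np.zeros(grid.shape, dtype=bool)
    thresh = {ThresholdMethod.otsu: threshold_otsu,
              ThresholdMethod.mean: threshold_mean,
              ThresholdMethod.triangle: threshold_triangle}[m](grid)
    return grid > thresh


def segment(image: np.ndarray, spec: EnhancerSpec) -> np.ndarray:
    """Full comparator pipeline: enhance, then threshold."""
    return threshold_segment(enhance(image, spec), spec)
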