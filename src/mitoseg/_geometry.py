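"""Shared per-object geometry conventions.

All shape descriptors in the package go through this module so that the
evaluation metrics and the morphometry tables use identical conventions:

* area — pixel count.
* perimeter — boundary contour length in the weighted-step convention of
  ``skimage.measure.perimeter`` (a filled n x n square measures 4(n-1));
  an isolated pixel, whose contour degenerates, is assigned its outer
  boundary length 4 so perimeters stay positive.
* ellipse moments — second central moments with the +1/12-pixel variance
  correction (each pixel treated as a unit square, not a point), so a
  single pixel has equal major and minor axes and eccentricity 0, and
  thin lines keep a strictly positive minor axis.
* eccentricity in [0, 1); aspect_ratio = major/minor >= 1;
  solidity = area / convex hull area in (0, 1].
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage.measure import regionprops

SHAPE_DESCRIPTORS = ("area", "eccentricity", "aspect_ratio", "perimeter", "solidity")


def ellipse_from_moments(mu: np.ndarray, area: float) -> dict[str, float]:
    """Axis lengths, eccentricity and orientation from central moments.

    ``mu`` is the raw central-moment matrix (``regionprops.moments_central``);
    variances get the +1/12 correction for finite pixel extent.
    """
    a = mu[2, 0] / area + 1.0 / 12.0
    c = mu[0, 2] / area + 1.0 / 12.0
    b = mu[1, 1] / area
    common = np.sqrt(((a - c) / 2.0) ** 2 + b * b)
    lam1 = (a + c) / 2.0 + common
    lam2 = max((a + c) / 2.0 - common, 1e-12)
    major = 4.0 * np.sqrt(lam1)
    minor = 4.0 * np.sqrt(lam2)
    ecc = float(np.sqrt(max(0.0, 1.0 - lam2 / lam1)))
    orientation = 0.5 * np.arctan2(2.0 * b, a - c)
    return {
        "major_axis_length": float(major),
        "minor_axis_length": float(minor),
        "eccentricity": ecc,
        "aspect_ratio": float(major / minor),
        "orientation": float(orientation),
    }


def object_shape_table(labels: np.ndarray) -> pd.DataFrame:
    """Per-object shape descriptors for a labeled image.

    Returns one row per label with columns ``label`` plus
    :data:`SHAPE_DESCRIPTORS`; empty for zero objects.
    """
    rows = []
    for region in regionprops(np.asarray(labels)):
        area = float(region.area)
        perim = float(region.perimeter)
        if perim <= 0:
            perim = 4.0  # isolated pixel: outer boundary of a unit square
        ell = ellipse_from_moments(region.moments_central, area)
        rows.append({
            "label": int(region.label),
            "area": area,
            "eccentricity": ell["eccentricity"],
            "aspect_ratio": ell["aspect_ratio"],
            "perimeter": perim,
            "solidity": float(region.solidity),
            "major_axis_length": ell["major_axis_length"],
            "minor_axis_length": ell["minor_axis_length"],
            "orientation": ell["orientation"],
        })
    cols = ["label", *SHAPE_DESCRIPTORS,
            "major_axis_length", "minor_axis_length", "orientation"]
    return pd.DataFrame(rows, columns=cols)
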