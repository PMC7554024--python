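"""Per-object morphometry of segmented mitochondria.

For every connected component of a segmentation mask this module measures
ten morphological features — area, perimeter, minor and major axis length,
eccentricity, aspect ratio, solidity, extent, orientation, circularity —
and three intensity features (mean, min, max over the object's pixels of
the raw image), plus skeleton branch statistics (branch count and branch
lengths per object) and per-image summary tables.

Conventions (shared with the evaluation metrics via :mod:`._geometry`):
8-connected components by default; perimeter in the weighted-step
convention with isolated pixels assigned 4; ellipse axes from +1/12-pixel
corrected central moments; circularity ``4·pi·area / perimeter**2``
clipped at 1.  Branches are maximal skeleton paths between endpoint and/or
junction pixels, with length counting 1 per axial and sqrt(2) per diagonal
step; a closed loop with no endpoint or junction is counted as a cycle,
not a branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.measure import regionprops
from skimage.morphology import skeletonize

from ._geometry import ellipse_from_moments

__all__ = [
    "MORPHOLOGICAL_FEATURES", "INTENSITY_FEATURES", "BranchStats",
    "label_objects", "measure_objects", "branch_statistics", "summarize_image",
]

MORPHOLOGICAL_FEATURES = (
    "area", "perimeter", "minor_axis_length", "major_axis_length",
    "eccentricity", "aspect_ratio", "solidity", "extent", "orientation",
    "circularity",
)
INTENSITY_FEATURES = ("mean_intensity", "min_intensity", "max_intensity")


def label_objects(mask: np.ndarray, connectivity: int = 8) -> tuple[np.ndarray, int]:
    """Label 8- (default) or 4-connected components of a binary mask."""
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    structure = np.ones((3, 3)) if connectivity == 8 else None
    return ndi.label(mask.astype(bool), structure=structure)


def measure_objects(labels: np.ndarray, intensity: np.ndarray | None = None) -> pd.DataFrame:
    """One row per object: 10 morphological + 3 intensity features.

    Without a raw image the intensity columns are NaN (the mask alone
    carries no intensity information).
    """
    labels = np.asarray(labels)
    if intensity is not None:
        intensity = np.asarray(intensity)
        if intensity.shape != labels.shape:
            raise ValueError("intensity image shape must match the labels")
    rows = []
    for region in regionprops(labels, intensity_image=intensity):
        area = float(region.area)
        perim = float(region.perimeter)
        if perim <= 0:
            perim = 4.0
        ell = ellipse_from_moments(region.moments_central, area)
        row = {
            "label": int(region.label),
            "area": area,
            "perimeter": perim,
            "minor_axis_length": ell["minor_axis_length"],
            "major_axis_length": ell["major_axis_length"],
            "eccentricity": ell["eccentricity"],
            "aspect_ratio": ell["aspect_ratio"],
            "solidity": float(region.solidity),
            "extent": float(region.extent),
            "orientation": ell["orientation"],
            "circularity": min(1.0, 4.0 * np.pi * area / perim ** 2),
        }
        if intensity is not None:
            row["mean_intensity"] = float(region.intensity_mean)
            row["min_intensity"] = float(region.intensity_min)
            row["max_intensity"] = float(region.intensity_max)
        else:
            row.update(dict.fromkeys(INTENSITY_FEATURES, float("nan")))
        rows.append(row)
    return pd.DataFrame(rows, columns=["label", *MORPHOLOGICAL_FEATURES,
                                       *INTENSITY_FEATURES])


@dataclass
class BranchStats:
    """Skeleton branch statistics for one image."""

    n_objects: int
    n_branches: int
    n_cycles: int
    average_branch_length: float
    per_object: pd.DataFrame  # label, n_branches, total_branch_length
    branch_lengths: tuple[float, ...] = ()


_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _trace_branches(skel: np.ndarray) -> tuple[list[float], int]:
    """Walk a skeleton's pixel graph; returns branch lengths and cycle count.

    Nodes are pixels of degree != 2 (endpoints and junctions); a branch is
    the path between two node visits.  Components made only of degree-2
    pixels are pure cycles.
    """
    coords = {tuple(p) for p in np.argwhere(skel)}
    if not coords:
        return [], 0

    def neighbors(p):
        out = []
        for dr, dc in _NEIGHBORS:
            q = (p[0] + dr, p[1] + dc)
            if q not in coords:
                continue
            # a diagonal step that can be replaced by two orthogonal steps is
            # a redundant edge (it would inflate the degree at junctions)
            if dr != 0 and dc != 0 and ((p[0], q[1]) in coords
                                        or (q[0], p[1]) in coords):
                continue
            out.append(q)
        return out

    degree = {p: len(neighbors(p)) for p in coords}
    nodes = {p for p, d in degree.items() if d != 2}
    lengths: list[float] = []
    visited_edges: set[frozenset] = set()

    def step_len(a, b):
        return np.sqrt(2.0) if a[0] != b[0] and a[1] != b[1] else 1.0

    for node in sorted(nodes):
        for nb in sorted(neighbors(node)):
            edge = frozenset((node, nb))
            if edge in visited_edges:
                continue
            visited_edges.add(edge)
            length = step_len(node, nb)
            prev, cur = node, nb
            while cur not in nodes:
                nxt = [q for q in neighbors(cur) if q != prev]
                if not nxt:
                    break
                nxt = nxt[0]
                visited_edges.add(frozenset((cur, nxt)))
                length += step_len(cur, nxt)
                prev, cur = cur, nxt
            lengths.append(length)

    # pure cycles: components never touched by a node walk
    seen = {p for e in visited_edges for p in e} | nodes
    n_cycles = 0
    remaining = coords - seen
    while remaining:
        n_cycles += 1
        stack = [next(iter(remaining))]
        comp = set()
        while stack:
            p = stack.pop()
            if p in comp:
                continue
            comp.add(p)
            stack.extend(q for q in neighbors(p) if q not in comp)
        remaining -= comp
    # an isolated single pixel is an endpoint pair with itself: degree 0,
    # contributes no branch (length 0 object)
    return lengths, n_cycles


def branch_statistics(mask: np.ndarray, connectivity: int = 8) -> BranchStats:
    """Skeletonize each object and count/measure its branches."""
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary")
    labels, n = label_objects(mask.astype(bool), connectivity)
    all_lengths: list[float] = []
    rows = []
    for i in range(1, n + 1):
        obj = labels == i
        skel = skeletonize(obj)
        lengths, _cycles = _trace_branches(skel)
        rows.append({"label": i, "n_branches": len(lengths),
                     "total_branch_length": float(sum(lengths))})
        all_lengths.extend(lengths)
    skel_all = skeletonize(mask.astype(bool))
    _, n_cycles = _trace_branches(skel_all)
    per_object = pd.DataFrame(rows, columns=["label", "n_branches",
                                             "total_branch_length"])
    return BranchStats(
        n_objects=n,
        n_branches=len(all_lengths),
        n_cycles=n_cycles,
        average_branch_length=float(np.mean(all_lengths)) if all_lengths else 0.0,
        per_object=per_object,
        branch_lengths=tuple(all_lengths),
    )


def summarize_image(features: pd.DataFrame, branches: BranchStats | None = None) -> pd.DataFrame:
    """Per-feature n/mean/median/sd/min/max for one image's objects.

    Zero objects yield n = 0 with NaN markers, never zeros; the sd of a
    single object is likewise NaN.  Branch totals are appended as scalar
    rows when provided.
    """
    feature_cols = [c for c in features.columns if c != "label"]
    rows = []
    for col in feature_cols:
        vals = features[col].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        n = len(vals)
        rows.append({
            "feature": col, "n": n,
            "mean": float(np.mean(vals)) if n else float("nan"),
            "median": float(np.median(vals)) if n else float("nan"),
            "sd": float(np.std(vals, ddof=1)) if n > 1 else float("nan"),
            "min": float(np.min(vals)) if n else float("nan"),
            "max": float(np.max(vals)) if n else float("nan"),
        })
    summary = pd.DataFrame(rows)
    if branches is not None:
        extra = pd.DataFrame([
            {"feature": "n_objects", "n": branches.n_objects,
             "mean": float(branches.n_objects)},
            {"feature": "n_branches", "n": branches.n_branches,
             "mean": float(branches.n_branches)},
            {"feature": "average_branch_length", "n": branches.n_branches,
             "mean": branches.average_branch_length},
        ])
        summary = pd.concat([summary, extra], ignore_index=True)
    return summary
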