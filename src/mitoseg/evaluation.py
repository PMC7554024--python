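"""Morphological segmentation-accuracy framework.

Segmentation quality is scored three ways:

* **Dice coefficient** — pixelwise overlap ``2|P ∩ T| / (|P| + |T|)``.
* **Average fold deviation** — ground-truth and predicted objects are
  matched by pixel overlap; for every one-to-one matched pair and each of
  five shape descriptors (area, eccentricity, aspect ratio, perimeter,
  solidity) the fold deviation ``max(g, p)/min(g, p)`` is computed and
  averaged per image and descriptor.  Objects matching more than one
  partner (splits/merges) are excluded, so the score isolates *shape*
  fidelity of correctly detected objects.
* **Energy distance** — for each image and descriptor, the distance
  between the full ground-truth and predicted descriptor distributions
  (all objects, matched or not), which also penalizes false positives and
  missed objects.  Energy distances are normalized per descriptor by the
  maximum across methods and images before statistical comparison, since
  the descriptors live on very different scales.

Labeling uses 8-connectivity by default so diagonally-linked tubules
count as single objects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from ._geometry import SHAPE_DESCRIPTORS, object_shape_table

__all__ = [
    "SHAPE_DESCRIPTORS", "MatchTable", "dice_coefficient", "label_mask",
    "match_objects", "shape_descriptors", "fold_deviation",
    "average_fold_deviation", "energy_distance", "normalize_energy_distances",
    "evaluate_method",
]


def dice_coefficient(pred: np.ndarray, truth: np.ndarray) -> float:
    """``2|P ∩ T| / (|P| + |T|)``; two empty masks agree perfectly (1.0)."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    p = pred > 0
    t = truth > 0
    denom = int(p.sum()) + int(t.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((p & t).sum()) / denom


def label_mask(mask: np.ndarray, connectivity: int = 8) -> tuple[np.ndarray, int]:
    """Connected components of a binary mask (labels 1..k)."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    structure = np.ones((3, 3)) if connectivity == 8 else None
    return ndi.label(np.asarray(mask) > 0, structure=structure)


@dataclass
class MatchTable:
    """Overlap pairs between ground-truth and predicted objects.

    ``pairs`` has one row per (gt, pred) object pair sharing at least
    ``min_overlap`` pixels; multiplicity flags identify clean one-to-one
    matches versus split/merged objects, and the unmatched lists hold
    objects with no partner at all.
    """

    pairs: pd.DataFrame                       # gt_id, pred_id, overlap_pixels
    n_gt: int
    n_pred: int
    unmatched_gt: tuple[int, ...] = ()
    unmatched_pred: tuple[int, ...] = ()

    @property
    def one_to_one(self) -> pd.DataFrame:
        """Pairs whose two objects each appear in exactly one pair."""
        if self.pairs.empty:
            return self.pairs
        gt_counts = self.pairs["gt_id"].value_counts()
        pred_counts = self.pairs["pred_id"].value_counts()
        keep = (self.pairs["gt_id"].map(gt_counts) == 1) & \
               (self.pairs["pred_id"].map(pred_counts) == 1)
        return self.pairs[keep]


def match_objects(gt_labels: np.ndarray, pred_labels: np.ndarray,
                  min_overlap: int = 1) -> MatchTable:
    """Record every ground-truth/prediction object pair sharing pixels."""
    gt_labels = np.asarray(gt_labels)
    pred_labels = np.asarray(pred_labels)
    if gt_labels.shape != pred_labels.shape:
        raise ValueError("label images must share a shape")
    both = (gt_labels > 0) & (pred_labels > 0)
    if both.any():
        pairs, counts = np.unique(
            np.stack([gt_labels[both], pred_labels[both]]), axis=1, return_counts=True)
        keep = counts >= max(1, min_overlap)
        df = pd.DataFrame({"gt_id": pairs[0][keep], "pred_id": pairs[1][keep],
                           "overlap_pixels": counts[keep]})
    else:
        df = pd.DataFrame(columns=["gt_id", "pred_id", "overlap_pixels"])
    gt_ids = np.unique(gt_labels[gt_labels > 0])
    pred_ids = np.unique(pred_labels[pred_labels > 0])
    return MatchTable(
        pairs=df,
        n_gt=len(gt_ids),
        n_pred=len(pred_ids),
        unmatched_gt=tuple(int(i) for i in gt_ids if i not in set(df["gt_id"])),
        unmatched_pred=tuple(int(i) for i in pred_ids if i not in set(df["pred_id"])),
    )


def shape_descriptors(labels: np.ndarray) -> pd.DataFrame:
    """Per-object table of the five shape descriptors (one row per label)."""
    return object_shape_table(labels)[["label", *SHAPE_DESCRIPTORS]]


def fold_deviation(gt_value: float, pred_value: float) -> float:
    """Symmetric ratio ``max(g, p)/min(g, p)``; 1 means exact agreement."""
    if gt_value <= 0 or pred_value <= 0:
        raise ValueError("fold deviation requires strictly positive values")
    return max(gt_value, pred_value) / min(gt_value, pred_value)


def average_fold_deviation(match: MatchTable, gt_desc: pd.DataFrame,
                           pred_desc: pd.DataFrame, descriptor: str) -> float:
    """Mean fold deviation over one-to-one matched pairs for one descriptor.

    Pairs where the descriptor is zero on either side (possible only for
    eccentricity of perfectly symmetric objects, where a ratio is
    undefined) are skipped.  Returns NaN when no usable pair exists —
    a missing value, never zero.
    """
    ones = match.one_to_one
    if ones.empty:
        return float("nan")
    gt_map = gt_desc.set_index("label")[descriptor]
    pred_map = pred_desc.set_index("label")[descriptor]
    devs = []
    for gt_id, pred_id in zip(ones["gt_id"], ones["pred_id"]):
        g, p = float(gt_map[gt_id]), float(pred_map[pred_id])
        if g > 0 and p > 0:
            devs.append(fold_deviation(g, p))
    return float(np.mean(devs)) if devs else float("nan")


def energy_distance(sample_a, sample_b) -> float:
    """Energy distance between two 1D samples.

    ``sqrt(2 E|X-Y| - E|X-X'| - E|Y-Y'|)`` with all expectations taken over
    every ordered pair of the empirical samples (self-pairs included).
    Zero iff the samples coincide as distributions; symmetric.
    """
    a = np.asarray(sample_a, dtype=np.float64).ravel()
    b = np.asarray(sample_b, dtype=np.float64).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("energy distance requires non-empty samples")
    between = np.abs(a[:, None] - b[None, :]).mean()
    within_a = np.abs(a[:, None] - a[None, :]).mean()
    within_b = np.abs(b[:, None] - b[None, :]).mean()
    return float(np.sqrt(max(0.0, 2.0 * between - within_a - within_b)))


def normalize_energy_distances(records: pd.DataFrame,
                               column: str = "energy_distance") -> pd.DataFrame:
    """Divide each descriptor's energy distances by their global maximum.

    The maximum is taken over every row (all methods and images) sharing a
    descriptor, so normalized values lie in [0, 1] with at least one 1 per
    descriptor unless the whole column is zero (then 0, with a warning).
    """
    out = records.copy()
    normalized = np.full(len(out), np.nan)
    for desc, idx in out.groupby("descriptor").groups.items():
        vals = out.loc[idx, column].to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        top = finite.max() if finite.size else np.nan
        if not np.isfinite(top) or top == 0:
            if finite.size and top == 0:
                warnings.warn(f"all {desc} energy distances are zero; normalized to 0")
            normalized[out.index.get_indexer(idx)] = 0.0 if top == 0 else np.nan
        else:
            normalized[out.index.get_indexer(idx)] = vals / top
    out["normalized_energy_distance"] = normalized
    return out


def evaluate_method(gt_masks, pred_masks, image_ids=None,
                    connectivity: int = 8) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score a method's predictions against ground truth, image by image.

    Returns ``(dice_table, morphology_table)``: the first has one row per
    image (``image``, ``dice``), the second one row per image x descriptor
    (``image``, ``descriptor``, ``avg_fold_deviation``, ``energy_distance``)
    — the N = images x 5 layout used for statistical comparison.
    """
    gt_masks, pred_masks = list(gt_masks), list(pred_masks)
    if len(gt_masks) != len(pred_masks):
        raise ValueError("ground-truth and prediction lists differ in length")
    if image_ids is None:
        image_ids = list(range(len(gt_masks)))
    dice_rows, morph_rows = [], []
    for img_id, gt, pred in zip(image_ids, gt_masks, pred_masks):
        dice_rows.append({"image": img_id, "dice": dice_coefficient(pred, gt)})
        gt_lab, _ = label_mask(gt, connectivity)
        pred_lab, _ = label_mask(pred, connectivity)
        match = match_objects(gt_lab, pred_lab)
        gt_desc = shape_descriptors(gt_lab)
        pred_desc = shape_descriptors(pred_lab)
        for desc in SHAPE_DESCRIPTORS:
            afd = average_fold_deviation(match, gt_desc, pred_desc, desc)
            if len(gt_desc) and len(pred_desc):
                ed = energy_distance(gt_desc[desc], pred_desc[desc])
            else:
                ed = 0.0 if len(gt_desc) == len(pred_desc) else float("nan")
            morph_rows.append({"image": img_id, "descriptor": desc,
                               "avg_fold_deviation": afd, "energy_distance": ed})
    return pd.DataFrame(dice_rows), pd.DataFrame(morph_rows)
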