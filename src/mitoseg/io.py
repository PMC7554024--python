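"""TIFF input/output helpers.

Raw images are stored as single-page grayscale TIFF (8- or 16-bit);
binary masks as 8-bit TIFF with values {0, 255}.  In memory, masks are
boolean arrays and raw images keep their integer dtype.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import tifffile


def read_image(path: str | os.PathLike) -> np.ndarray:
    """Read a single-page grayscale TIFF as a 2D array."""
    arr = tifffile.imread(str(path))
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2D grayscale image, got shape {arr.shape}")
    return arr


def read_mask(path: str | os.PathLike) -> np.ndarray:
    """Read a binary mask TIFF; any nonzero pixel is foreground."""
    return read_image(path) > 0


def write_image(path: str | os.PathLike, image: np.ndarray) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(path), np.asarray(image))


def write_mask(path: str | os.PathLike, mask: np.ndarray) -> None:
    """Write a boolean mask as 8-bit {0, 255} TIFF."""
    write_image(path, (np.asarray(mask) > 0).astype(np.uint8) * 255)


def paired_files(raw_dir: str | os.PathLike, mask_dir: str | os.PathLike,
                 mask_suffix: str = "") -> list[tuple[Path, Path]]:
    """Match raw and mask TIFFs by stem; raise naming the unpaired files."""
    raw_dir, mask_dir = Path(raw_dir), Path(mask_dir)
    raws = sorted(p for p in raw_dir.glob("*.tif*") if p.is_file())
    masks = {p.stem.removesuffix(mask_suffix): p
             for p in mask_dir.glob("*.tif*") if p.is_file()}
    pairs, missing = [], []
    for r in raws:
        m = masks.pop(r.stem, None)
        if m is None:
            missing.append(r.name)
        else:
            pairs.append((r, m))
    if missing or masks:
        orphans = missing + [p.name for p in masks.values()]
        raise FileNotFoundError(f"unpaired raw/mask files: {', '.join(sorted(orphans))}")
    return pairs
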