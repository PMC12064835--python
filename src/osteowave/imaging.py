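"""Raster-based quantifications: bone-area segmentation and regional
proliferation fractions.

Bone area follows the fixed-tissue protocol: threshold the image at a
common intensity value, keep the largest 8-connected component (the frontal
bone), and convert its pixel count to µm².  Regional proliferation counts
PH3-positive nuclei in 100 µm windows ahead of, behind, and at the center
of the labelled bone.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
from skimage import measure

__all__ = [
    "SegmentationResult",
    "segment_bone_area",
    "RegionFraction",
    "regional_proliferation",
]


@dataclasses.dataclass
class SegmentationResult:
    """Largest-component bone segmentation of one image."""

    area_um2: float
    mask: np.ndarray               # boolean mask of the selected component
    n_pixels: int
    empty: bool                    # True if nothing was above threshold


def segment_bone_area(
    image: np.ndarray, threshold: float, pixel_size: float = 1.0
) -> SegmentationResult:
    """Threshold at a common intensity and keep the largest 8-connected region.

    Returns the selected component's area in µm² (pixel count times
    ``pixel_size``²).  An empty mask yields area 0 with the ``empty`` flag
    set rather than an error.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("image must be a 2D grayscale raster")
    lo, hi = float(image.min()), float(image.max())
    if not lo <= threshold <= hi:
        raise ValueError(
            f"threshold {threshold} outside the image value range [{lo}, {hi}]"
        )
    binary = image >= threshold
    if not np.any(binary):
        return SegmentationResult(0.0, np.zeros_like(binary), 0, True)
    labels = measure.label(binary, connectivity=2)   # 8-connectivity in 2D
    counts = np.bincount(labels.ravel())
    counts[0] = 0                                    # background
    best = int(np.argmax(counts))
    mask = labels == best
    n = int(counts[best])
    return SegmentationResult(n * pixel_size**2, mask, n, False)


@dataclasses.dataclass
class RegionFraction:
    """Percentage of PH3-positive nuclei in one region."""

    region: str
    percent_positive: float        # NaN when the region holds no nuclei
    n_positive: int
    n_total: int
    empty: bool


def regional_proliferation(
    positions_x: Sequence[float],
    ph3_positive: Sequence[bool],
    front_x: float,
    center_x: float,
    box: float = 100.0,
) -> dict[str, RegionFraction]:
    """PH3-positive percentages in the three standard 100 µm windows.

    Regions (with +x medial and the bone at low x):
    ``um_ahead`` — undifferentiated mesenchyme within ``box`` µm medial of
    the front; ``bone_behind`` — bone within ``box`` µm lateral of the
    front; ``bone_center`` — a ``box`` µm window centred on ``center_x``
    (the thickest part of the labelled bone).  Empty regions are flagged
    and their percentage is NaN.
    """
    x = np.asarray(positions_x, dtype=float)
    pos = np.asarray(ph3_positive, dtype=bool)
    if len(x) != len(pos):
        raise ValueError("positions and labels must have equal length")
    windows = {
        "um_ahead": (front_x, front_x + box),
        "bone_behind": (front_x - box, front_x),
        "bone_center": (center_x - box / 2, center_x + box / 2),
    }
    out: dict[str, RegionFraction] = {}
    for name, (lo, hi) in windows.items():
        mask = (x >= lo) & (x < hi)
        n_tot = int(np.sum(mask))
        n_pos = int(np.sum(pos[mask]))
        if n_tot == 0:
            out[name] = RegionFraction(name, float("nan"), 0, 0, True)
        else:
            out[name] = RegionFraction(name, 100.0 * n_pos / n_tot, n_pos, n_tot, False)
    return out
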