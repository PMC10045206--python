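"""PCAT segmentation from vessel-wall masks.

The pericoronary adipose tissue (PCAT) of a slice is defined by two
rules applied in sequence:

1. a peri-vessel annulus: voxels outside the (filled) outer-wall region
   whose Euclidean distance to that region, measured in millimetres, is
   at most one vessel diameter;
2. the adipose attenuation window: HU in [-190, -30], inclusive at both
   ends.

The vessel diameter is the per-slice equivalent-disc diameter of the
outer-wall region, ``2 * sqrt(area / pi)``; it is rotation invariant and
well defined for irregular walls.  All processing is per-slice (2-D), as
appropriate for straightened multiplanar-reformatted vessel stacks.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from .core import FAT_HU_WINDOW, PCATMask, VesselVolume, WallSegmentation

logger = logging.getLogger(__name__)


def vessel_diameter(outer_wall_mask: np.ndarray, spacing_mm: tuple[float, float]) -> float:
    """Equivalent-disc diameter (mm) of the filled outer-wall region.

    Parameters
    ----------
    outer_wall_mask
        2-D boolean mask of the filled outer-wall region.
    spacing_mm
        In-plane (dy, dx) voxel spacing in mm.

    Returns
    -------
    float
        ``2 * sqrt(area / pi)`` with area in mm^2.
    """
    outer_wall_mask = np.asarray(outer_wall_mask, dtype=bool)
    n = int(outer_wall_mask.sum())
    if n == 0:
        raise ValueError("no wall on slice")
    dy, dx = spacing_mm
    area = n * dy * dx
    return float(2.0 * np.sqrt(area / np.pi))


def pcat_candidate_annulus(
    outer_wall_mask: np.ndarray,
    diameter_mm: float,
    spacing_mm: tuple[float, float],
) -> np.ndarray:
    """Peri-vessel annulus of radial width ``diameter_mm`` around the wall.

    Returns the voxels strictly outside the outer-wall region whose
    Euclidean distance (in mm, anisotropy honoured via the distance
    transform sampling) to the region is <= ``diameter_mm``.  A
    non-positive diameter yields an empty mask.
    """
    outer_wall_mask = np.asarray(outer_wall_mask, dtype=bool)
    if not outer_wall_mask.any():
        raise ValueError("no wall on slice")
    if diameter_mm <= 0:
        return np.zeros_like(outer_wall_mask)
    dist = ndimage.distance_transform_edt(~outer_wall_mask, sampling=spacing_mm)
    return (dist > 0) & (dist <= diameter_mm)


def apply_hu_window(
    volume_slice: np.ndarray,
    candidate: np.ndarray,
    lo: float = FAT_HU_WINDOW[0],
    hi: float = FAT_HU_WINDOW[1],
) -> np.ndarray:
    """Keep candidate voxels with HU in [lo, hi] (inclusive both ends)."""
    volume_slice = np.asarray(volume_slice)
    candidate = np.asarray(candidate, dtype=bool)
    if volume_slice.shape != candidate.shape:
        raise ValueError("volume slice and candidate mask shapes differ")
    return candidate & (volume_slice >= lo) & (volume_slice <= hi)


def segment_pcat(
    volume: VesselVolume,
    walls: WallSegmentation,
    range_kind: str = "Vessel",
    hu_window: tuple[float, float] = FAT_HU_WINDOW,
    exclude_proximal_mm: float = 0.0,
) -> PCATMask:
    """Compose annulus + HU-window rules over a frame range.

    Parameters
    ----------
    volume, walls
        The vessel stack and its wall segmentation.
    range_kind
        "LOI" restricts to the lesion-of-interest frames, "Vessel" to the
        whole-vessel frames.
    exclude_proximal_mm
        Optionally drop this many millimetres of the most proximal
        (lowest-index) slices of the selected range, as done for
        right-coronary ostia; default 0 (no exclusion).

    Slices with an empty wall are skipped and logged; the returned mask
    stack matches the volume shape, with non-selected slices empty.
    """
    indices = list(volume.slice_indices(range_kind))
    if exclude_proximal_mm > 0:
        skip = int(np.ceil(exclude_proximal_mm / volume.spacing_mm[0]))
        indices = indices[skip:]
    if not indices:
        raise ValueError(f"selected {range_kind} range is empty")
    lo, hi = hu_window
    spacing = volume.inplane_spacing
    masks = np.zeros_like(volume.voxels, dtype=bool)
    kept: list[int] = []
    for i in indices:
        wall = walls.outer_wall_masks[i]
        if not wall.any():
            logger.info("slice %d skipped: empty wall", i)
            continue
        annulus = pcat_candidate_annulus(wall, float(walls.diameter_mm[i]), spacing)
        masks[i] = apply_hu_window(volume.voxels[i], annulus, lo, hi)
        kept.append(i)
    if not kept:
        raise ValueError(f"no wall present anywhere in the {range_kind} range")
    return PCATMask(masks=masks, hu_window=(lo, hi), slice_indices=kept)
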