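"""Core data containers shared across the PCAT pipeline.

All image containers hold straightened-vessel stacks: axis 0 indexes
axial slices along the (virtually straightened) coronary centreline,
axes 1-2 are the in-plane rows/columns.  Hounsfield units (HU)
throughout; spacing is (dz, dy, dx) in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Adipose attenuation window in HU, inclusive at both ends.
FAT_HU_WINDOW: tuple[float, float] = (-190.0, -30.0)

#: Frame-range flavours: the registered lesion of interest vs the whole vessel.
RANGE_KINDS = ("LOI", "Vessel")

#: Binary vulnerability targets carried per vessel.
TARGETS = ("tcfa", "mc", "tcfa_mc")


@dataclass(frozen=True)
class VesselLabel:
    """Vessel-level vulnerable-plaque labels.

    ``tcfa`` marks thin-cap fibroatheroma, ``mc`` marks microchannels;
    the combined label is their conjunction and is derived, never stored
    independently.
    """

    tcfa: bool
    mc: bool

    @property
    def tcfa_mc(self) -> bool:
        return self.tcfa and self.mc

    def value(self, target: str) -> bool:
        if target not in TARGETS:
            raise ValueError(f"unknown target {target!r}; expected one of {TARGETS}")
        return getattr(self, target)

    def as_dict(self) -> dict[str, bool]:
        return {"tcfa": self.tcfa, "mc": self.mc, "tcfa_mc": self.tcfa_mc}


@dataclass
class VesselVolume:
    """HU voxel stack of one straightened vessel.

    ``loi_range`` and ``vessel_range`` are half-open slice intervals
    [a, b) with loi_range contained in vessel_range contained in
    [0, n_slices).
    """

    voxels: np.ndarray  # (n_slices, ny, nx) float HU
    spacing_mm: tuple[float, float, float]  # (dz, dy, dx)
    loi_range: tuple[int, int]
    vessel_range: tuple[int, int]
    vessel_id: str

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3-D (slice, row, col) array")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("HU values must be finite")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("all spacing components must be > 0")
        n = self.voxels.shape[0]
        a, b = self.loi_range
        c, d = self.vessel_range
        if not (0 <= c <= a < b <= d <= n):
            raise ValueError(
                f"require loi_range {self.loi_range} within vessel_range "
                f"{self.vessel_range} within [0, {n})"
            )

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def inplane_spacing(self) -> tuple[float, float]:
        return self.spacing_mm[1], self.spacing_mm[2]

    def slice_indices(self, range_kind: str) -> range:
        if range_kind == "LOI":
            return range(*self.loi_range)
        if range_kind == "Vessel":
            return range(*self.vessel_range)
        raise ValueError(f"range_kind must be one of {RANGE_KINDS}, got {range_kind!r}")


@dataclass
class WallSegmentation:
    """Per-slice lumen and outer vessel-wall masks.

    ``outer_wall_masks`` are the filled regions bounded by the outer wall
    contour (so lumen is a subset of the outer wall region on every
    slice).  ``diameter_mm`` is the per-slice equivalent-disc diameter of
    the outer-wall region, 0 where the slice has no wall.
    """

    lumen_masks: np.ndarray  # (n_slices, ny, nx) bool
    outer_wall_masks: np.ndarray  # (n_slices, ny, nx) bool
    diameter_mm: np.ndarray  # (n_slices,)

    def __post_init__(self) -> None:
        self.lumen_masks = np.asarray(self.lumen_masks, dtype=bool)
        self.outer_wall_masks = np.asarray(self.outer_wall_masks, dtype=bool)
        self.diameter_mm = np.asarray(self.diameter_mm, dtype=float)
        if self.lumen_masks.shape != self.outer_wall_masks.shape:
            raise ValueError("lumen and outer-wall stacks must share a shape")
        if self.diameter_mm.shape[0] != self.lumen_masks.shape[0]:
            raise ValueError("one diameter per slice required")
        if np.any(self.lumen_masks & ~self.outer_wall_masks):
            raise ValueError("lumen must be contained in the outer-wall region")
        nonempty = self.outer_wall_masks.any(axis=(1, 2))
        if np.any(nonempty & (self.diameter_mm <= 0)):
            raise ValueError("diameter_mm must be > 0 wherever the wall is nonempty")


@dataclass
class PCATMask:
    """Per-slice binary PCAT (fat) masks after the annulus + HU-window rules."""

    masks: np.ndarray  # (n_slices, ny, nx) bool
    hu_window: tuple[float, float] = FAT_HU_WINDOW
    slice_indices: list[int] = field(default_factory=list)  # slices actually segmented

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks, dtype=bool)

    @property
    def n_fat_voxels(self) -> np.ndarray:
        return self.masks.sum(axis=(1, 2))
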