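"""Fixed-window gray-level discretization.

HU values are binned into ``n_bins`` equal-width levels over the fixed
adipose window (-190, -30) rather than over the per-mask min/max, so
levels are comparable across vessels and slices.  Level 1 corresponds to
the window floor and level ``n_bins`` to the ceiling; values outside the
window are clamped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..core import FAT_HU_WINDOW

BIN_CHOICES = (8, 16, 32)


@dataclass(frozen=True)
class DiscretizationSpec:
    n_bins: int
    range_hu: tuple[float, float] = FAT_HU_WINDOW

    def __post_init__(self) -> None:
        if self.n_bins not in BIN_CHOICES:
            raise ValueError(f"n_bins must be one of {BIN_CHOICES}, got {self.n_bins}")
        lo, hi = self.range_hu
        if not hi > lo:
            raise ValueError("range_hu must satisfy hi > lo")

    @property
    def bin_width(self) -> float:
        lo, hi = self.range_hu
        return (hi - lo) / self.n_bins


def discretize(hu_values: np.ndarray, spec: DiscretizationSpec) -> np.ndarray:
    """Map HU values to integer levels 1..n_bins.

    ``level = min(floor((x - lo) / width) + 1, n_bins)``, with values
    clamped to the window first, so lo maps to 1 and hi maps to n_bins.
    """
    x = np.asarray(hu_values, dtype=float)
    lo, hi = spec.range_hu
    x = np.clip(x, lo, hi)
    levels = np.floor((x - lo) / spec.bin_width).astype(np.int64) + 1
    return np.minimum(levels, spec.n_bins)
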