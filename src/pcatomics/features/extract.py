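"""Per-slice feature extraction and across-slice aggregation.

The per-vessel feature vector is built in two steps:

1. every retained slice (>= ``min_fat_voxels`` in-mask voxels) yields
   113 base features — 21 shape, 17 first-order, 75 texture — at each of
   the three bin settings (8, 16, 32), i.e. a slices x 339 matrix;
2. each of the 339 columns is summarised across slices by min, max,
   mean and sample SD, giving 113 * 3 * 4 = 1356 named values.

Shape features ignore gray levels entirely and the bulk of the
first-order features are computed on raw HU, so those columns are
replicated identically across bin settings; they are kept per bin
setting anyway so that the 252 / 204 / 900 family partition of the 1356
values holds exactly.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ..core import PCATMask, VesselVolume
from .discretize import BIN_CHOICES, DiscretizationSpec, discretize
from .firstorder import FIRSTORDER_FEATURES, first_order_features
from .shape import SHAPE_FEATURES, shape_features
from .texture import (
    GLCM_FEATURES,
    GLDM_FEATURES,
    GLRLM_FEATURES,
    GLSZM_FEATURES,
    NGTDM_FEATURES,
    glcm_features,
    glcm_matrix,
    gldm_features,
    gldm_matrix,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)

logger = logging.getLogger(__name__)

AGG_STATS = ("min", "max", "mean", "sd")

FAMILY_FEATURES: dict[str, tuple[str, ...]] = {
    "shape": SHAPE_FEATURES,
    "firstorder": FIRSTORDER_FEATURES,
    "glcm": GLCM_FEATURES,
    "gldm": GLDM_FEATURES,
    "glrlm": GLRLM_FEATURES,
    "glszm": GLSZM_FEATURES,
    "ngtdm": NGTDM_FEATURES,
}

FAMILIES = tuple(FAMILY_FEATURES)
TEXTURE_FAMILIES = ("glcm", "gldm", "glrlm", "glszm", "ngtdm")

#: Minimum fat voxels for a slice to enter aggregation.
DEFAULT_MIN_FAT_VOXELS = 10


def slice_columns(bins: tuple[int, ...] = BIN_CHOICES) -> list[tuple[str, str, int]]:
    """Canonical (family, feature, n_bins) column order of the slice matrix."""
    return [
        (family, feature, n_bins)
        for n_bins in bins
        for family in FAMILIES
        for feature in FAMILY_FEATURES[family]
    ]


def feature_vector_names(bins: tuple[int, ...] = BIN_CHOICES) -> list[str]:
    """Canonical 1356 feature names, ``{stat}_{family}_{feature}_{bins}b``.

    Ordered by (stat, family, feature, bins): this is also the canonical
    column order used by the correlation-pruning stage.
    """
    return [
        f"{stat}_{family}_{feature}_{n_bins}b"
        for stat in AGG_STATS
        for family in FAMILIES
        for feature in FAMILY_FEATURES[family]
        for n_bins in bins
    ]


def parse_feature_name(name: str) -> tuple[str, str, str, int]:
    """Split a vector name back into (stat, family, feature, n_bins)."""
    stat, rest = name.split("_", 1)
    body, bins_part = rest.rsplit("_", 1)
    family, feature = body.split("_", 1)
    return stat, family, feature, int(bins_part[:-1])


def family_of(name: str) -> str:
    return parse_feature_name(name)[1]


def extract_slice_features(
    volume_slice: np.ndarray,
    pcat_slice_mask: np.ndarray,
    spec: DiscretizationSpec,
    spacing_mm: tuple[float, float],
) -> dict[tuple[str, str], float]:
    """The 113 base features of one slice at one bin setting.

    Keys are (family, feature) pairs; values are finite reals.
    """
    mask = np.asarray(pcat_slice_mask, dtype=bool)
    hu = np.asarray(volume_slice, dtype=float)[mask]
    levels_img = discretize(volume_slice, spec)
    levels_in = levels_img[mask]
    ng = spec.n_bins

    out: dict[tuple[str, str], float] = {}
    for feature, value in shape_features(mask, spacing_mm).items():
        out[("shape", feature)] = value
    for feature, value in first_order_features(hu, levels_in).items():
        out[("firstorder", feature)] = value
    for feature, value in glcm_features(glcm_matrix(levels_img, mask, ng)).items():
        out[("glcm", feature)] = value
    for feature, value in gldm_features(gldm_matrix(levels_img, mask, ng)).items():
        out[("gldm", feature)] = value
    for feature, value in glrlm_features(levels_img, mask, ng).items():
        out[("glrlm", feature)] = value
    for feature, value in glszm_features(levels_img, mask, ng).items():
        out[("glszm", feature)] = value
    for feature, value in ngtdm_features(levels_img, mask, ng).items():
        out[("ngtdm", feature)] = value
    return out


def slice_feature_matrix(
    volume: VesselVolume,
    pcat: PCATMask,
    bins: tuple[int, ...] = BIN_CHOICES,
    min_fat_voxels: int = DEFAULT_MIN_FAT_VOXELS,
) -> pd.DataFrame:
    """Slices x 339 matrix over the retained slices of a PCAT mask.

    Slices with fewer than ``min_fat_voxels`` fat voxels are excluded
    and logged; the row index records the retained slice indices.
    """
    spacing = volume.inplane_spacing
    specs = {n: DiscretizationSpec(n_bins=n) for n in bins}
    rows: dict[int, dict[tuple[str, str, int], float]] = {}
    for i in pcat.slice_indices:
        n_fat = int(pcat.masks[i].sum())
        if n_fat < min_fat_voxels:
            logger.info("slice %d excluded: %d fat voxels < %d", i, n_fat, min_fat_voxels)
            continue
        row: dict[tuple[str, str, int], float] = {}
        for n_bins, spec in specs.items():
            for (family, feature), value in extract_slice_features(
                volume.voxels[i], pcat.masks[i], spec, spacing
            ).items():
                row[(family, feature, n_bins)] = value
        rows[i] = row
    if not rows:
        raise ValueError("no PCAT in range: every slice is empty or below the voxel floor")
    columns = pd.MultiIndex.from_tuples(
        slice_columns(bins), names=["family", "feature", "n_bins"]
    )
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.columns = pd.MultiIndex.from_tuples(frame.columns, names=columns.names)
    return frame.reindex(columns=columns).sort_index()


def aggregate_features(matrix: pd.DataFrame) -> pd.Series:
    """Collapse the slice matrix into the 1356-entry feature vector.

    min, max, mean and sample (n-1) SD per column; SD is 0 when only a
    single slice was retained.
    """
    if matrix.shape[0] == 0:
        raise ValueError("no PCAT in range")
    stats = {
        "min": matrix.min(axis=0),
        "max": matrix.max(axis=0),
        "mean": matrix.mean(axis=0),
        "sd": matrix.std(axis=0, ddof=1).fillna(0.0),
    }
    bins = tuple(sorted({c[2] for c in matrix.columns}))
    values = {
        f"{stat}_{family}_{feature}_{n_bins}b": float(stats[stat][(family, feature, n_bins)])
        for stat in AGG_STATS
        for family, feature, n_bins in matrix.columns
    }
    # canonical (stat, family, feature, bins) order, restricted to the
    # columns actually present in the slice matrix
    names = [n for n in feature_vector_names(bins) if n in values]
    if len(names) != len(values):  # columns outside the registry (ad-hoc matrices)
        names = list(values)
    return pd.Series([values[n] for n in names], index=names, dtype=float)


def extract_feature_vector(
    volume: VesselVolume,
    pcat: PCATMask,
    bins: tuple[int, ...] = BIN_CHOICES,
    min_fat_voxels: int = DEFAULT_MIN_FAT_VOXELS,
) -> pd.Series:
    """Full per-vessel radiomic vector (1356 values at the default bins)."""
    return aggregate_features(slice_feature_matrix(volume, pcat, bins, min_fat_voxels))
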