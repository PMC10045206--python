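"""Vessel-level feature tables: radiomic vectors joined with labels."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import RANGE_KINDS, TARGETS, VesselLabel, VesselVolume, WallSegmentation
from .features import BIN_CHOICES, DEFAULT_MIN_FAT_VOXELS, extract_feature_vector
from .segmentation import segment_pcat


@dataclass
class FeatureTable:
    """Vessels x features matrix with per-vessel binary labels.

    ``features`` is indexed by vessel id; ``labels`` shares that index
    and has boolean columns tcfa / mc / tcfa_mc.
    """

    features: pd.DataFrame
    labels: pd.DataFrame
    range_kind: str

    def __post_init__(self) -> None:
        if self.range_kind not in RANGE_KINDS:
            raise ValueError(f"range_kind must be one of {RANGE_KINDS}")
        if not self.features.index.equals(self.labels.index):
            raise ValueError("features and labels must share a row index")
        if self.features.columns.duplicated().any():
            raise ValueError("feature column names must be unique")
        if self.features.isna().any().any():
            raise ValueError("feature table contains missing values")

    @property
    def n_vessels(self) -> int:
        return self.features.shape[0]

    @property
    def columns(self) -> list[str]:
        return list(self.features.columns)

    def y(self, target: str) -> np.ndarray:
        if target not in TARGETS:
            raise ValueError(f"unknown target {target!r}")
        return self.labels[target].to_numpy(dtype=int)

    def X(self, names: list[str] | None = None) -> np.ndarray:
        frame = self.features if names is None else self.features[list(names)]
        return frame.to_numpy(dtype=float)

    def subset(self, names: list[str]) -> "FeatureTable":
        return FeatureTable(
            features=self.features[list(names)].copy(),
            labels=self.labels,
            range_kind=self.range_kind,
        )

    def with_labels(self, labels: pd.DataFrame) -> "FeatureTable":
        """Same features under different labels (e.g. a permutation)."""
        return FeatureTable(features=self.features, labels=labels, range_kind=self.range_kind)


def labels_frame(labels: list[VesselLabel], index: pd.Index) -> pd.DataFrame:
    return pd.DataFrame(
        [lab.as_dict() for lab in labels], index=index, columns=list(TARGETS)
    ).astype(bool)


def build_feature_table(
    cohort: list[tuple[VesselVolume, WallSegmentation]],
    labels: list[VesselLabel],
    range_kind: str,
    bins: tuple[int, ...] = BIN_CHOICES,
    min_fat_voxels: int = DEFAULT_MIN_FAT_VOXELS,
    hu_window: tuple[float, float] | None = None,
) -> FeatureTable:
    """Segment PCAT and extract the radiomic vector for every vessel."""
    if len(cohort) != len(labels):
        raise ValueError("one label per vessel required")
    rows = {}
    for volume, walls in cohort:
        kwargs = {} if hu_window is None else {"hu_window": hu_window}
        pcat = segment_pcat(volume, walls, range_kind, **kwargs)
        rows[volume.vessel_id] = extract_feature_vector(volume, pcat, bins, min_fat_voxels)
    features = pd.DataFrame.from_dict(rows, orient="index")
    features.index.name = "vessel_id"
    return FeatureTable(
        features=features,
        labels=labels_frame(labels, features.index),
        range_kind=range_kind,
    )


def permuted_labels(table: FeatureTable, seed: int) -> pd.DataFrame:
    """Row-permuted copy of the label frame (for null calibration)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(table.labels.shape[0])
    return pd.DataFrame(
        table.labels.to_numpy()[perm],
        index=table.labels.index,
        columns=table.labels.columns,
    ).astype(bool)
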