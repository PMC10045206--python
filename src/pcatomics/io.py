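"""File I/O: NIfTI volumes/masks, CSV tables, JSON sidecars.

Stacks are written with axis order (slice, row, col) and an affine that
encodes the (dz, dy, dx) spacing on its diagonal (reversed to match the
array axis order).  Frame ranges and identifiers travel in a JSON
sidecar next to each volume.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import PCATMask, VesselLabel, VesselVolume, WallSegmentation
from .tables import FeatureTable


def _affine(spacing_mm: tuple[float, float, float]) -> np.ndarray:
    dz, dy, dx = spacing_mm
    return np.diag([dz, dy, dx, 1.0])


def save_vessel(
    volume: VesselVolume, walls: WallSegmentation, out_dir: str | Path
) -> dict[str, str]:
    """Write one vessel's volume, wall masks and metadata sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = volume.vessel_id
    paths = {
        "volume": out_dir / f"{stem}_hu.nii.gz",
        "lumen": out_dir / f"{stem}_lumen.nii.gz",
        "outer_wall": out_dir / f"{stem}_outer_wall.nii.gz",
        "meta": out_dir / f"{stem}_meta.json",
    }
    affine = _affine(volume.spacing_mm)
    nib.save(nib.Nifti1Image(volume.voxels.astype(np.float32), affine), paths["volume"])
    nib.save(nib.Nifti1Image(walls.lumen_masks.astype(np.uint8), affine), paths["lumen"])
    nib.save(
        nib.Nifti1Image(walls.outer_wall_masks.astype(np.uint8), affine),
        paths["outer_wall"],
    )
    meta = {
        "vessel_id": volume.vessel_id,
        "spacing_mm": list(volume.spacing_mm),
        "loi_range": list(volume.loi_range),
        "vessel_range": list(volume.vessel_range),
        "diameter_mm": [float(d) for d in walls.diameter_mm],
    }
    paths["meta"].write_text(json.dumps(meta, indent=2))
    return {k: str(v) for k, v in paths.items()}


def load_vessel(meta_path: str | Path) -> tuple[VesselVolume, WallSegmentation]:
    """Read back a vessel written by :func:`save_vessel`."""
    meta_path = Path(meta_path)
    meta = json.loads(meta_path.read_text())
    stem = meta["vessel_id"]
    folder = meta_path.parent
    voxels = np.asarray(nib.load(folder / f"{stem}_hu.nii.gz").dataobj, dtype=np.float32)
    lumen = np.asarray(nib.load(folder / f"{stem}_lumen.nii.gz").dataobj).astype(bool)
    outer = np.asarray(nib.load(folder / f"{stem}_outer_wall.nii.gz").dataobj).astype(bool)
    volume = VesselVolume(
        voxels=voxels,
        spacing_mm=tuple(meta["spacing_mm"]),
        loi_range=tuple(meta["loi_range"]),
        vessel_range=tuple(meta["vessel_range"]),
        vessel_id=stem,
    )
    walls = WallSegmentation(
        lumen_masks=lumen,
        outer_wall_masks=outer,
        diameter_mm=np.asarray(meta["diameter_mm"], dtype=float),
    )
    return volume, walls


def save_labels(labels: list[VesselLabel], vessel_ids: list[str], path: str | Path) -> None:
    frame = pd.DataFrame([lab.as_dict() for lab in labels], index=vessel_ids)
    frame.index.name = "vessel_id"
    frame.to_csv(path)


def load_labels(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="vessel_id").astype(bool)


def save_pcat_mask(
    pcat: PCATMask,
    spacing_mm: tuple[float, float, float],
    diameter_mm: np.ndarray,
    mask_path: str | Path,
    csv_path: str | Path | None = None,
) -> None:
    """Write the PCAT mask stack plus the per-slice summary CSV."""
    nib.save(
        nib.Nifti1Image(pcat.masks.astype(np.uint8), _affine(spacing_mm)), str(mask_path)
    )
    if csv_path is not None:
        pd.DataFrame(
            {
                "slice": np.arange(pcat.masks.shape[0]),
                "n_fat_voxels": pcat.n_fat_voxels,
                "diameter_mm": diameter_mm,
            }
        ).to_csv(csv_path, index=False)


def save_feature_table(table: FeatureTable, path: str | Path) -> None:
    table.features.to_csv(path)


def load_feature_table(
    features_path: str | Path, labels_path: str | Path, range_kind: str
) -> FeatureTable:
    features = pd.read_csv(features_path, index_col="vessel_id")
    labels = load_labels(labels_path).loc[features.index]
    return FeatureTable(features=features, labels=labels, range_kind=range_kind)
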