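"""End-to-end orchestration: phantom -> segmentation -> features ->
selection -> evaluation, from a single config."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import FAT_HU_WINDOW, RANGE_KINDS, TARGETS
from .evaluation import CVProtocol, ModelResult, evaluate_model
from .features import BIN_CHOICES, DEFAULT_MIN_FAT_VOXELS
from .phantom import PhantomConfig, generate_cohort
from .selection import (
    CORRELATION_THRESHOLD,
    K_PER_FAMILY,
    MAX_FINAL_FEATURES,
    MRMR_K,
    SelectionTrace,
    select_features,
)
from .tables import FeatureTable, build_feature_table

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """One auditable home for every pipeline constant."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    hu_window: tuple[float, float] = FAT_HU_WINDOW
    bins: tuple[int, ...] = BIN_CHOICES
    min_fat_voxels: int = DEFAULT_MIN_FAT_VOXELS
    correlation_threshold: float = CORRELATION_THRESHOLD
    k_per_family: int = K_PER_FAMILY
    mrmr_k: int = MRMR_K
    max_final_features: int = MAX_FINAL_FEATURES
    cv: CVProtocol = field(default_factory=CVProtocol)
    targets: tuple[str, ...] = TARGETS
    ranges: tuple[str, ...] = RANGE_KINDS

    def __post_init__(self) -> None:
        for t in self.targets:
            if t not in TARGETS:
                raise ValueError(f"unknown target {t!r}")
        for r in self.ranges:
            if r not in RANGE_KINDS:
                raise ValueError(f"unknown range kind {r!r}")

    def as_dict(self) -> dict:
        data = dataclasses.asdict(self)
        data["phantom"] = dataclasses.asdict(self.phantom)
        data["cv"] = dataclasses.asdict(self.cv)
        return data

    def config_hash(self) -> str:
        canon = json.dumps(self.as_dict(), sort_keys=True, default=list)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        phantom = PhantomConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.pop("phantom", {}).items()
        })
        cv = CVProtocol(**raw.pop("cv", {}))
        cleaned = {
            k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()
        }
        return cls(phantom=phantom, cv=cv, **cleaned)


def _check_strata(table: FeatureTable, target: str, n_folds: int) -> None:
    y = table.y(target)
    counts = np.bincount(y, minlength=2)
    if counts.min() < n_folds:
        raise RuntimeError(
            f"stage selection/{target}: minority class has {counts.min()} vessels, "
            f"cannot stratify {n_folds} folds"
        )


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage for every (target, range) pair; return the manifest."""
    from .io import save_feature_table, save_labels  # local import keeps nibabel optional here

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logger.info("pipeline config hash %s", config.config_hash())

    cohort, labels = generate_cohort(config.phantom)
    vessel_ids = [v.vessel_id for v, _ in cohort]
    labels_path = out_dir / "labels.csv"
    save_labels(labels, vessel_ids, labels_path)

    manifest: dict = {
        "config": config.as_dict(),
        "config_hash": config.config_hash(),
        "seed": config.phantom.rng_seed,
        "files": {"labels": str(labels_path)},
        "results": [],
    }

    tables: dict[str, FeatureTable] = {}
    for range_kind in config.ranges:
        table = build_feature_table(
            cohort,
            labels,
            range_kind,
            bins=config.bins,
            min_fat_voxels=config.min_fat_voxels,
            hu_window=config.hu_window,
        )
        tables[range_kind] = table
        path = out_dir / f"features_{range_kind.lower()}.csv"
        save_feature_table(table, path)
        manifest["files"][f"features_{range_kind}"] = str(path)

    for range_kind, table in tables.items():
        for target in config.targets:
            _check_strata(table, target, config.cv.n_folds)
            trace = select_features(
                table,
                target,
                config.cv,
                correlation_threshold=config.correlation_threshold,
                k_per_family=config.k_per_family,
                mrmr_k=config.mrmr_k,
                max_final_features=config.max_final_features,
            )
            result = evaluate_model(table, trace.final_set, target, config.cv)
            stem = f"{target}_{range_kind.lower()}"
            trace_path = out_dir / f"trace_{stem}.json"
            trace_path.write_text(json.dumps(trace.as_dict(), indent=2))
            result_path = out_dir / f"result_{stem}.json"
            result_path.write_text(json.dumps(result.summary(), indent=2))
            roc_path = out_dir / f"roc_{stem}.csv"
            pd.DataFrame(result.mean_roc, columns=["fpr", "tpr"]).to_csv(
                roc_path, index=False
            )
            manifest["files"][f"trace_{stem}"] = str(trace_path)
            manifest["files"][f"result_{stem}"] = str(result_path)
            manifest["files"][f"roc_{stem}"] = str(roc_path)
            manifest["results"].append(result.summary())
            logger.info(
                "%s / %s: %d features, mean AUC %.3f (SD %.3f)",
                target,
                range_kind,
                len(trace.final_set),
                result.mean_auc,
                result.sd_auc,
            )

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
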