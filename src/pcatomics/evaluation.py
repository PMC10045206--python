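"""Repeated stratified cross-validated logistic evaluation.

The protocol is stratified k-fold (default 3) repeated many times
(default 1000).  Within a repeat, a logistic model with a light ridge
penalty is fitted on the training folds (features standardized on the
training folds only) and the held-out fold is scored; the pooled
out-of-fold scores of the repeat yield one AUC.  The reported summary is
the mean and sample SD of the per-repeat AUCs, plus a mean ROC curve by
vertical averaging of the per-repeat ROC curves on a fixed FPR grid.

The pooled-score AUC is numerically identical to the Mann-Whitney
U statistic divided by n+ * n-: both count correctly ranked
positive/negative pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .tables import FeatureTable

#: Inverse ridge strength of every multivariate logistic fit.  A light
#: penalty that leaves coefficients essentially unshrunk but keeps fits
#: finite when a feature separates the classes perfectly.
LIGHT_RIDGE_C = 100.0

#: FPR grid for vertical ROC averaging.
ROC_GRID = np.linspace(0.0, 1.0, 101)


@dataclass(frozen=True)
class CVProtocol:
    """Repeated stratified k-fold protocol parameters."""

    n_folds: int = 3
    n_repeats: int = 1000
    stratified: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("need at least two folds")
        if self.n_repeats < 1:
            raise ValueError("need at least one repeat")

    def with_repeats(self, n_repeats: int) -> "CVProtocol":
        return CVProtocol(self.n_folds, n_repeats, self.stratified, self.rng_seed)


def _repeat_seed(protocol: CVProtocol, repeat: int, attempt: int = 0) -> int:
    ss = np.random.SeedSequence([protocol.rng_seed, repeat, attempt])
    return int(ss.generate_state(1)[0])


def repeat_folds(
    y: np.ndarray, protocol: CVProtocol, repeat: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """(train, test) index pairs of one repeat.

    A shuffle whose training folds do not contain both classes is
    redrawn (with a derived seed) rather than skipped, so every repeat
    contributes exactly one AUC.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("need exactly two classes present")
    if counts.min() < protocol.n_folds:
        raise ValueError(
            f"minority class has {counts.min()} members; cannot stratify "
            f"{protocol.n_folds} folds"
        )
    for attempt in range(100):
        skf = StratifiedKFold(
            n_splits=protocol.n_folds,
            shuffle=True,
            random_state=_repeat_seed(protocol, repeat, attempt),
        )
        folds = list(skf.split(np.zeros_like(y), y))
        if all(np.unique(y[tr]).size == 2 for tr, _ in folds):
            return folds
    raise RuntimeError("could not produce a stratifiable shuffle")  # pragma: no cover


def _standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (train - mu) / sd, (test - mu) / sd


def pooled_cv_scores(
    X: np.ndarray,
    y: np.ndarray,
    protocol: CVProtocol,
    repeat: int,
    ridge_c: float = LIGHT_RIDGE_C,
) -> np.ndarray:
    """Out-of-fold decision scores for every sample in one repeat."""
    scores = np.empty(y.shape[0], dtype=float)
    for train, test in repeat_folds(y, protocol, repeat):
        xtr, xte = _standardize(X[train], X[test])
        model = LogisticRegression(C=ridge_c, solver="lbfgs", max_iter=2000)
        model.fit(xtr, y[train])
        scores[test] = model.decision_function(xte)
    return scores


@dataclass
class ModelResult:
    """Outcome of repeated-CV evaluation of one feature set."""

    target: str
    range_kind: str
    feature_set: list[str]
    per_repeat_auc: np.ndarray
    mean_roc: np.ndarray  # (101, 2) columns FPR, TPR
    n_vessels: int

    @property
    def mean_auc(self) -> float:
        return float(self.per_repeat_auc.mean())

    @property
    def sd_auc(self) -> float:
        return float(self.per_repeat_auc.std(ddof=1)) if self.per_repeat_auc.size > 1 else 0.0

    def summary(self) -> dict:
        return {
            "target": self.target,
            "range_kind": self.range_kind,
            "feature_set": list(self.feature_set),
            "n_features": len(self.feature_set),
            "n_vessels": self.n_vessels,
            "n_repeats": int(self.per_repeat_auc.size),
            "mean_auc": self.mean_auc,
            "sd_auc": self.sd_auc,
        }


def evaluate_model(
    table: FeatureTable,
    feature_set: list[str],
    target: str,
    cv: CVProtocol,
    ridge_c: float = LIGHT_RIDGE_C,
) -> ModelResult:
    """Repeated-CV evaluation of a fixed feature set."""
    feature_set = list(feature_set)
    missing = set(feature_set) - set(table.columns)
    if missing:
        raise ValueError(f"features not in table: {sorted(missing)}")
    X = table.X(feature_set)
    y = table.y(target)
    aucs = np.empty(cv.n_repeats, dtype=float)
    tprs = np.empty((cv.n_repeats, ROC_GRID.size), dtype=float)
    for r in range(cv.n_repeats):
        scores = pooled_cv_scores(X, y, cv, r, ridge_c)
        aucs[r] = roc_auc_score(y, scores)
        fpr, tpr, _ = roc_curve(y, scores)
        tprs[r] = np.interp(ROC_GRID, fpr, tpr)
    mean_roc = np.column_stack([ROC_GRID, tprs.mean(axis=0)])
    return ModelResult(
        target=target,
        range_kind=table.range_kind,
        feature_set=feature_set,
        per_repeat_auc=aucs,
        mean_roc=mean_roc,
        n_vessels=table.n_vessels,
    )


def compare_ranges(*results: ModelResult) -> pd.DataFrame:
    """Tabulate mean AUC +/- SD per (target, range) cell."""
    rows = [res.summary() for res in results]
    frame = pd.DataFrame(rows)
    return frame.sort_values(["target", "range_kind"]).reset_index(drop=True)
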