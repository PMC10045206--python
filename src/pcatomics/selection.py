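"""Cascade feature selection.

Stages, in order:

1. correlation pruning: greedy scan in the canonical column order
   dropping any column with |Pearson r| > 0.95 against an earlier kept
   column;
2. univariate screening: per-feature single-covariate logistic models
   under repeated stratified 3-fold CV, scored by mean pooled
   out-of-fold AUC;
3. family pooling: the 15 best features per family (7 families: shape,
   first-order and the five texture subfamilies), at most 105 names;
4. minimum-redundancy maximum-relevance (mRMR, mutual-information
   difference variant) down to 50, then re-applied towards 10;
5. coefficient-based recursive elimination of the remaining candidates,
   returning the subset with the best mean CV AUC (ties favour the
   smaller subset).

The univariate screen is computed on the full table, as is usual when
the goal is a per-feature association map; the resulting final-model CV
AUC therefore carries selection bias.  ``nested_model_auc`` provides the
honest held-out alternative, re-running a fast variant of the cascade
inside every training fold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .evaluation import (
    LIGHT_RIDGE_C,
    CVProtocol,
    _standardize,
    evaluate_model,
    repeat_folds,
)
from .features import family_of
from .tables import FeatureTable

logger = logging.getLogger(__name__)

CORRELATION_THRESHOLD = 0.95
K_PER_FAMILY = 15
MRMR_K = 50
MAX_FINAL_FEATURES = 10

#: Ridge penalty (on the slope) of the univariate logistic fits.
UNIVARIATE_RIDGE = 1e-2


@dataclass
class SelectionTrace:
    """Record of every cascade stage for one (target, range) run."""

    target: str
    range_kind: str
    surviving_after_correlation: list[str]
    univariate_auc: pd.Series
    top105: list[str]
    mrmr50: list[str]
    candidate10: list[str]
    final_set: list[str]
    elimination_path: list[dict] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "target": self.target,
            "range_kind": self.range_kind,
            "n_after_correlation": len(self.surviving_after_correlation),
            "surviving_after_correlation": self.surviving_after_correlation,
            "univariate_auc": {k: float(v) for k, v in self.univariate_auc.items()},
            "top105": self.top105,
            "mrmr50": self.mrmr50,
            "candidate10": self.candidate10,
            "final_set": self.final_set,
            "elimination_path": self.elimination_path,
        }


# ---------------------------------------------------------------------------
# Stage 1: correlation pruning
# ---------------------------------------------------------------------------

def prune_correlated(
    table: FeatureTable, threshold: float = CORRELATION_THRESHOLD
) -> FeatureTable:
    """Drop the later of any feature pair with |Pearson r| > threshold.

    The scan is greedy in the table's column order (the canonical
    stat/family/feature/bins order), so the earlier column of a
    correlated pair always survives.  Constant columns have undefined
    correlation; they are kept and a warning is emitted.
    """
    if table.n_vessels < 2:
        raise ValueError("need at least two rows to estimate correlations")
    X = table.X()
    names = table.columns
    sd = X.std(axis=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature columns: correlation undefined, kept",
            stacklevel=2,
        )
    centred = X - X.mean(axis=0)
    denom = np.where(sd > 0, sd, 1.0) * np.sqrt(X.shape[0])
    Z = centred / denom  # corr(a, b) = Z[:, a] @ Z[:, b]
    kept_idx: list[int] = []
    dropped: list[str] = []
    for j in range(len(names)):
        if constant[j]:
            kept_idx.append(j)
            continue
        if kept_idx:
            r = Z[:, kept_idx].T @ Z[:, j]
            live = ~constant[kept_idx]
            if np.any(np.abs(r[live]) > threshold):
                dropped.append(names[j])
                continue
        kept_idx.append(j)
    logger.info("correlation pruning dropped %d of %d features", len(dropped), len(names))
    return table.subset([names[j] for j in kept_idx])


# ---------------------------------------------------------------------------
# Stage 2: univariate CV-AUC screening
# ---------------------------------------------------------------------------

def _sigmoid(eta: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * np.clip(eta, -35.0, 35.0)))


def _fit_univariate_batch(
    x: np.ndarray, y: np.ndarray, ridge: float = UNIVARIATE_RIDGE, n_iter: int = 30
) -> tuple[np.ndarray, np.ndarray]:
    """Newton fit of intercept+slope logistic models for every column of x.

    ``x`` is (n, p), already standardized; the ridge acts on the slope
    only.  Returns arrays (a, b) of shape (p,).
    """
    n, p = x.shape
    a = np.zeros(p)
    b = np.zeros(p)
    yv = y[:, None].astype(float)
    for _ in range(n_iter):
        eta = a[None, :] + b[None, :] * x
        mu = _sigmoid(eta)
        w = np.maximum(mu * (1.0 - mu), 1e-12)
        resid = yv - mu
        ga = resid.sum(axis=0)
        gb = (x * resid).sum(axis=0) - ridge * b
        h_aa = w.sum(axis=0)
        h_ab = (w * x).sum(axis=0)
        h_bb = (w * x * x).sum(axis=0) + ridge
        det = h_aa * h_bb - h_ab**2
        da = (h_bb * ga - h_ab * gb) / det
        db = (h_aa * gb - h_ab * ga) / det
        a += da
        b += db
        if max(np.abs(da).max(), np.abs(db).max()) < 1e-8:
            break
    return a, b


def _columnwise_auc(y: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """ROC AUC of every score column via mid-rank Mann-Whitney counting.

    Identical to the ROC-curve AUC on the pooled scores, including tie
    handling (ties contribute half a concordant pair).
    """
    from scipy.stats import rankdata

    ranks = rankdata(scores, axis=0)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    pos_rank_sum = ranks[y == 1].sum(axis=0)
    return (pos_rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def univariate_auc_map(
    table: FeatureTable,
    target: str,
    cv: CVProtocol,
    features: list[str] | None = None,
) -> pd.Series:
    """Mean pooled-CV AUC of a single-feature logistic model, per feature.

    All features share the same fold splits (determined by
    ``cv.rng_seed``), so the map is a like-for-like comparison.
    """
    names = table.columns if features is None else list(features)
    X = table.X(names)
    y = table.y(target)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    auc_sum = np.zeros(len(names))
    for r in range(cv.n_repeats):
        scores = np.empty_like(X)
        for train, test in repeat_folds(y, cv, r):
            xtr, xte = _standardize(X[train], X[test])
            a, b = _fit_univariate_batch(xtr, y[train])
            scores[test] = a[None, :] + b[None, :] * xte
        auc_sum += _columnwise_auc(y, scores)
    return pd.Series(auc_sum / cv.n_repeats, index=names, name="mean_auc")


def univariate_auc(
    table: FeatureTable, feature: str, target: str, cv: CVProtocol
) -> float:
    """Mean CV AUC of one feature (same protocol as the full map)."""
    return float(univariate_auc_map(table, target, cv, features=[feature]).iloc[0])


# ---------------------------------------------------------------------------
# Stage 3: top-k per family
# ---------------------------------------------------------------------------

def top_k_per_family(auc_map: pd.Series, k: int = K_PER_FAMILY) -> list[str]:
    """Up to ``k`` highest-AUC features per family, ties broken by name.

    Families with fewer than ``k`` surviving features contribute all of
    them.  The result keeps the canonical column order.
    """
    chosen: set[str] = set()
    by_family: dict[str, list[str]] = {}
    for name in auc_map.index:
        by_family.setdefault(family_of(name), []).append(name)
    for family, names in by_family.items():
        ranked = sorted(names, key=lambda n: (-auc_map[n], n))
        if len(names) < k:
            logger.info("family %s exhausted: %d < %d features", family, len(names), k)
        chosen.update(ranked[:k])
    return [name for name in auc_map.index if name in chosen]


# ---------------------------------------------------------------------------
# Stage 4: mRMR (mutual-information difference)
# ---------------------------------------------------------------------------

def _discretize_3level(x: np.ndarray) -> np.ndarray:
    """3-level coding at mean +/- SD, the MI estimator's working alphabet."""
    mu, sd = x.mean(), x.std()
    out = np.ones(x.shape, dtype=int)
    out[x < mu - sd] = 0
    out[x > mu + sd] = 2
    return out


def _mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in MI (bits) between two small discrete vectors."""
    n = a.shape[0]
    joint: dict[tuple[int, int], int] = {}
    for pair in zip(a.tolist(), b.tolist()):
        joint[pair] = joint.get(pair, 0) + 1
    pa: dict[int, float] = {}
    pb: dict[int, float] = {}
    for (va, vb), c in joint.items():
        pa[va] = pa.get(va, 0.0) + c / n
        pb[vb] = pb.get(vb, 0.0) + c / n
    mi = 0.0
    for (va, vb), c in joint.items():
        p = c / n
        mi += p * np.log2(p / (pa[va] * pb[vb]))
    return float(max(mi, 0.0))


def mrmr_select(
    table: FeatureTable, candidates: list[str], target: str, k: int
) -> list[str]:
    """Greedy mRMR with the mutual-information difference criterion.

    The first pick maximizes relevance I(f; y); each subsequent pick
    maximizes I(f; y) - mean over already-selected s of I(f; s).
    Features are 3-level discretized at mean +/- SD for MI estimation.
    Ties are broken by candidate order, so the result is deterministic.
    """
    candidates = list(candidates)
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(candidates):
        raise ValueError(f"k={k} exceeds the {len(candidates)} candidates")
    if k == len(candidates):
        return candidates
    y = table.y(target)
    coded = {name: _discretize_3level(table.features[name].to_numpy()) for name in candidates}
    relevance = {name: _mutual_information(coded[name], y) for name in candidates}
    selected: list[str] = []
    remaining = list(candidates)
    redundancy = {name: 0.0 for name in candidates}  # running sum of MI vs selected
    while len(selected) < k:
        if selected:
            scores = [
                relevance[name] - redundancy[name] / len(selected) for name in remaining
            ]
        else:
            scores = [relevance[name] for name in remaining]
        best = remaining[int(np.argmax(scores))]
        selected.append(best)
        remaining.remove(best)
        for name in remaining:
            redundancy[name] += _mutual_information(coded[name], coded[best])
    return selected


# ---------------------------------------------------------------------------
# Stage 5: coefficient-based recursive elimination
# ---------------------------------------------------------------------------

def recursive_elimination(
    table: FeatureTable,
    candidates: list[str],
    target: str,
    cv: CVProtocol,
    ridge_c: float = LIGHT_RIDGE_C,
) -> tuple[list[str], list[dict]]:
    """Drop the smallest-|coefficient| feature until one remains.

    At each subset size the mean CV AUC is recorded; the returned final
    set is the subset with the highest mean AUC, ties resolved towards
    the smaller subset.  Coefficients are taken from a logistic fit on
    the full (standardized) table.
    """
    current = list(candidates)
    if not current:
        raise ValueError("no candidate features")
    y = table.y(target)
    path: list[dict] = []
    while True:
        result = evaluate_model(table, current, target, cv, ridge_c)
        path.append(
            {"features": list(current), "mean_auc": result.mean_auc, "sd_auc": result.sd_auc}
        )
        if len(current) == 1:
            break
        X = table.X(current)
        Xs = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        model = LogisticRegression(C=ridge_c, solver="lbfgs", max_iter=2000)
        model.fit(Xs, y)
        weakest = int(np.argmin(np.abs(model.coef_[0])))
        current.pop(weakest)
    best = max(path, key=lambda rec: (rec["mean_auc"], -len(rec["features"])))
    return list(best["features"]), path


# ---------------------------------------------------------------------------
# Full cascade
# ---------------------------------------------------------------------------

def select_features(
    table: FeatureTable,
    target: str,
    cv: CVProtocol,
    correlation_threshold: float = CORRELATION_THRESHOLD,
    k_per_family: int = K_PER_FAMILY,
    mrmr_k: int = MRMR_K,
    max_final_features: int = MAX_FINAL_FEATURES,
) -> SelectionTrace:
    """Run the full cascade and return the per-stage trace."""
    pruned = prune_correlated(table, correlation_threshold)
    auc_map = univariate_auc_map(pruned, target, cv)
    top105 = top_k_per_family(auc_map, k_per_family)
    mrmr50 = mrmr_select(table, top105, target, min(mrmr_k, len(top105)))
    candidate10 = mrmr_select(table, mrmr50, target, min(max_final_features, len(mrmr50)))
    final_set, path = recursive_elimination(table, candidate10, target, cv)
    return SelectionTrace(
        target=target,
        range_kind=table.range_kind,
        surviving_after_correlation=pruned.columns,
        univariate_auc=auc_map,
        top105=top105,
        mrmr50=mrmr50,
        candidate10=candidate10,
        final_set=final_set,
        elimination_path=path,
    )


# ---------------------------------------------------------------------------
# Nested (held-out) evaluation
# ---------------------------------------------------------------------------

def _fast_select(
    features: pd.DataFrame, y: np.ndarray, max_features: int
) -> list[str]:
    """Cheap training-fold-only cascade for nested evaluation.

    Rank-AUC screening per family followed by mRMR, with no inner CV:
    this is the selection step that runs inside every training fold of
    ``nested_model_auc``.
    """
    X = features.to_numpy(dtype=float)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    ranks = pd.DataFrame(X).rank(axis=0).to_numpy()
    auc = (ranks[y == 1].sum(axis=0) - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    auc = np.maximum(auc, 1.0 - auc)  # association strength, direction-free
    auc_map = pd.Series(auc, index=features.columns)
    pooled = top_k_per_family(auc_map, K_PER_FAMILY)
    ranked = sorted(pooled, key=lambda n: (-auc_map[n], n))[: 3 * max_features]
    stub = FeatureTable(
        features=features[ranked],
        labels=pd.DataFrame(
            {"tcfa": y.astype(bool), "mc": y.astype(bool), "tcfa_mc": y.astype(bool)},
            index=features.index,
        ),
        range_kind="Vessel",
    )
    k = min(max_features, len(ranked))
    return mrmr_select(stub, ranked, "tcfa", k)


def nested_model_auc(
    table: FeatureTable,
    target: str,
    cv: CVProtocol,
    max_features: int = MAX_FINAL_FEATURES,
    ridge_c: float = LIGHT_RIDGE_C,
) -> np.ndarray:
    """Per-repeat AUCs with selection nested inside every training fold.

    Feature selection sees only the training folds, so the pooled
    out-of-fold AUC is an honest estimate free of selection bias; under
    permuted labels it concentrates near 0.5.
    """
    y = table.y(target)
    aucs = np.empty(cv.n_repeats, dtype=float)
    for r in range(cv.n_repeats):
        scores = np.empty(y.shape[0], dtype=float)
        for train, test in repeat_folds(y, cv, r):
            chosen = _fast_select(table.features.iloc[train], y[train], max_features)
            X = table.features[chosen].to_numpy(dtype=float)
            xtr, xte = _standardize(X[train], X[test])
            model = LogisticRegression(C=ridge_c, solver="lbfgs", max_iter=2000)
            model.fit(xtr, y[train])
            scores[test] = model.decision_function(xte)
        aucs[r] = roc_auc_score(y, scores)
    return aucs
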