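"""Cascade feature selection: pruning, screening, mRMR, elimination."""

import numpy as np
import pandas as pd
import pytest

from pcatomics import (
    CVProtocol,
    FeatureTable,
    mrmr_select,
    prune_correlated,
    recursive_elimination,
    select_features,
    top_k_per_family,
    univariate_auc,
    univariate_auc_map,
)

import oracles


def make_table(X, y, names=None):
    names = names or [f"mean_glcm_f{j}_8b" for j in range(X.shape[1])]
    index = pd.Index([f"v{i}" for i in range(X.shape[0])], name="vessel_id")
    features = pd.DataFrame(X, index=index, columns=names)
    yb = np.asarray(y, dtype=bool)
    labels = pd.DataFrame({"tcfa": yb, "mc": yb, "tcfa_mc": yb}, index=index)
    return FeatureTable(features=features, labels=labels, range_kind="Vessel")


class TestPruneCorrelated:
    def test_duplicate_column_keeps_earlier(self, rng):
        x = rng.normal(size=20)
        table = make_table(np.column_stack([x, x, rng.normal(size=20)]), rng.random(20) < 0.5)
        pruned = prune_correlated(table)
        assert pruned.columns == [table.columns[0], table.columns[2]]

    def test_negated_column_dropped(self, rng):
        x = rng.normal(size=20)
        table = make_table(np.column_stack([x, -x]), rng.random(20) < 0.5)
        assert prune_correlated(table).columns == [table.columns[0]]

    def test_matches_all_pairs_oracle(self, rng):
        X = rng.normal(size=(20, 30))
        X[:, 5] = X[:, 2] * 1.01 + rng.normal(scale=1e-3, size=20)
        X[:, 17] = -X[:, 9]
        table = make_table(X, rng.random(20) < 0.5)
        pruned = prune_correlated(table, threshold=0.95)
        # oracle: explicit greedy scan over all earlier kept columns
        corr = np.corrcoef(X, rowvar=False)
        kept = []
        for j in range(X.shape[1]):
            if all(abs(corr[j, k]) <= 0.95 for k in kept):
                kept.append(j)
        assert pruned.columns == [table.columns[k] for k in kept]

    def test_constant_column_kept_with_warning(self, rng):
        X = rng.normal(size=(15, 3))
        X[:, 1] = 7.0
        table = make_table(X, rng.random(15) < 0.5)
        with pytest.warns(UserWarning, match="constant"):
            pruned = prune_correlated(table)
        assert table.columns[1] in pruned.columns


class TestUnivariateAUC:
    def test_uninformative_feature_near_half(self, rng, fast_cv):
        y = np.repeat([0, 1], 12)
        X = np.column_stack([np.zeros(24), rng.normal(size=24)])
        table = make_table(X, y)
        auc = univariate_auc(table, table.columns[0], "tcfa", fast_cv)
        assert auc == pytest.approx(0.5, abs=0.15)

    def test_perfect_separator_hits_one(self, fast_cv):
        y = np.repeat([0, 1], 12)
        X = (y + 0.0).reshape(-1, 1)
        table = make_table(X, y)
        assert univariate_auc(table, table.columns[0], "tcfa", fast_cv) == 1.0

    def test_strong_monotone_feature_matches_mann_whitney(self, rng):
        """For a strongly monotone feature the CV logistic score ordering
        approaches the feature's own ranking, so the mean CV AUC tracks
        the direct rank AUC closely."""
        y = rng.random(30) < 0.5
        y[:3], y[-3:] = 0, 1
        x = rng.normal(size=30) + 3.0 * y
        table = make_table(x.reshape(-1, 1), y)
        cv = CVProtocol(n_repeats=100, rng_seed=1)
        auc = univariate_auc(table, table.columns[0], "tcfa", cv)
        expected = oracles.mann_whitney_auc(x.tolist(), y.astype(int).tolist())
        assert auc == pytest.approx(expected, abs=0.02)


class TestTopKPerFamily:
    def test_family_caps_and_exhaustion(self):
        names = [f"mean_glcm_c{j}_8b" for j in range(20)] + [
            f"mean_ngtdm_n{j}_8b" for j in range(7)
        ]
        auc_map = pd.Series(np.linspace(0.9, 0.5, len(names)), index=names)
        chosen = top_k_per_family(auc_map, k=15)
        glcm = [n for n in chosen if "_glcm_" in n]
        ngtdm = [n for n in chosen if "_ngtdm_" in n]
        assert len(glcm) == 15 and len(ngtdm) == 7

    def test_ties_broken_by_name(self):
        names = [f"mean_glcm_{c}_8b" for c in "dcba"]
        auc_map = pd.Series([0.7, 0.7, 0.7, 0.7], index=names)
        chosen = top_k_per_family(auc_map, k=2)
        assert sorted(chosen) == ["mean_glcm_a_8b", "mean_glcm_b_8b"]


class TestMRMR:
    def test_k_equals_candidates_returns_all(self, rng):
        X = rng.normal(size=(20, 4))
        table = make_table(X, rng.random(20) < 0.5)
        assert mrmr_select(table, table.columns, "tcfa", 4) == table.columns

    def test_duplicate_informative_feature_deferred(self, rng):
        y = np.repeat([0, 1], 10).astype(float)
        signal = y + rng.normal(scale=0.1, size=20)
        X = np.column_stack([signal, signal, rng.normal(size=20), rng.normal(size=20)])
        table = make_table(X, y.astype(bool))
        picked = mrmr_select(table, table.columns, "tcfa", 3)
        # the clone of the first pick is maximally redundant: not second
        assert picked[0] == table.columns[0]
        assert picked[1] != table.columns[1]

    def test_matches_greedy_trace_oracle(self, rng):
        from pcatomics.selection import _discretize_3level, _mutual_information

        X = rng.normal(size=(24, 6))
        y = (X[:, 0] + 0.5 * X[:, 3] + rng.normal(size=24)) > 0
        table = make_table(X, y)
        picked = mrmr_select(table, table.columns, "tcfa", 3)
        coded = [_discretize_3level(X[:, j]) for j in range(6)]
        yv = y.astype(int)
        rel = [_mutual_information(c, yv) for c in coded]
        selected, remaining = [], list(range(6))
        while len(selected) < 3:
            scores = []
            for j in remaining:
                red = np.mean([_mutual_information(coded[j], coded[s]) for s in selected]) if selected else 0.0
                scores.append(rel[j] - red)
            best = remaining[int(np.argmax(scores))]
            selected.append(best)
            remaining.remove(best)
        assert picked == [table.columns[j] for j in selected]

    def test_invalid_k_rejected(self, rng):
        table = make_table(rng.normal(size=(10, 3)), rng.random(10) < 0.5)
        with pytest.raises(ValueError):
            mrmr_select(table, table.columns, "tcfa", 0)
        with pytest.raises(ValueError):
            mrmr_select(table, table.columns, "tcfa", 4)


class TestRecursiveElimination:
    def test_informative_feature_survives(self, rng, fast_cv):
        y = np.repeat([0, 1], 12)
        X = rng.normal(size=(24, 10))
        X[:, 4] += 3.0 * y  # strong effect
        table = make_table(X, y)
        final, path = recursive_elimination(table, table.columns, "tcfa", fast_cv)
        assert table.columns[4] in final
        assert len(final) <= 10
        assert len(path) == 10  # one record per subset size

    def test_all_noise_auc_near_half(self, rng, fast_cv):
        y = np.repeat([0, 1], 12)
        X = rng.normal(size=(24, 5))
        table = make_table(X, y)
        _, path = recursive_elimination(table, table.columns, "tcfa", fast_cv)
        best = max(rec["mean_auc"] for rec in path)
        # held-out scoring bounds the optimism of 5 noise features
        assert 0.3 <= best <= 0.75


class TestCascade:
    def test_trace_deterministic(self, small_table):
        cv = CVProtocol(n_repeats=10, rng_seed=99)
        t1 = select_features(small_table, "tcfa", cv)
        t2 = select_features(small_table, "tcfa", cv)
        assert t1.final_set == t2.final_set
        assert t1.top105 == t2.top105
        assert t1.mrmr50 == t2.mrmr50
        pd.testing.assert_series_equal(t1.univariate_auc, t2.univariate_auc)

    def test_stage_cardinalities(self, small_table):
        cv = CVProtocol(n_repeats=10, rng_seed=99)
        trace = select_features(small_table, "tcfa", cv)
        assert len(trace.top105) <= 105
        assert len(trace.mrmr50) <= 50
        assert len(trace.candidate10) <= 10
        assert 1 <= len(trace.final_set) <= 10
        assert set(trace.mrmr50) <= set(trace.top105)
        assert set(trace.candidate10) <= set(trace.mrmr50)
        assert set(trace.final_set) <= set(trace.candidate10)
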