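"""Splitting, feature selection, classifier scoring and the grid search."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from timeradiomics.matrix import LabelledMatrix
from timeradiomics.model_search import (
    CLASSIFIERS,
    ModelConfig,
    SearchGrid,
    build_integrated_model,
    grid_search,
    rank_features,
    select_features,
    split_cohort,
    train_classifier,
)


def make_matrix(n=60, p=12, informative=(0,), strength=2.0, seed=0, label="cd8"):
    """Features with a planted informative subset driving the label."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = (rng.random(n) < 0.5).astype(int)
    y[: n // 2] = 0
    y[n // 2:] = 1
    for j in informative:
        X[:, j] += strength * y
    idx = [f"case{i}" for i in range(n)]
    cols = [f"f{j}" for j in range(p)]
    return LabelledMatrix(
        X=pd.DataFrame(X, index=idx, columns=cols),
        y=pd.Series(y, index=idx),
        label_kind=label,
    )


class TestSplit:
    def test_seventy_thirty_counts(self):
        y = pd.Series([0, 1] * 5, index=[f"c{i}" for i in range(10)])
        train, test = split_cohort(y, 0.7, seed=0)
        assert len(train) == 7 and len(test) == 3

    def test_deterministic_in_seed(self):
        y = pd.Series([0, 1] * 20, index=[f"c{i}" for i in range(40)])
        assert split_cohort(y, seed=3) == split_cohort(y, seed=3)
        assert split_cohort(y, seed=3) != split_cohort(y, seed=4)

    def test_stratification_bounds_prevalence(self):
        y = pd.Series([0, 1] * 20, index=[f"c{i}" for i in range(40)])
        for seed in range(100):
            train, _ = split_cohort(y, 0.7, seed)
            prev = y.loc[train].mean()
            assert 0.4 <= prev <= 0.6

    def test_tiny_class_rejected(self):
        y = pd.Series([0] * 9 + [1], index=[f"c{i}" for i in range(10)])
        with pytest.raises(ValueError):
            split_cohort(y)


class TestSelectors:
    def test_perfect_separator_ranked_first_by_all_methods(self):
        lm = make_matrix(n=40, p=8, informative=(3,), strength=6.0, seed=1)
        for method in ("ANOVA", "KW", "RFE", "Relief"):
            ranking = rank_features(method, lm.X, lm.y)
            assert ranking[0] == "f3", method

    def test_anova_equals_squared_t_ranking(self):
        lm = make_matrix(n=30, p=6, informative=(0, 2), strength=1.0, seed=2)
        f_scores = {}
        for col in lm.X.columns:
            a = lm.X.loc[lm.y == 0, col]
            b = lm.X.loc[lm.y == 1, col]
            t, _ = sps.ttest_ind(a, b)
            f_scores[col] = t**2
        expected = sorted(f_scores, key=f_scores.get, reverse=True)
        assert rank_features("ANOVA", lm.X, lm.y) == expected

    def test_relief_detects_interacting_pair(self):
        # XOR-structured pair: marginally uninformative, jointly decisive
        rng = np.random.default_rng(3)
        n = 40
        a = rng.integers(0, 2, n)
        b = rng.integers(0, 2, n)
        y = (a ^ b).astype(int)
        X = pd.DataFrame(
            {
                "xor_a": a + 0.05 * rng.normal(size=n),
                "xor_b": b + 0.05 * rng.normal(size=n),
                "noise1": rng.normal(size=n),
                "noise2": rng.normal(size=n),
            },
            index=[f"c{i}" for i in range(n)],
        )
        ranking = rank_features("Relief", X, pd.Series(y, index=X.index))
        assert set(ranking[:2]) == {"xor_a", "xor_b"}

    def test_constant_feature_never_selected_first(self):
        lm = make_matrix(n=30, p=5, informative=(1,), seed=4)
        X = lm.X.copy()
        X["const"] = 1.0
        for method in ("ANOVA", "KW", "Relief"):
            ranking = rank_features(method, X, lm.y)
            assert ranking[-1] == "const"

    def test_select_features_returns_k(self):
        lm = make_matrix(seed=5)
        assert len(select_features("ANOVA", lm.X, lm.y, 4)) == 4
        with pytest.raises(ValueError):
            select_features("ANOVA", lm.X, lm.y, 99)


class TestClassifiers:
    def test_separable_data_perfect_training_auc(self):
        from timeradiomics.stats import roc_auc

        lm = make_matrix(n=30, p=3, informative=(0,), strength=8.0, seed=6)
        for name in ("LR", "SVM"):
            scorer = train_classifier(name, lm.X, lm.y)
            assert roc_auc(scorer(lm.X), lm.y).auc == 1.0

    def test_null_labels_chance_test_auc(self):
        from timeradiomics.stats import roc_auc

        aucs = {name: [] for name in CLASSIFIERS}
        for seed in range(6):
            lm = make_matrix(n=200, p=5, informative=(), seed=seed)
            train, test = split_cohort(lm.y, 0.7, seed)
            for name in CLASSIFIERS:
                scorer = train_classifier(name, lm.X.loc[train], lm.y.loc[train])
                aucs[name].append(roc_auc(scorer(lm.X.loc[test]), lm.y.loc[test]).auc)
        for name, vals in aucs.items():
            assert abs(np.mean(vals) - 0.5) < 0.1, name

    def test_lr_monotone_in_single_feature(self):
        lm = make_matrix(n=40, p=1, informative=(0,), strength=1.0, seed=8)
        scorer = train_classifier("LR", lm.X, lm.y)
        s = scorer(lm.X)
        order_f = lm.X["f0"].sort_values().index
        assert list(s.loc[order_f].sort_values().index) == list(order_f)

    def test_scores_within_unit_interval(self):
        lm = make_matrix(seed=9)
        for name in CLASSIFIERS:
            s = train_classifier(name, lm.X, lm.y)(lm.X)
            assert (0.0 <= s).all() and (s <= 1.0).all()

    def test_unknown_name_rejected(self):
        lm = make_matrix(seed=10)
        with pytest.raises(ValueError):
            train_classifier("MLP", lm.X, lm.y)


class TestGridSearch:
    def test_single_config_grid_returns_it(self):
        lm = make_matrix(seed=11)
        grid = SearchGrid(selectors=("ANOVA",), classifiers=("LR",), n_features=(3,))
        best, leaderboard, results = grid_search(lm, grid, seed=0)
        assert best.config == ModelConfig("ANOVA", "LR", 3, 0)
        assert len(leaderboard) == 1

    def test_full_grid_leaderboard_has_360_rows(self):
        lm = make_matrix(n=40, p=12, informative=(0,), seed=12)
        best, leaderboard, _ = grid_search(lm, SearchGrid(), seed=0)
        assert len(leaderboard) == 4 * 9 * 10

    def test_planted_feature_recovered_small_model(self):
        wins = 0
        for seed in range(10):
            lm = make_matrix(n=80, p=10, informative=(2,), strength=3.0, seed=seed)
            grid = SearchGrid(selectors=("ANOVA", "KW"), classifiers=("LR", "NB"),
                              n_features=tuple(range(1, 6)))
            best, _, _ = grid_search(lm, grid, seed=seed)
            if best.config.n_features <= 3 and "f2" in best.feature_ids:
                wins += 1
        assert wins >= 8

    def test_no_leak_permuting_test_labels_keeps_models(self):
        lm = make_matrix(n=60, p=8, informative=(0,), seed=13)
        grid = SearchGrid(selectors=("ANOVA",), classifiers=("LR",), n_features=(2,))
        train, test = split_cohort(lm.y, 0.7, seed=1)
        best, _, _ = grid_search(lm, grid, seed=1, split=(train, test))
        # permute labels of the test rows only and re-run on the same split
        rng = np.random.default_rng(0)
        y2 = lm.y.copy()
        y2.loc[test] = rng.permutation(y2.loc[test].to_numpy())
        if (y2.loc[test] == lm.y.loc[test]).all():
            y2.loc[test[:2]] = 1 - y2.loc[test[:2]]
        lm2 = LabelledMatrix(X=lm.X, y=y2, label_kind=lm.label_kind)
        best2, _, _ = grid_search(lm2, grid, seed=1, split=(train, test))
        assert best2.feature_ids == best.feature_ids
        pd.testing.assert_series_equal(best2.test_scores, best.test_scores)

    def test_pure_function_of_inputs(self):
        lm = make_matrix(seed=14)
        grid = SearchGrid(selectors=("ANOVA",), classifiers=("LR", "DT"),
                          n_features=(1, 2))
        a = grid_search(lm, grid, seed=2)[1]
        b = grid_search(lm, grid, seed=2)[1]
        pd.testing.assert_frame_equal(a, b)


class TestIntegratedModel:
    def _cohorts(self, seed=0, strength=3.0):
        lm_time = make_matrix(n=80, p=10, informative=(1,), strength=strength,
                              seed=seed)
        rng = np.random.default_rng(seed + 100)
        n_ici = 50
        X_ici = pd.DataFrame(
            rng.normal(size=(n_ici, 10)),
            index=[f"ici{i}" for i in range(n_ici)],
            columns=lm_time.X.columns,
        )
        latent = rng.normal(size=n_ici)
        X_ici["f1"] += strength * (latent > 0)
        response = pd.Series(
            ((latent + 0.5 * rng.normal(size=n_ici)) > 0).astype(int),
            index=X_ici.index,
        )
        return lm_time, X_ici, response

    def _results(self, lm):
        grid = SearchGrid(selectors=("ANOVA",), classifiers=("LR",),
                          n_features=(2,))
        best, _, _ = grid_search(lm, grid, seed=0)
        return best

    def test_strong_shared_coupling_gives_high_auc(self):
        aucs = []
        for seed in range(5):
            lm, X_ici, response = self._cohorts(seed=seed)
            best = self._results(lm)
            integ = build_integrated_model(lm, best, best, X_ici,
                                           ici_response=response)
            aucs.append(integ.response_roc.auc)
        assert np.mean(aucs) >= 0.75

    def test_null_coupling_chance_auc(self):
        aucs = []
        for seed in range(5):
            lm, X_ici, response = self._cohorts(seed=seed, strength=0.0)
            rng = np.random.default_rng(seed)
            response = pd.Series(rng.integers(0, 2, len(X_ici)), index=X_ici.index)
            if response.nunique() < 2:
                response.iloc[:2] = [0, 1]
            best = self._results(lm)
            integ = build_integrated_model(lm, best, best, X_ici,
                                           ici_response=response)
            aucs.append(integ.response_roc.auc)
        assert abs(np.mean(aucs) - 0.5) < 0.15

    def test_groups_nonempty_when_scores_straddle_threshold(self):
        lm, X_ici, response = self._cohorts(seed=3)
        best = self._results(lm)
        integ = build_integrated_model(lm, best, best, X_ici, ici_response=response)
        if integ.scores.min() < integ.threshold < integ.scores.max():
            assert (integ.groups == 0).any() and (integ.groups == 1).any()

    def test_missing_feature_columns_listed(self):
        lm, X_ici, response = self._cohorts(seed=4)
        best = self._results(lm)
        with pytest.raises(ValueError, match="lacks columns"):
            build_integrated_model(lm, best, best, X_ici.drop(columns=["f1"]))
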