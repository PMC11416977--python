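"""Selector x classifier model exploration over a labelled feature matrix.

The search mirrors the automated model-exploration workflow common in CT
radiomics: a stratified 70/30 split, training-only Z-score normalization
and Pearson deduplication, four feature selectors (ANOVA, Kruskal-Wallis,
RFE, Relief) crossed with nine classifiers and 1..10 retained features,
ranked by AUC on the held-out test set.  The integrated model refits the
winning surgical-cohort (TIME) classifier on the union of the TIME and
response retained features and transfers it to the immunotherapy cohort,
dichotomizing the predicted infiltration at the Youden-optimal threshold
fitted on the surgical cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.feature_selection import RFE
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .matrix import LabelledMatrix, ZScoreScaler, pcc_dedup
from .stats import RocResult, optimal_cutoff, roc_auc

__all__ = [
    "SELECTORS",
    "CLASSIFIERS",
    "ModelConfig",
    "ModelResult",
    "SearchGrid",
    "split_cohort",
    "rank_features",
    "select_features",
    "train_classifier",
    "grid_search",
    "IntegratedResult",
    "build_integrated_model",
]

SELECTORS = ("ANOVA", "KW", "RFE", "Relief")
CLASSIFIERS = ("SVM", "LDA", "RF", "LR", "LRLasso", "AdaBoost", "DT", "GP", "NB")


@dataclass(frozen=True)
class ModelConfig:
    """One point of the exploration grid."""

    selector: str
    classifier: str
    n_features: int
    split_seed: int = 0

    def __post_init__(self) -> None:
        if self.selector not in SELECTORS:
            raise ValueError(f"unknown selector {self.selector!r}")
        if self.classifier not in CLASSIFIERS:
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")


@dataclass(frozen=True)
class SearchGrid:
    """The selector/classifier/feature-count grid to explore."""

    selectors: tuple[str, ...] = SELECTORS
    classifiers: tuple[str, ...] = CLASSIFIERS
    n_features: tuple[int, ...] = tuple(range(1, 11))

    def configs(self, seed: int) -> list[ModelConfig]:
        return [
            ModelConfig(s, c, k, seed)
            for s in self.selectors
            for c in self.classifiers
            for k in self.n_features
        ]


@dataclass(frozen=True)
class ModelResult:
    """Fit and evaluation of one grid configuration."""

    config: ModelConfig
    feature_ids: tuple[str, ...]
    train_auc: float
    train_ci: tuple[float, float]
    test_auc: float
    test_ci: tuple[float, float]
    test_scores: pd.Series = field(repr=False)
    threshold: float = 0.5


def split_cohort(y: pd.Series, fraction: float = 0.7, seed: int = 0):
    """Stratified train/test split of case ids, deterministic in seed."""
    counts = y.value_counts()
    if (counts < 2).any():
        raise ValueError("every class needs >= 2 cases to stratify the split")
    train_idx, test_idx = train_test_split(
        y.index.to_numpy(),
        train_size=fraction,
        stratify=y.to_numpy(),
        random_state=seed,
    )
    return list(train_idx), list(test_idx)


def _relief_scores(X: np.ndarray, y: np.ndarray, k: int = 3) -> np.ndarray:
    """Relief-F margin scores with k nearest hits/misses, all cases as anchors."""
    n, p = X.shape
    scores = np.zeros(p)
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    for i in range(n):
        hits = np.where(y == y[i])[0]
        misses = np.where(y != y[i])[0]
        hits = hits[hits != i]
        if len(hits) == 0 or len(misses) == 0:
            continue
        nh = hits[np.argsort(d2[i, hits])[:k]]
        nm = misses[np.argsort(d2[i, misses])[:k]]
        scores += np.abs(X[i] - X[nm]).mean(axis=0) - np.abs(X[i] - X[nh]).mean(axis=0)
    return scores / n


def rank_features(method: str, X: pd.DataFrame, y: pd.Series,
                  seed: int = 0) -> list[str]:
    """Full feature ranking (best first) by one selection method.

    ANOVA ranks by the F statistic, KW by the Kruskal-Wallis H statistic,
    RFE by the elimination order of an L2 logistic model refit with the
    smallest-|weight| feature dropped each round, Relief by the
    near-hit/near-miss margin.  Constant features score 0 (or F = 0) and
    are never ranked above non-constant ones.
    """
    Xa = X.to_numpy(dtype=np.float64)
    ya = y.to_numpy(dtype=np.int64)
    cols = np.array(X.columns)
    constant = Xa.std(axis=0) == 0
    if method == "ANOVA":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from sklearn.feature_selection import f_classif

            f, _ = f_classif(Xa, ya)
        scores = np.where(np.isfinite(f), f, 0.0)
    elif method == "KW":
        scores = np.zeros(Xa.shape[1])
        for j in range(Xa.shape[1]):
            if constant[j]:
                continue
            try:
                h, _ = sps.kruskal(Xa[ya == 0, j], Xa[ya == 1, j])
            except ValueError:  # identical values in both groups
                h = 0.0
            scores[j] = h
    elif method == "RFE":
        rfe = RFE(
            LogisticRegression(max_iter=2000),
            n_features_to_select=1,
            step=1,
        ).fit(Xa, ya)
        scores = -rfe.ranking_.astype(float)  # rank 1 = kept longest
    elif method == "Relief":
        scores = _relief_scores(Xa, ya)
    else:
        raise ValueError(f"unknown selector {method!r}")
    scores = np.where(constant, -np.inf, scores)
    # stable sort: ties keep manifest order
    order = np.argsort(-scores, kind="stable")
    return list(cols[order])


def select_features(method: str, X: pd.DataFrame, y: pd.Series, k: int,
                    seed: int = 0) -> list[str]:
    """Top-k features of :func:`rank_features`."""
    if k > X.shape[1]:
        raise ValueError(f"k={k} exceeds the {X.shape[1]} available features")
    return rank_features(method, X, y, seed)[:k]


def _make_classifier(name: str, seed: int):
    if name == "SVM":
        return SVC(kernel="linear", random_state=seed)
    if name == "LDA":
        return LinearDiscriminantAnalysis()
    if name == "RF":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if name == "LR":
        return LogisticRegression(max_iter=2000)
    if name == "LRLasso":
        return LogisticRegression(penalty="l1", solver="liblinear",
                                  max_iter=2000, random_state=seed)
    if name == "AdaBoost":
        return AdaBoostClassifier(random_state=seed)
    if name == "DT":
        return DecisionTreeClassifier(random_state=seed)
    if name == "GP":
        return GaussianProcessClassifier(random_state=seed)
    if name == "NB":
        return GaussianNB()
    raise ValueError(f"unknown classifier {name!r}")


def train_classifier(name: str, X: pd.DataFrame, y: pd.Series, seed: int = 0):
    """Fit a named classifier; returns a callable giving scores in [0, 1].

    Probabilistic models score with the positive-class probability;
    margin-based models (SVM) squash the decision value through a
    logistic link, preserving the ranking.
    """
    if min(np.bincount(y.to_numpy())) < 2:
        raise ValueError("need >= 2 cases per class to train")
    clf = _make_classifier(name, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(X.to_numpy(dtype=np.float64), y.to_numpy())

    cols = list(X.columns)

    def score(Xnew: pd.DataFrame) -> pd.Series:
        arr = Xnew[cols].to_numpy(dtype=np.float64)
        if hasattr(clf, "predict_proba"):
            s = clf.predict_proba(arr)[:, 1]
        else:
            s = 1.0 / (1.0 + np.exp(-clf.decision_function(arr)))
        return pd.Series(s, index=Xnew.index)

    score.model = clf
    return score


def grid_search(
    matrix: LabelledMatrix,
    grid: SearchGrid | None = None,
    seed: int = 0,
    fraction: float = 0.7,
    pcc_threshold: float = 0.99,
    split: tuple[list, list] | None = None,
) -> tuple[ModelResult, pd.DataFrame, list[ModelResult]]:
    """Evaluate every grid configuration on one stratified split.

    All configurations share the same split, normalization and
    deduplication (all fitted on training rows only).  A precomputed
    ``split`` (train ids, test ids) may be supplied.  Returns the winner
    (highest test AUC; ties broken by fewer features, then canonical
    selector/classifier order), the leaderboard and all results.
    """
    grid = grid or SearchGrid()
    train_ids, test_ids = split if split is not None else split_cohort(
        matrix.y, fraction, seed
    )
    scaler = ZScoreScaler().fit(matrix.X.loc[train_ids])
    Xn = scaler.transform(matrix.X)
    kept = pcc_dedup(Xn.loc[train_ids], pcc_threshold)
    Xn = Xn[kept]
    Xtr, ytr = Xn.loc[train_ids], matrix.y.loc[train_ids]
    Xte, yte = Xn.loc[test_ids], matrix.y.loc[test_ids]

    rankings = {s: rank_features(s, Xtr, ytr, seed) for s in grid.selectors}

    results: list[ModelResult] = []
    for cfg in grid.configs(seed):
        feats = rankings[cfg.selector][: cfg.n_features]
        scorer = train_classifier(cfg.classifier, Xtr[feats], ytr, seed)
        tr_scores = scorer(Xtr[feats])
        te_scores = scorer(Xte[feats])
        roc_tr = roc_auc(tr_scores, ytr)
        roc_te = roc_auc(te_scores, yte)
        results.append(
            ModelResult(
                config=cfg,
                feature_ids=tuple(feats),
                train_auc=roc_tr.auc,
                train_ci=roc_tr.ci,
                test_auc=roc_te.auc,
                test_ci=roc_te.ci,
                test_scores=te_scores,
                threshold=optimal_cutoff(roc_tr),
            )
        )

    def sort_key(r: ModelResult):
        return (
            -r.test_auc,
            r.config.n_features,
            SELECTORS.index(r.config.selector),
            CLASSIFIERS.index(r.config.classifier),
        )

    ranked = sorted(results, key=sort_key)
    leaderboard = pd.DataFrame(
        {
            "selector": [r.config.selector for r in ranked],
            "classifier": [r.config.classifier for r in ranked],
            "n_features": [r.config.n_features for r in ranked],
            "train_auc": [r.train_auc for r in ranked],
            "test_auc": [r.test_auc for r in ranked],
        }
    )
    return ranked[0], leaderboard, results


@dataclass(frozen=True)
class IntegratedResult:
    """Cross-cohort transfer of a TIME model to the immunotherapy cohort."""

    feature_ids: tuple[str, ...]
    classifier: str
    threshold: float
    scores: pd.Series = field(repr=False)
    groups: pd.Series = field(repr=False)
    response_roc: RocResult | None = None


def build_integrated_model(
    time_matrix: LabelledMatrix,
    time_result: ModelResult,
    response_result: ModelResult,
    ici_features: pd.DataFrame,
    ici_response: pd.Series | None = None,
    combination: str = "union",
    seed: int = 0,
) -> IntegratedResult:
    """Predict infiltration for the immunotherapy cohort.

    The TIME-winning classifier is refit on the full surgical cohort using
    the combination (default union, in manifest order) of the TIME and
    response retained features; immunotherapy cases are normalized with
    surgical-cohort parameters, scored, and dichotomized at the
    Youden-optimal threshold of the surgical-cohort scores.
    """
    if combination == "union":
        feats = [f for f in time_matrix.X.columns
                 if f in set(time_result.feature_ids) | set(response_result.feature_ids)]
    elif combination == "intersection":
        feats = [f for f in time_result.feature_ids
                 if f in set(response_result.feature_ids)]
    elif combination == "time_only":
        feats = list(time_result.feature_ids)
    else:
        raise ValueError(f"unknown combination rule {combination!r}")
    missing = [f for f in feats if f not in ici_features.columns]
    if missing:
        raise ValueError(f"immunotherapy feature table lacks columns: {missing}")

    scaler = ZScoreScaler().fit(time_matrix.X[feats])
    Xtr = scaler.transform(time_matrix.X[feats])
    feats = list(Xtr.columns)  # constant features dropped by the scaler
    scorer = train_classifier(time_result.config.classifier, Xtr,
                              time_matrix.y, seed)
    train_scores = scorer(Xtr)
    threshold = optimal_cutoff(roc_auc(train_scores, time_matrix.y))

    Xici = scaler.transform(ici_features)
    scores = scorer(Xici)
    groups = (scores > threshold).astype(np.int64)
    resp_roc = None
    if ici_response is not None:
        resp_roc = roc_auc(scores, ici_response.loc[scores.index])
    return IntegratedResult(
        feature_ids=tuple(feats),
        classifier=time_result.config.classifier,
        threshold=float(threshold),
        scores=scores,
        groups=groups,
        response_roc=resp_roc,
    )
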