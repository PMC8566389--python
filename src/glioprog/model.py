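"""Random Forest classification with threefold cross-validation.

One forest is trained per fold of a seeded, label-stratified k-fold split;
held-out cases receive the forest's class-vote fraction as their PD
probability, and impurity-based (Gini) feature importances are collected
per fold and averaged. Forest hyperparameters are pinned to the common
defaults (100 trees, Gini impurity, sqrt(p) features per split, unlimited
depth) so results are reproducible across library versions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .features import FEATURE_COLUMNS

POSITIVE_LABEL = "PD"

logger = logging.getLogger(__name__)

__all__ = ["CVResult", "cross_validated_predict", "feature_importances",
           "ProgressionForest", "POSITIVE_LABEL"]


def _make_forest(seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=100, criterion="gini", max_features="sqrt",
        max_depth=None, random_state=seed,
    )


@dataclass
class CVResult:
    """Pooled out-of-fold predictions plus per-fold importances."""

    table: pd.DataFrame                 # case_id, label, fold, prob_pd
    fold_importances: np.ndarray        # (k, p), each row sums to 1
    feature_names: tuple[str, ...]
    n_excluded: int = 0

    @property
    def probs(self) -> np.ndarray:
        return self.table["prob_pd"].to_numpy()

    @property
    def labels(self) -> np.ndarray:
        return self.table["label"].to_numpy()


def cross_validated_predict(features: pd.DataFrame, k: int = 3,
                            seed: int = 0,
                            feature_columns: tuple[str, ...] = FEATURE_COLUMNS,
                            ) -> CVResult:
    """Stratified k-fold out-of-fold PD probabilities.

    Rows with missing feature values (flagged empty-ROI cases) are excluded
    with a logged count. Deterministic for a fixed (table, k, seed).
    """
    feature_columns = tuple(feature_columns)
    missing = [c for c in feature_columns if c not in features.columns]
    if missing:
        raise ValueError(f"feature table lacks columns: {missing}")
    complete = features.dropna(subset=list(feature_columns)).reset_index(drop=True)
    n_excluded = len(features) - len(complete)
    if n_excluded:
        logger.warning("excluding %d case(s) with missing features "
                       "(empty progressive ROI)", n_excluded)

    y = complete["label"].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("both classes must be present")
    if counts.min() < k:
        raise ValueError(
            f"need at least k={k} cases per class, got {dict(zip(classes, counts))}")
    X = complete[list(feature_columns)].to_numpy(dtype=float)

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    prob = np.full(len(complete), np.nan)
    fold_of = np.full(len(complete), -1, dtype=int)
    importances = np.zeros((k, X.shape[1]))
    for fold, (train, test) in enumerate(skf.split(X, y)):
        if np.unique(y[train]).size < 2:
            raise ValueError(f"a class is absent from training fold {fold}")
        forest = _make_forest(seed)
        forest.fit(X[train], y[train])
        pd_col = list(forest.classes_).index(POSITIVE_LABEL)
        prob[test] = forest.predict_proba(X[test])[:, pd_col]
        fold_of[test] = fold
        importances[fold] = forest.feature_importances_

    table = pd.DataFrame({
        "case_id": complete["case_id"] if "case_id" in complete else
        [f"case_{i}" for i in range(len(complete))],
        "label": y,
        "fold": fold_of,
        "prob_pd": prob,
    })
    return CVResult(table=table, fold_importances=importances,
                    feature_names=feature_columns, n_excluded=n_excluded)


def feature_importances(cv: CVResult) -> pd.Series:
    """Fold-mean impurity importances, renormalized to sum to 1, sorted
    descending with stable names."""
    mean_imp = cv.fold_importances.mean(axis=0)
    total = mean_imp.sum()
    if total > 0:
        mean_imp = mean_imp / total
    s = pd.Series(mean_imp, index=list(cv.feature_names), name="importance")
    return s.sort_values(ascending=False, kind="stable")


class ProgressionForest(ClassifierMixin, BaseEstimator):
    """sklearn-compatible Random Forest for PD-vs-TRC classification.

    A thin estimator over :class:`RandomForestClassifier` with the pinned
    pipeline defaults, adding :meth:`cross_val_predict` for the out-of-fold
    protocol used throughout the package.
    """

    def __init__(self, n_estimators: int = 100, k: int = 3, random_state: int = 0):
        self.n_estimators = n_estimators
        self.k = k
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_estimators, criterion="gini",
            max_features="sqrt", random_state=self.random_state)
        self.forest_.fit(X, y)
        self.classes_ = self.forest_.classes_
        self.feature_importances_ = self.forest_.feature_importances_
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "forest_")
        return self.forest_.predict(np.asarray(X, dtype=float))

    def predict_proba(self, X):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "forest_")
        return self.forest_.predict_proba(np.asarray(X, dtype=float))

    def cross_val_predict(self, features: pd.DataFrame,
                          feature_columns=FEATURE_COLUMNS) -> CVResult:
        return cross_validated_predict(features, k=self.k,
                                       seed=self.random_state,
                                       feature_columns=feature_columns)
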