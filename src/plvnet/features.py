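"""Feature selection and group classification.

A :class:`FeatureTable` holds one row per sample (a subject-segment)
and one labelled column per feature (band-or-network | metric | node,
or spectral power/ratio features). Selection methods — univariate
filter, two-sample KS, chi-square, tree importance, l2-penalised linear
coefficients, PCA — are fit on training folds only. Classifiers cover
random forest, RBF-SVM, KNN and Gaussian naive Bayes baselines plus two
tree ensembles: three tree models (random forest and two gradient-
boosted variants) combined by soft probability voting (ELTS) or hard
majority voting (ELTH). Evaluation is stratified 10-fold
cross-validation without repeated sampling, selection refit per fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.ensemble import (GradientBoostingClassifier,
                              RandomForestClassifier, VotingClassifier)
from sklearn.feature_selection import chi2 as sk_chi2
from sklearn.feature_selection import f_classif
from sklearn.linear_model import Ridge
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

SELECTOR_KINDS = ("filter", "ks", "chi2", "tree", "l2", "pca")
CLASSIFIER_KINDS = ("rf", "svm", "knn", "bn", "lgbm", "gbst", "elth", "elts")

#: Default hyperparameters; all overridable via ``make_classifier``.
DEFAULT_PARAMS: dict[str, dict] = {
    "rf": {"n_estimators": 500},
    "lgbm": {"n_estimators": 200, "learning_rate": 0.1, "max_depth": 3},
    "gbst": {"n_estimators": 200, "learning_rate": 0.1, "max_depth": 3},
    "svm": {"kernel": "rbf", "C": 1.0},
    "knn": {"n_neighbors": 5},
    "bn": {},
}


@dataclass
class FeatureTable:
    """Samples x features matrix with group labels and sample provenance."""

    values: pd.DataFrame
    groups: pd.Series
    subjects: pd.Series
    segments: pd.Series

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("feature table contains missing values")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()]
            raise ValueError(f"duplicate feature labels: {list(dupes)}")
        if self.groups.nunique() != 2:
            raise ValueError("exactly 2 group labels required")
        for s in (self.groups, self.subjects, self.segments):
            if len(s) != len(self.values):
                raise ValueError("sample metadata length mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.values)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def class_vector(self) -> np.ndarray:
        """Group labels encoded 0/1 in sorted label order."""
        classes = sorted(self.groups.unique())
        return self.groups.map({c: i for i, c in enumerate(classes)}).to_numpy()

    def subset(self, mask: np.ndarray) -> "FeatureTable":
        return FeatureTable(
            values=self.values.iloc[mask].reset_index(drop=True),
            groups=self.groups.iloc[mask].reset_index(drop=True),
            subjects=self.subjects.iloc[mask].reset_index(drop=True),
            segments=self.segments.iloc[mask].reset_index(drop=True),
        )


@dataclass
class CVResult:
    """Per-fold accuracies and selected features of one CV run."""

    classifier: str
    selector: str
    seed: int
    fold_accuracies: list[float]
    selected_features: list[list[str]]
    mean_accuracy: float = dc_field(init=False)

    def __post_init__(self) -> None:
        self.mean_accuracy = float(np.mean(self.fold_accuracies))


# ---------------------------------------------------------------------------
# Feature selection
# ---------------------------------------------------------------------------

class FeatureSelector:
    """Train-fold-fitted feature selector / transformer.

    ``method='pca'`` transforms to principal components; all others pick
    a subset of the original columns.
    """

    def __init__(self, method: str = "filter", k: int = 20,
                 ks_alpha: float = 0.001, seed: int = 0):
        if method not in SELECTOR_KINDS:
            raise ValueError(
                f"unknown selector {method!r}; valid: {SELECTOR_KINDS}"
            )
        if k < 1:
            raise ValueError("k must be >= 1")
        self.method = method
        self.k = k
        self.ks_alpha = ks_alpha
        self.seed = seed
        self.selected_: list[str] | None = None

    def fit(self, X: pd.DataFrame, y: np.ndarray) -> "FeatureSelector":
        k = min(self.k, X.shape[1])
        cols = np.asarray(X.columns)
        Xv = X.to_numpy(dtype=np.float64)
        m = self.method
        if m == "filter":
            # constant features (e.g. empty networks in a band) score -inf
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                scores, _ = f_classif(Xv, y)
            scores = np.nan_to_num(scores, nan=-np.inf)
            self.selected_ = list(cols[np.argsort(-scores)[:k]])
        elif m == "ks":
            a, b = Xv[y == 0], Xv[y == 1]
            pvals = np.array([
                stats.ks_2samp(a[:, j], b[:, j]).pvalue
                for j in range(Xv.shape[1])
            ])
            keep = pvals < self.ks_alpha
            if not keep.any():
                # degenerate fold: keep the single most separable feature
                keep = pvals == pvals.min()
            self.selected_ = list(cols[keep])
        elif m == "chi2":
            if (Xv < 0).any():
                raise ValueError(
                    "chi-square selection requires non-negative features; "
                    "shift or rescale them first"
                )
            scores, _ = sk_chi2(Xv, y)
            scores = np.nan_to_num(scores, nan=-np.inf)
            self.selected_ = list(cols[np.argsort(-scores)[:k]])
        elif m == "tree":
            forest = RandomForestClassifier(
                n_estimators=200, random_state=self.seed, n_jobs=1
            ).fit(Xv, y)
            imp = forest.feature_importances_
            self.selected_ = list(cols[np.argsort(-imp)[:k]])
        elif m == "l2":
            self._scaler = StandardScaler().fit(Xv)
            ridge = Ridge(alpha=1.0).fit(self._scaler.transform(Xv), y)
            self.selected_ = list(cols[np.argsort(-np.abs(ridge.coef_))[:k]])
        elif m == "pca":
            self._scaler = StandardScaler().fit(Xv)
            self._pca = PCA(n_components=min(k, Xv.shape[0], Xv.shape[1]),
                            random_state=self.seed)
            self._pca.fit(self._scaler.transform(Xv))
            self.selected_ = [f"PC{i + 1}" for i in
                              range(self._pca.n_components_)]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if self.selected_ is None:
            raise RuntimeError("selector not fitted")
        if self.method == "pca":
            z = self._pca.transform(self._scaler.transform(
                X.to_numpy(dtype=np.float64)))
            return pd.DataFrame(z, columns=self.selected_, index=X.index)
        return X[self.selected_]


def select_features(table: FeatureTable, method: str, k: int,
                    seed: int = 0, ks_alpha: float = 0.001) -> FeatureTable:
    """Fit a selector on the whole table and return the reduced table."""
    sel = FeatureSelector(method, k, ks_alpha=ks_alpha, seed=seed)
    sel.fit(table.values, table.class_vector())
    reduced = sel.transform(table.values)
    return FeatureTable(values=reduced.reset_index(drop=True),
                        groups=table.groups.reset_index(drop=True),
                        subjects=table.subjects.reset_index(drop=True),
                        segments=table.segments.reset_index(drop=True))


# ---------------------------------------------------------------------------
# Classifiers
# ---------------------------------------------------------------------------

def _tree_members(seed: int, params: dict[str, dict]):
    from lightgbm import LGBMClassifier

    rf = RandomForestClassifier(random_state=seed, n_jobs=1,
                                **params.get("rf", DEFAULT_PARAMS["rf"]))
    lgbm = LGBMClassifier(random_state=seed, n_jobs=1, verbose=-1,
                          **params.get("lgbm", DEFAULT_PARAMS["lgbm"]))
    gbst = GradientBoostingClassifier(random_state=seed,
                                      **params.get("gbst",
                                                   DEFAULT_PARAMS["gbst"]))
    return [("rf", rf), ("lgbm", lgbm), ("gbst", gbst)]


def make_classifier(kind: str, seed: int = 0,
                    params: dict[str, dict] | None = None):
    """Build a seeded classifier; ``elts``/``elth`` are soft/hard votes
    of random forest + two gradient-boosted tree models."""
    params = {**DEFAULT_PARAMS, **(params or {})}
    if kind == "rf":
        return RandomForestClassifier(random_state=seed, n_jobs=1,
                                      **params["rf"])
    if kind == "svm":
        return Pipeline([("scale", StandardScaler()),
                         ("svc", SVC(random_state=seed, **params["svm"]))])
    if kind == "knn":
        return KNeighborsClassifier(**params["knn"])
    if kind == "bn":
        return GaussianNB(**params["bn"])
    if kind == "lgbm":
        from lightgbm import LGBMClassifier
        return LGBMClassifier(random_state=seed, n_jobs=1, verbose=-1,
                              **params["lgbm"])
    if kind == "gbst":
        return GradientBoostingClassifier(random_state=seed, **params["gbst"])
    if kind == "elts":
        return VotingClassifier(_tree_members(seed, params), voting="soft")
    if kind == "elth":
        return VotingClassifier(_tree_members(seed, params), voting="hard")
    raise ValueError(f"unknown classifier {kind!r}; valid: {CLASSIFIER_KINDS}")


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def cross_validate(table: FeatureTable, kind: str = "elts",
                   selector: str = "filter", k: int = 20,
                   k_folds: int = 10, seed: int = 0,
                   params: dict[str, dict] | None = None,
                   group_by_subject: bool = False) -> CVResult:
    """Stratified k-fold accuracy with per-fold feature selection.

    ``group_by_subject=True`` keeps all segments of a subject in the
    same fold, preventing subject-identity leakage; the default treats
    each subject-segment as an independent sample.
    """
    y = table.class_vector()
    counts = np.bincount(y)
    if (counts < k_folds).any() and not group_by_subject:
        raise ValueError(
            f"need at least {k_folds} samples per class for {k_folds}-fold CV"
        )
    if group_by_subject:
        from sklearn.model_selection import StratifiedGroupKFold
        splitter = StratifiedGroupKFold(n_splits=k_folds, shuffle=True,
                                        random_state=seed)
        splits = splitter.split(table.values, y, groups=table.subjects)
    else:
        splitter = StratifiedKFold(n_splits=k_folds, shuffle=True,
                                   random_state=seed)
        splits = splitter.split(table.values, y)

    accs, selected = [], []
    for train_idx, test_idx in splits:
        if len(np.unique(y[train_idx])) < 2:
            raise ValueError("a class is absent from a training fold")
        sel = FeatureSelector(selector, k, seed=seed)
        sel.fit(table.values.iloc[train_idx], y[train_idx])
        clf = make_classifier(kind, seed=seed, params=params)
        clf.fit(sel.transform(table.values.iloc[train_idx]), y[train_idx])
        pred = clf.predict(sel.transform(table.values.iloc[test_idx]))
        accs.append(float((pred == y[test_idx]).mean()))
        selected.append(list(sel.selected_))
    return CVResult(classifier=kind, selector=selector, seed=seed,
                    fold_accuracies=accs, selected_features=selected)


def run_comparison(tables: dict[str, FeatureTable],
                   kinds: tuple[str, ...] = ("elts",),
                   selector: str = "filter", k: int = 20,
                   k_folds: int = 10, seeds: tuple[int, ...] = (0,),
                   params: dict[str, dict] | None = None) -> pd.DataFrame:
    """CV accuracy for every (feature condition, classifier, seed)
    combination, as a tidy results table."""
    rows = []
    for condition, table in tables.items():
        for kind in kinds:
            for seed in seeds:
                res = cross_validate(table, kind=kind, selector=selector,
                                     k=k, k_folds=k_folds, seed=seed,
                                     params=params)
                rows.append({
                    "condition": condition,
                    "classifier": kind,
                    "seed": seed,
                    "mean_accuracy": res.mean_accuracy,
                    "fold_accuracies": res.fold_accuracies,
                })
    return pd.DataFrame(rows)
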