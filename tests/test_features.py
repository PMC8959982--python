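"""Feature selection and classification machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from plvnet import FeatureTable, cross_validate, make_classifier, select_features
from plvnet.features import FeatureSelector

FAST_PARAMS = {"rf": {"n_estimators": 50},
               "lgbm": {"n_estimators": 30, "learning_rate": 0.1,
                        "max_depth": 3},
               "gbst": {"n_estimators": 30, "learning_rate": 0.1,
                        "max_depth": 3}}


def make_table(rng, n_per_class=40, n_noise=31, effect=3.0, shift=0.0):
    """One informative feature (class means 0 vs `effect`) + pure noise."""
    n = 2 * n_per_class
    X = rng.standard_normal((n, n_noise + 1)) + shift
    y = np.repeat(["A", "B"], n_per_class)
    X[n_per_class:, 0] += effect
    cols = ["planted"] + [f"noise{i}" for i in range(n_noise)]
    return FeatureTable(
        values=pd.DataFrame(X, columns=cols),
        groups=pd.Series(y),
        subjects=pd.Series([f"s{i}" for i in range(n)]),
        segments=pd.Series(np.zeros(n, dtype=int)),
    )


def test_filter_recovers_planted_feature():
    rng = np.random.default_rng(0)
    hits = sum(
        "planted" in select_features(make_table(rng), "filter", 5).feature_names
        for _ in range(100))
    assert hits >= 95


@pytest.mark.parametrize("method", ["ks", "chi2", "tree", "l2"])
def test_other_selectors_recover_strong_feature(method):
    rng = np.random.default_rng(1)
    shift = 10.0 if method == "chi2" else 0.0  # chi2 needs non-negative
    table = make_table(rng, effect=3.0, shift=shift)
    reduced = select_features(table, method, 5)
    assert "planted" in reduced.feature_names


def test_ks_null_selection_rate():
    """At p < 0.001 on identically distributed features the selection
    rate stays near the nominal level."""
    rng = np.random.default_rng(2)
    n_feat, n = 4000, 100
    X = rng.standard_normal((n, n_feat))
    y = np.repeat([0, 1], n // 2)
    a, b = X[y == 0], X[y == 1]
    hits = sum(
        stats.ks_2samp(a[:, j], b[:, j], method="asymp").pvalue < 0.001
        for j in range(n_feat))
    # conservative discrete test: observed rate <= nominal + 3 MC sigmas
    assert hits / n_feat <= 0.001 + 3 * np.sqrt(0.001 / n_feat)


def test_chi2_rejects_negative_features():
    rng = np.random.default_rng(3)
    with pytest.raises(ValueError, match="non-negative"):
        select_features(make_table(rng), "chi2", 5)


def test_pca_rank2_perfect_reconstruction():
    rng = np.random.default_rng(4)
    base = rng.standard_normal((40, 2)) @ rng.standard_normal((2, 10))
    y = np.repeat([0, 1], 20)
    sel = FeatureSelector("pca", k=2).fit(
        pd.DataFrame(base, columns=[f"f{i}" for i in range(10)]), y)
    z = sel._pca.transform(sel._scaler.transform(base))
    recon = sel._scaler.inverse_transform(sel._pca.inverse_transform(z))
    assert np.allclose(recon, base, atol=1e-8)


def test_selector_validation():
    with pytest.raises(ValueError, match="unknown selector"):
        FeatureSelector("magic")
    with pytest.raises(ValueError, match="k must be"):
        FeatureSelector("filter", k=0)


def test_unknown_classifier_rejected():
    with pytest.raises(ValueError, match="elts"):
        make_classifier("zzz")


def test_soft_vote_probability_is_member_mean():
    rng = np.random.default_rng(5)
    table = make_table(rng, n_per_class=30, effect=1.0)
    X, y = table.values, table.class_vector()
    elts = make_classifier("elts", seed=0, params=FAST_PARAMS).fit(X, y)
    probs = [make_classifier(k, seed=0, params=FAST_PARAMS)
             .fit(X, y).predict_proba(X)
             for k in ("rf", "lgbm", "gbst")]
    assert np.allclose(elts.predict_proba(X), np.mean(probs, axis=0))


def test_classifiers_are_deterministic():
    rng = np.random.default_rng(6)
    table = make_table(rng, n_per_class=25, effect=1.0, shift=5.0)
    X, y = table.values, table.class_vector()
    for kind in ("rf", "svm", "knn", "bn", "lgbm", "gbst", "elts", "elth"):
        p1 = make_classifier(kind, seed=3, params=FAST_PARAMS).fit(X, y).predict(X)
        p2 = make_classifier(kind, seed=3, params=FAST_PARAMS).fit(X, y).predict(X)
        assert np.array_equal(p1, p2), kind


def test_cv_folds_partition_samples():
    rng = np.random.default_rng(7)
    table = make_table(rng)
    from sklearn.model_selection import StratifiedKFold
    y = table.class_vector()
    seen = []
    for _, test_idx in StratifiedKFold(10, shuffle=True,
                                       random_state=0).split(table.values, y):
        seen.extend(test_idx)
    assert sorted(seen) == list(range(table.n_samples))


def test_cv_perfectly_separable_is_perfect():
    rng = np.random.default_rng(8)
    table = make_table(rng, effect=50.0)
    res = cross_validate(table, kind="rf", selector="filter", k=5,
                         seed=0, params=FAST_PARAMS)
    assert res.mean_accuracy == 1.0
    assert len(res.fold_accuracies) == 10
    assert np.isclose(res.mean_accuracy, np.mean(res.fold_accuracies))


def test_cv_permuted_labels_at_chance():
    rng = np.random.default_rng(9)
    accs = []
    for rep in range(10):
        table = make_table(rng, effect=0.0)
        res = cross_validate(table, kind="rf", selector="filter", k=5,
                             seed=rep, params=FAST_PARAMS)
        accs.append(res.mean_accuracy)
    ci = 1.96 * np.std(accs, ddof=1) / np.sqrt(len(accs))
    assert abs(np.mean(accs) - 0.5) < max(ci, 0.06)


def test_selection_never_sees_test_labels():
    """Selected features depend only on the training fold."""
    rng = np.random.default_rng(10)
    table = make_table(rng)
    y = table.class_vector()
    from sklearn.model_selection import StratifiedKFold
    train_idx, test_idx = next(
        StratifiedKFold(10, shuffle=True, random_state=0)
        .split(table.values, y))
    sel1 = FeatureSelector("filter", 5).fit(table.values.iloc[train_idx],
                                            y[train_idx])
    y_shuffled = y.copy()
    y_shuffled[test_idx] = rng.permutation(y_shuffled[test_idx])
    sel2 = FeatureSelector("filter", 5).fit(table.values.iloc[train_idx],
                                            y_shuffled[train_idx])
    assert sel1.selected_ == sel2.selected_


def test_feature_table_validation():
    rng = np.random.default_rng(11)
    t = make_table(rng, n_per_class=5)
    bad = t.values.copy()
    bad.iloc[0, 0] = np.nan
    with pytest.raises(ValueError, match="missing"):
        FeatureTable(values=bad, groups=t.groups, subjects=t.subjects,
                     segments=t.segments)
    with pytest.raises(ValueError, match="2 group"):
        FeatureTable(values=t.values, groups=pd.Series(["A"] * 10),
                     subjects=t.subjects, segments=t.segments)
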