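import numpy as np
import pandas as pd
import pytest

from lipotherm import estimate_threshold, split_activity
from lipotherm.activity import (
    ActivityClassifier,
    ActivityRegressor,
    select_features,
    variable_importance,
    _make_pipeline,
    _family_spec,
)
from lipotherm.exceptions import LipothermError


def _feature_frame(rng, n=40, p=4, informative=True):
    X = pd.DataFrame(
        rng.normal(size=(n, p)),
        columns=[f"f{i}" for i in range(p)],
        index=[f"C{i:02d}" for i in range(n)],
    )
    return X


# ---------------------------------------------------------------------------
# ED50 split and threshold


def test_split_activity_labels_and_boundary():
    labels, counts = split_activity(pd.Series([100.0, 500.0, 350.0]), 350.0)
    assert list(labels) == ["active", "inactive", "inactive"]  # >= is inactive
    assert counts == {"active": 1, "inactive": 2}


def test_split_activity_degenerate_side_is_reported_not_raised():
    labels, counts = split_activity(pd.Series([10.0, 20.0]), 350.0)
    assert counts == {"active": 2, "inactive": 0}


def test_threshold_falls_back_on_unimodal_data(rng):
    vals = np.exp(rng.normal(np.log(200), 0.1, size=30))
    assert estimate_threshold(vals) == 350.0
    assert estimate_threshold([100.0, 110.0]) == 350.0  # too few points


def test_threshold_found_between_separated_modes(rng):
    lo = 100 * np.exp(rng.normal(0, 0.15, 30))
    hi = 600 * np.exp(rng.normal(0, 0.15, 30))
    thr = estimate_threshold(np.concatenate([lo, hi]))
    # valley sits in the empirical gap between the two dose populations
    assert lo.max() < thr < hi.min()


def test_bimodal_mixture_labels_match_components(rng):
    lo = 110 * np.exp(rng.normal(0, 0.3, 40))
    hi = 620 * np.exp(rng.normal(0, 0.25, 40))
    ed50 = pd.Series(np.concatenate([lo, hi]))
    thr = estimate_threshold(ed50)
    labels, _ = split_activity(ed50, thr)
    expected = ["active"] * 40 + ["inactive"] * 40
    agreement = np.mean(labels.to_numpy() == np.array(expected))
    assert agreement >= 0.95


# ---------------------------------------------------------------------------
# classification


def test_separable_classes_classified_perfectly(rng):
    X = _feature_frame(rng, n=40)
    y = np.where(X["f0"] > 0, "active", "inactive")
    X["f0"] += np.where(X["f0"] > 0, 5.0, -5.0)  # huge margin
    rep = ActivityClassifier(X, y, "penalized_logistic", seed=0, n_repeats=3).fit()
    assert rep.test_metrics["accuracy"] == 1.0
    assert rep.importance[0][0] == "f0"


@pytest.mark.parametrize("family", ["random_forest", "pls_da"])
def test_other_classifier_families_fit_and_report(rng, family):
    X = _feature_frame(rng, n=30)
    y = np.where(X["f0"] + 0.1 * rng.normal(size=30) > 0, "active", "inactive")
    rep = ActivityClassifier(X, y, family, seed=1, n_repeats=2).fit()
    assert 0.0 <= rep.test_metrics["accuracy"] <= 1.0
    assert set(f for f, _ in rep.importance) == set(X.columns)
    assert rep.hyperparameters  # tuning happened


def test_reports_are_seed_deterministic(rng):
    X = _feature_frame(rng, n=24)
    y = np.where(X["f1"] > 0, "active", "inactive")
    a = ActivityClassifier(X, y, "penalized_logistic", seed=7, n_repeats=2).fit()
    b = ActivityClassifier(X, y, "penalized_logistic", seed=7, n_repeats=2).fit()
    assert a.to_dict() == b.to_dict()


def test_unknown_family_rejected(rng):
    X = _feature_frame(rng, n=12)
    with pytest.raises(LipothermError):
        ActivityClassifier(X, ["active"] * 6 + ["inactive"] * 6, "pls_regression")


# ---------------------------------------------------------------------------
# regression


def test_noiseless_linear_target_recovered(rng):
    X = _feature_frame(rng, n=30)
    y = 2.0 * X["f0"] + 1.0
    rep = ActivityRegressor(X, y, "penalized_regression", seed=0, n_repeats=2).fit()
    assert rep.test_metrics["rmse"] < 0.05
    assert rep.test_metrics["r2"] > 0.99


def test_constant_target_flagged_degenerate(rng):
    X = _feature_frame(rng, n=20)
    y = np.full(20, 250.0)
    rep = ActivityRegressor(X, y, "penalized_regression", seed=0, n_repeats=2).fit()
    assert rep.test_metrics["rmse"] == pytest.approx(0.0, abs=1e-6)
    assert rep.test_metrics.get("degenerate_target")


def test_monotone_target_ranks_driver_first(rng):
    X = _feature_frame(rng, n=40)
    y = 300 - 80 * X["f2"] + rng.normal(0, 10, size=40)
    rep = ActivityRegressor(X, y, "penalized_regression", seed=0, n_repeats=3).fit()
    assert rep.importance[0][0] == "f2"


# ---------------------------------------------------------------------------
# permutation importance


def test_unused_feature_has_near_zero_importance(rng):
    X = _feature_frame(rng, n=40)
    y = 3.0 * X["f0"]
    est, _ = _family_spec("penalized_regression", 0)
    pipe = _make_pipeline(est)
    pipe.fit(X, y)
    scores = dict(variable_importance(pipe, X, y, seed=0))
    assert scores["f0"] > 10 * max(abs(scores["f1"]), abs(scores["f3"]), 1e-9)
    assert abs(scores["f1"]) < 0.05 * scores["f0"]


# ---------------------------------------------------------------------------
# feature selection


def test_single_feature_returned_unchanged(rng):
    X = _feature_frame(rng, n=20, p=1)
    sel, trace = select_features(X, rng.normal(size=20), "rfe", "penalized_regression")
    assert sel == ["f0"]


def test_rfe_matches_brute_force_on_two_features(rng):
    from lipotherm.activity import _subset_score

    X = _feature_frame(rng, n=30, p=2)
    y = 2.0 * X["f0"] + rng.normal(0, 0.3, 30)
    sel, trace = select_features(X, y, "rfe", "penalized_regression", seed=3)
    scores = {
        tuple(sub): _subset_score(X, y, "penalized_regression", "regression", sub, 3, 3, 3)
        for sub in (["f0"], ["f1"], ["f0", "f1"])
    }
    best = max(scores, key=scores.get)
    assert tuple(sel) == best


@pytest.mark.parametrize("method", ["rfe", "simulated_annealing"])
def test_informative_feature_retained(method):
    hits = 0
    runs = 12
    for seed in range(runs):
        rng = np.random.default_rng(1000 + seed)
        X = _feature_frame(rng, n=36, p=8)
        y = 4.0 * X["f0"] + rng.normal(0, 0.5, 36)
        sel, _ = select_features(
            X, y, method, "penalized_regression", seed=seed, sa_iterations=25
        )
        hits += "f0" in sel
    assert hits >= runs - 1


# ---------------------------------------------------------------------------
# leakage canary


def test_global_feature_screening_inflates_cv_accuracy(rng):
    """Selecting features on the full table before CV leaks the held-out
    folds: on pure noise it reports far-better-than-chance accuracy, while
    the honest in-fold protocol stays near chance. Guards the design rule
    that all preprocessing lives inside the CV pipeline."""
    from sklearn.model_selection import StratifiedKFold
    from sklearn.linear_model import LogisticRegression

    n, p = 30, 200
    X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"g{i}" for i in range(p)])
    y = np.array(["a", "b"] * (n // 2))

    def cv_accuracy(select_inside):
        accs = []
        for tr, te in StratifiedKFold(5, shuffle=True, random_state=0).split(X, y):
            pool = tr if select_inside else np.arange(n)
            corr = [abs(np.corrcoef(X.iloc[pool, j], (y[pool] == "a").astype(float))[0, 1])
                    for j in range(p)]
            keep = np.argsort(corr)[-5:]
            clf = LogisticRegression().fit(X.iloc[tr, keep], y[tr])
            accs.append(np.mean(clf.predict(X.iloc[te, keep]) == y[te]))
        return np.mean(accs)

    leaked = cv_accuracy(select_inside=False)
    honest = cv_accuracy(select_inside=True)
    assert leaked > honest + 0.15
    assert abs(honest - 0.5) < 0.2
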