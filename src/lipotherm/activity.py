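"""Anticonvulsant-activity modelling from chromatographic feature tables.

The endpoint is ED50 in the maximal-electroshock seizure model (mg/kg; the
dose protecting half the animals — *lower* means *more potent*). ED50 across
a congeneric series is typically bimodal, splitting compounds into an active
(low-dose) and an inactive (high-dose) population; the discrimination
boundary defaults to 350 mg/kg and can be re-estimated from the valley of a
smoothed density.

Model families
--------------
Classification: elastic-net logistic regression, random forest, PLS-DA.
Regression: elastic-net (penalized) regression, random forest, PLS.

All tuning uses repeated 3-fold cross-validation; features are standardized
*inside* every fold (sklearn pipelines), never globally — with a dozen
compounds, any preprocessing fitted on the full table leaks the test fold
into training. Variable importance is model-agnostic permutation importance.
Feature selection offers recursive feature elimination and simulated
annealing over the subset space, both scored by cross-validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.linear_model import ElasticNet, LogisticRegression
from sklearn.metrics import accuracy_score, mean_absolute_error, mean_squared_error, r2_score
from sklearn.model_selection import (
    RepeatedKFold,
    RepeatedStratifiedKFold,
    cross_val_score,
    train_test_split,
)
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .exceptions import LipothermError, ValidationError

__all__ = [
    "DEFAULT_ED50_THRESHOLD",
    "split_activity",
    "estimate_threshold",
    "ActivityModelReport",
    "ActivityClassifier",
    "ActivityRegressor",
    "train_classifier",
    "train_regressor",
    "select_features",
    "variable_importance",
    "build_feature_table",
]

DEFAULT_ED50_THRESHOLD = 350.0  # mg/kg

CLASSIFIER_FAMILIES = ("penalized_logistic", "random_forest", "pls_da")
REGRESSOR_FAMILIES = ("penalized_regression", "rf_regression", "pls_regression")


# ---------------------------------------------------------------------------
# ED50 handling


def split_activity(ed50, threshold: float = DEFAULT_ED50_THRESHOLD):
    """Label doses: ED50 < threshold -> 'active', >= threshold -> 'inactive'.

    Returns (labels, counts). All records on one side raises no error; a
    degenerate labelling is reported through the counts.
    """
    if threshold <= 0:
        raise ValidationError(f"threshold={threshold} must be > 0")
    ed50 = pd.Series(ed50, dtype=float)
    if (ed50 <= 0).any():
        raise ValidationError("ED50 values must be > 0")
    labels = pd.Series(
        np.where(ed50 < threshold, "active", "inactive"), index=ed50.index, name="class_label"
    )
    counts = labels.value_counts().reindex(["active", "inactive"], fill_value=0).to_dict()
    return labels, counts


def estimate_threshold(
    ed50, fallback: float = DEFAULT_ED50_THRESHOLD, bandwidth: str | float = "scott"
) -> float:
    """Valley of a smoothed log-dose density between the two largest modes.

    Doses are lognormal-ish, so the kernel density estimate runs on
    log10(ED50); the deepest minimum between the two highest maxima is
    returned on the dose scale. Unimodal or too-small samples fall back to
    ``fallback``.
    """
    x = np.log10(np.asarray(ed50, dtype=float))
    if x.size < 6 or np.ptp(x) == 0:
        return float(fallback)
    kde = stats.gaussian_kde(x, bw_method=bandwidth)
    grid = np.linspace(x.min(), x.max(), 512)
    dens = kde(grid)
    interior = np.arange(1, grid.size - 1)
    maxima = interior[(dens[interior] > dens[interior - 1]) & (dens[interior] >= dens[interior + 1])]
    if maxima.size < 2:
        return float(fallback)
    top2 = maxima[np.argsort(dens[maxima])[-2:]]
    lo, hi = sorted(top2)
    between = np.arange(lo, hi + 1)
    valley = between[np.argmin(dens[between])]
    return float(10 ** grid[valley])


# ---------------------------------------------------------------------------
# PLS-DA estimator (PLS regression on a binary indicator, 0.5 cut)


class PLSDAClassifier(BaseEstimator, ClassifierMixin):
    """Partial least squares discriminant analysis for two classes.

    Fits PLS regression on a 0/1 indicator of the positive class and
    classifies by thresholding the predicted score at 0.5. Suited to
    collinear, low-n feature tables where projection to a couple of latent
    components is the natural dimension reduction.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise LipothermError("PLS-DA here supports exactly two classes")
        ncomp = min(self.n_components, X.shape[1], max(1, X.shape[0] - 1))
        self.pls_ = PLSRegression(n_components=ncomp, scale=False)
        self.pls_.fit(X, (np.asarray(y) == self.classes_[1]).astype(float))
        return self

    def decision_function(self, X):
        return self.pls_.predict(np.asarray(X, dtype=float)).ravel() - 0.5

    def predict(self, X):
        return np.where(self.decision_function(X) >= 0, self.classes_[1], self.classes_[0])


# ---------------------------------------------------------------------------
# family -> (estimator, hyperparameter grid)


def _family_spec(family: str, seed: int):
    if family == "penalized_logistic":
        est = LogisticRegression(solver="saga", max_iter=10000, tol=1e-4)
        grid = {"C": [0.1, 1.0, 10.0], "l1_ratio": [0.0, 0.5, 1.0]}
    elif family == "random_forest":
        est = RandomForestClassifier(n_estimators=500, random_state=seed)
        grid = {"max_features": ["sqrt", 1.0]}
    elif family == "pls_da":
        est = PLSDAClassifier()
        grid = {"n_components": [1, 2, 3]}
    elif family == "penalized_regression":
        est = ElasticNet(max_iter=50000, tol=1e-8)
        grid = {"alpha": [1e-5, 1e-3, 0.1, 1.0], "l1_ratio": [0.0, 0.1, 0.5, 1.0]}
    elif family == "rf_regression":
        est = RandomForestRegressor(n_estimators=500, random_state=seed)
        grid = {"max_features": ["sqrt", 1.0]}
    elif family == "pls_regression":
        est = PLSRegression(scale=False)
        grid = {"n_components": [1, 2, 3]}
    else:
        raise LipothermError(
            f"unknown model family {family!r}; classification families are "
            f"{CLASSIFIER_FAMILIES}, regression families {REGRESSOR_FAMILIES}"
        )
    return est, grid


def _make_pipeline(est) -> Pipeline:
    return Pipeline([("scale", StandardScaler()), ("model", est)])


def _grid_points(grid: dict):
    """Expand a dict of lists into dicts, in stable order."""
    keys = sorted(grid)
    points = [{}]
    for key in keys:
        points = [{**p, key: v} for p in points for v in grid[key]]
    return points


@dataclass
class ActivityModelReport:
    """What a fitted activity model is and how well it does.

    ``importance`` ranks every feature supplied to the final model by mean
    permutation-importance score (metric degradation under shuffling).
    """

    model_family: str
    task: str  # "classification" | "regression"
    hyperparameters: dict
    cv_metrics: dict
    test_metrics: dict
    importance: list  # [(feature, score), ...] descending
    selection_method: str
    selected_features: list
    seed: int
    estimator: Pipeline = field(repr=False, default=None)
    selection_trace: list = field(default_factory=list, repr=False)

    def to_dict(self) -> dict:
        return {
            "model_family": self.model_family,
            "task": self.task,
            "hyperparameters": self.hyperparameters,
            "cv_metrics": self.cv_metrics,
            "test_metrics": self.test_metrics,
            "importance": [[f, float(s)] for f, s in self.importance],
            "selection_method": self.selection_method,
            "selected_features": list(self.selected_features),
            "seed": self.seed,
        }

    def summary(self) -> str:
        lines = [
            f"{self.model_family} ({self.task}), selection = {self.selection_method}",
            f"hyperparameters: {self.hyperparameters}",
            f"cross-validation: {self.cv_metrics}",
            f"held-out test:    {self.test_metrics}",
            "permutation importance:",
        ]
        lines += [f"  {f:<24s} {s: .4f}" for f, s in self.importance]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# CV scoring


def _cv(task: str, n_splits: int, n_repeats: int, seed: int):
    if task == "classification":
        return RepeatedStratifiedKFold(n_splits=n_splits, n_repeats=n_repeats, random_state=seed)
    return RepeatedKFold(n_splits=n_splits, n_repeats=n_repeats, random_state=seed)


def _cv_score(pipe, X, y, task, n_splits, n_repeats, seed) -> float:
    """Mean CV accuracy (classification) or negative RMSE (regression)."""
    scoring = "accuracy" if task == "classification" else "neg_root_mean_squared_error"
    cv = _cv(task, n_splits, n_repeats, seed)
    scores = cross_val_score(pipe, X, y, scoring=scoring, cv=cv, error_score="raise")
    return float(scores.mean())


def _tune(family, X, y, task, n_splits, n_repeats, seed):
    est, grid = _family_spec(family, seed)
    best = (-math.inf, None)
    for point in _grid_points(grid):
        pipe = _make_pipeline(clone(est).set_params(**point))
        score = _cv_score(pipe, X, y, task, n_splits, n_repeats, seed)
        if score > best[0]:
            best = (score, point)
    cv_score, params = best
    final = _make_pipeline(clone(est).set_params(**params))
    final.fit(X, y)
    return final, params, cv_score


def _safe_split(X, y, test_size, seed, task, max_retries=20):
    """Train/test split; for classification, retry (bounded) until the train
    split holds both classes."""
    stratify = y if task == "classification" and pd.Series(y).value_counts().min() >= 2 else None
    for attempt in range(max_retries):
        Xtr, Xte, ytr, yte = train_test_split(
            X, y, test_size=test_size, random_state=seed + attempt, stratify=stratify
        )
        if task != "classification" or len(np.unique(ytr)) >= 2:
            return Xtr, Xte, ytr, yte
    raise LipothermError(
        f"could not obtain a two-class training split in {max_retries} attempts"
    )


def variable_importance(
    model, X: pd.DataFrame, y, metric: str | None = None, n_permutations: int = 30, seed: int = 0
) -> list:
    """Model-agnostic permutation importance, ranked descending.

    Score = mean degradation of the metric when one feature column is
    shuffled, over ``n_permutations`` seeded shuffles.
    """
    if metric is None:
        metric = "accuracy" if isinstance(model[-1], ClassifierMixin) else "neg_root_mean_squared_error"
    res = permutation_importance(
        model, X, np.asarray(y), scoring=metric, n_repeats=n_permutations, random_state=seed
    )
    order = np.argsort(res.importances_mean)[::-1]
    return [(X.columns[i], float(res.importances_mean[i])) for i in order]


# ---------------------------------------------------------------------------
# feature selection


def select_features(
    X: pd.DataFrame,
    y,
    method: str,
    family: str,
    task: str | None = None,
    n_splits: int = 3,
    n_repeats: int = 3,
    seed: int = 0,
    sa_iterations: int = 40,
    sa_t0: float = 0.02,
    sa_cooling: float = 0.9,
):
    """Wrapper feature selection scored by repeated k-fold CV.

    'rfe' iteratively drops the least permutation-important feature and keeps
    the best-scoring subset size; 'simulated_annealing' runs a seeded
    Metropolis walk over subset space with geometric cooling. Both return
    (selected feature list, trace of (subset, cv_score)).
    """
    task = task or ("classification" if family in CLASSIFIER_FAMILIES else "regression")
    if X.shape[1] < 1:
        raise LipothermError("no features to select from")
    if X.shape[1] == 1:
        return list(X.columns), [(list(X.columns), math.nan)]
    if method == "rfe":
        return _rfe(X, y, family, task, n_splits, n_repeats, seed)
    if method == "simulated_annealing":
        return _simulated_annealing(
            X, y, family, task, n_splits, n_repeats, seed, sa_iterations, sa_t0, sa_cooling
        )
    raise LipothermError(f"unknown selection method {method!r}")


def _subset_score(X, y, family, task, cols, n_splits, n_repeats, seed):
    est, _ = _family_spec(family, seed)
    pipe = _make_pipeline(est)
    return _cv_score(pipe, X[list(cols)], y, task, n_splits, n_repeats, seed)


def _rfe(X, y, family, task, n_splits, n_repeats, seed):
    cols = list(X.columns)
    trace = []
    best = (-math.inf, list(cols))
    while len(cols) >= 1:
        score = _subset_score(X, y, family, task, cols, n_splits, n_repeats, seed)
        trace.append((list(cols), score))
        if score > best[0]:
            best = (score, list(cols))
        if len(cols) == 1:
            break
        est, _ = _family_spec(family, seed)
        pipe = _make_pipeline(est)
        pipe.fit(X[cols], np.asarray(y))
        imp = variable_importance(pipe, X[cols], y, n_permutations=10, seed=seed)
        cols.remove(imp[-1][0])
    return best[1], trace


def _simulated_annealing(
    X, y, family, task, n_splits, n_repeats, seed, iterations, t0, cooling
):
    rng = np.random.default_rng(seed)
    cols = list(X.columns)
    p = len(cols)
    mask = np.ones(p, dtype=bool)

    def score_of(m):
        return _subset_score(
            X, y, family, task, [c for c, keep in zip(cols, m) if keep],
            n_splits, n_repeats, seed,
        )

    current = score_of(mask)
    best_mask, best_score = mask.copy(), current
    trace = [([c for c, keep in zip(cols, mask) if keep], current)]
    temp = t0
    for _ in range(iterations):
        cand = mask.copy()
        j = int(rng.integers(p))
        cand[j] = ~cand[j]
        if cand.sum() == 0:
            continue
        cand_score = score_of(cand)
        accept = cand_score >= current or rng.random() < math.exp((cand_score - current) / temp)
        if accept:
            mask, current = cand, cand_score
            if current > best_score:
                best_mask, best_score = mask.copy(), current
        trace.append(([c for c, keep in zip(cols, cand) if keep], cand_score))
        temp *= cooling
    return [c for c, keep in zip(cols, best_mask) if keep], trace


# ---------------------------------------------------------------------------
# model objects


class _ActivityModelBase:
    task: str = ""
    families: tuple = ()

    def __init__(
        self,
        features: pd.DataFrame,
        target,
        family: str,
        selection_method: str = "none",
        test_size: float = 5 / 14,
        n_splits: int = 3,
        n_repeats: int = 10,
        selection_repeats: int = 3,
        seed: int = 0,
    ):
        if family not in self.families:
            raise LipothermError(f"{family!r} is not a {self.task} family {self.families}")
        self.features = features.astype(float)
        if self.features.isna().any().any():
            raise ValidationError("feature table contains missing values")
        self.target = pd.Series(target, index=features.index)
        if self.target.isna().any():
            raise ValidationError("missing targets are not allowed")
        self.family = family
        self.selection_method = selection_method
        self.test_size = test_size
        self.n_splits = n_splits
        self.n_repeats = n_repeats
        self.selection_repeats = selection_repeats
        self.seed = int(seed)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, target_column: str, family: str, **kw):
        features = df.drop(columns=[target_column])
        return cls(features, df[target_column], family, **kw)

    def _test_metrics(self, model, Xte, yte) -> dict:
        raise NotImplementedError

    def fit(self) -> ActivityModelReport:
        X, y = self.features, self.target.to_numpy()
        Xtr, Xte, ytr, yte = _safe_split(X, y, self.test_size, self.seed, self.task)

        selected = list(X.columns)
        trace = []
        if self.selection_method != "none":
            selected, trace = select_features(
                Xtr, ytr, self.selection_method, self.family, task=self.task,
                n_splits=self.n_splits, n_repeats=self.selection_repeats, seed=self.seed,
            )
        model, params, cv_score = _tune(
            self.family, Xtr[selected], ytr, self.task, self.n_splits, self.n_repeats, self.seed
        )
        test_metrics = self._test_metrics(model, Xte[selected], yte)
        cv_key = "accuracy" if self.task == "classification" else "neg_rmse"
        importance = variable_importance(model, Xte[selected], yte, seed=self.seed)
        return ActivityModelReport(
            model_family=self.family,
            task=self.task,
            hyperparameters=params,
            cv_metrics={cv_key: cv_score},
            test_metrics=test_metrics,
            importance=importance,
            selection_method=self.selection_method,
            selected_features=selected,
            seed=self.seed,
            estimator=model,
            selection_trace=trace,
        )


class ActivityClassifier(_ActivityModelBase):
    """Active/inactive discrimination from chromatographic features.

    ``fit()`` tunes the family's hyperparameters by repeated 3-fold CV on a
    seeded train split (default 9/5-style proportions), evaluates on the
    held-out test split, and reports permutation importance.
    """

    task = "classification"
    families = CLASSIFIER_FAMILIES

    def _test_metrics(self, model, Xte, yte) -> dict:
        pred = model.predict(Xte)
        return {"accuracy": float(accuracy_score(yte, pred))}


class ActivityRegressor(_ActivityModelBase):
    """ED50 regression from chromatographic features (RMSE / R^2 / MAE)."""

    task = "regression"
    families = REGRESSOR_FAMILIES

    def _test_metrics(self, model, Xte, yte) -> dict:
        pred = np.asarray(model.predict(Xte)).ravel()
        if np.ptp(yte) == 0:
            return {
                "rmse": float(np.sqrt(mean_squared_error(yte, pred))),
                "r2": 0.0,
                "mae": float(mean_absolute_error(yte, pred)),
                "degenerate_target": True,
            }
        return {
            "rmse": float(np.sqrt(mean_squared_error(yte, pred))),
            "r2": float(r2_score(yte, pred)),
            "mae": float(mean_absolute_error(yte, pred)),
        }


def train_classifier(features, target, family, selection_method="none", seed=0, **kw):
    """Functional wrapper around :class:`ActivityClassifier`."""
    return ActivityClassifier(
        features, target, family, selection_method=selection_method, seed=seed, **kw
    ).fit()


def train_regressor(features, target, family, selection_method="none", seed=0, **kw):
    """Functional wrapper around :class:`ActivityRegressor`."""
    return ActivityRegressor(
        features, target, family, selection_method=selection_method, seed=seed, **kw
    ).fit()


# ---------------------------------------------------------------------------
# feature-table assembly


def build_feature_table(lipo_results, thermo_results=None, t_ref: float = 293.15) -> pd.DataFrame:
    """Assemble the per-compound feature table the activity models consume.

    Columns: phi0/S/log_kw per modifier from the lipophilicity results, plus
    dH (kJ/mol) and dG (kJ/mol) per modifier when van't Hoff results are
    supplied (non-linear series contribute NaN and should be handled by the
    caller before modelling).
    """
    rows: dict[str, dict] = {}
    for ix in lipo_results.indices:
        row = rows.setdefault(ix.compound_id, {})
        row[f"phi0_{ix.modifier}"] = ix.phi0
        row[f"S_{ix.modifier}"] = ix.S
        row[f"log_kw_{ix.modifier}"] = ix.log_kw
    if thermo_results is not None:
        for r in thermo_results.results:
            row = rows.setdefault(r.compound_id, {})
            row[f"dH_kJ_{r.modifier}"] = r.dH / 1e3
            if r.linear_ok:
                row[f"dG_kJ_{r.modifier}"] = (r.dH - t_ref * r.dS_star) / 1e3
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = "compound_id"
    return df
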