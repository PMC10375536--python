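"""Affinity models on descriptor tables: nested CV, baselines, selection.

Regression models predict log10(Kd/M); classification models predict a
four-level affinity class (0 strongest to 3 weakest) obtained by binning
log10(Kd/M) at -8, -7 and -6 with the upper edge included in each bin.
Models are scored under nested cross-validation: an outer k-fold (default
k=5) provides the held-out scores, and on each outer-training portion an
inner k-fold (default k=5) drives a seeded randomized hyperparameter search
with a fixed trial budget. Regression is scored by MAE, classification by
balanced accuracy (unweighted mean per-class recall). Two reference
baselines are provided: predicting the training-fold mean, and predictions
drawn as random permutations of the training targets (averaged over many
permutations).

Every run is reproducible from its seed; per-fold trial seeds are spawned
from the master seed so reports are bit-identical across reruns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import (AdaBoostClassifier, AdaBoostRegressor,
                              ExtraTreesClassifier, ExtraTreesRegressor,
                              GradientBoostingClassifier, GradientBoostingRegressor,
                              HistGradientBoostingClassifier, HistGradientBoostingRegressor,
                              RandomForestClassifier, RandomForestRegressor)
from sklearn.inspection import permutation_importance
from sklearn.metrics import balanced_accuracy_score, mean_absolute_error
from sklearn.model_selection import KFold, ParameterSampler, StratifiedKFold
from sklearn.svm import SVC, SVR

#: Default class-bin edges on log10(Kd/M); each bin includes its upper edge.
DEFAULT_CLASS_EDGES = (-8.0, -7.0, -6.0)


def bin_affinity(log_kd: float, edges: Sequence[float] = DEFAULT_CLASS_EDGES) -> int:
    """Affinity class of a log10(Kd/M) value: 0 for ≤ edges[0], then one class
    per half-open interval (lo, hi], and len(edges) above the last edge."""
    if not math.isfinite(log_kd):
        raise ValueError("log_kd must be finite")
    for c, edge in enumerate(edges):
        if log_kd <= edge:
            return c
    return len(edges)


def class_midpoints(edges: Sequence[float] = DEFAULT_CLASS_EDGES) -> list[float]:
    """Representative log10(Kd/M) per class (outer classes offset by half a bin)."""
    step = edges[1] - edges[0] if len(edges) > 1 else 1.0
    mids = [edges[0] - step / 2]
    mids += [(a + b) / 2 for a, b in zip(edges[:-1], edges[1:])]
    mids.append(edges[-1] + step / 2)
    return mids


def mae(predicted: Sequence[float], observed: Sequence[float]) -> float:
    """Mean absolute error in log10(Kd/M) units."""
    if len(predicted) == 0 or len(predicted) != len(observed):
        raise ValueError("predicted and observed must be equal-length and nonempty")
    return float(mean_absolute_error(observed, predicted))


def balanced_accuracy(predicted_classes: Sequence[int], true_classes: Sequence[int]) -> float:
    """Unweighted mean of per-class recall over classes present in the truth."""
    if len(predicted_classes) == 0 or len(predicted_classes) != len(true_classes):
        raise ValueError("predicted and true classes must be equal-length and nonempty")
    return float(balanced_accuracy_score(true_classes, predicted_classes))


# ---------------------------------------------------------------------------
# Model registry
# ---------------------------------------------------------------------------

def _space_uniform(lo, hi):
    class _U:
        def rvs(self, random_state=None):
            return float(random_state.uniform(lo, hi))
    return _U()


def _space_loguniform(lo, hi):
    class _L:
        def rvs(self, random_state=None):
            return float(10.0 ** random_state.uniform(math.log10(lo), math.log10(hi)))
    return _L()


def model_space(name: str, task: str, seed: int = 0):
    """(estimator, hyperparameter distributions) for a supported model family.

    Families mirror the tree/boosting/SVM stack customarily compared for this
    problem: random_forest, extra_trees, gradient_boosting,
    hist_gradient_boosting, adaboost, svm, linear_svm (an SVM restricted to
    the linear kernel), plus xgboost / lightgbm when those backends are
    installed.
    """
    if task not in ("regression", "classification"):
        raise ValueError("task must be 'regression' or 'classification'")
    reg = task == "regression"
    tree_space = {"n_estimators": [100, 200, 400],
                  "max_depth": [None, 4, 8, 16],
                  "min_samples_leaf": [1, 2, 4, 8]}
    gb_space = {"n_estimators": [100, 200, 400],
                "learning_rate": _space_loguniform(0.01, 0.3),
                "max_depth": [2, 3, 4, 6]}
    if name == "random_forest":
        est = (RandomForestRegressor if reg else RandomForestClassifier)(random_state=seed)
        return est, tree_space
    if name == "extra_trees":
        est = (ExtraTreesRegressor if reg else ExtraTreesClassifier)(random_state=seed)
        return est, tree_space
    if name == "gradient_boosting":
        est = (GradientBoostingRegressor if reg else GradientBoostingClassifier)(random_state=seed)
        return est, gb_space
    if name == "hist_gradient_boosting":
        est = (HistGradientBoostingRegressor if reg else HistGradientBoostingClassifier)(random_state=seed)
        return est, {"max_iter": [100, 200, 400],
                     "learning_rate": _space_loguniform(0.01, 0.3),
                     "max_depth": [None, 3, 6]}
    if name == "adaboost":
        est = (AdaBoostRegressor if reg else AdaBoostClassifier)(random_state=seed)
        return est, {"n_estimators": [50, 100, 200],
                     "learning_rate": _space_loguniform(0.01, 1.0)}
    if name == "svm":
        est = SVR() if reg else SVC(random_state=seed)
        space = {"C": _space_loguniform(0.1, 100.0),
                 "gamma": _space_loguniform(1e-3, 1.0),
                 "kernel": ["rbf", "linear"]}
        if reg:
            space["epsilon"] = _space_loguniform(1e-4, 0.3)
        return est, space
    if name == "linear_svm":
        est = SVR(kernel="linear") if reg else SVC(kernel="linear", random_state=seed)
        space = {"C": _space_loguniform(0.1, 1000.0)}
        if reg:
            space["epsilon"] = _space_loguniform(1e-5, 0.1)
        return est, space
    if name == "xgboost":
        from xgboost import XGBClassifier, XGBRegressor
        est = (XGBRegressor if reg else XGBClassifier)(random_state=seed, verbosity=0)
        return est, gb_space
    if name == "lightgbm":
        from lightgbm import LGBMClassifier, LGBMRegressor
        est = (LGBMRegressor if reg else LGBMClassifier)(random_state=seed, verbose=-1)
        return est, {"n_estimators": [100, 200, 400],
                     "learning_rate": _space_loguniform(0.01, 0.3),
                     "num_leaves": [7, 15, 31]}
    raise ValueError(f"unsupported model family {name!r}")


@dataclass
class ModelReport:
    """Per-outer-fold and aggregate scores of one nested-CV evaluation."""

    task: str
    model: str
    metric: str  # "MAE" | "balanced_accuracy"
    fold_scores: list[float]
    seed: int
    hyperparameter_trace: list[dict] = field(default_factory=list)
    fold_test_ids: list[list] = field(default_factory=list)

    @property
    def aggregate(self) -> float:
        return float(np.mean(self.fold_scores))

    def to_dict(self) -> dict:
        return {"task": self.task, "model": self.model, "metric": self.metric,
                "fold_scores": self.fold_scores, "aggregate": self.aggregate,
                "seed": self.seed, "hyperparameter_trace": self.hyperparameter_trace}


def _score(task: str, y_true, y_pred) -> float:
    return mae(y_pred, y_true) if task == "regression" else balanced_accuracy(y_pred, y_true)


def _better(task: str, a: float, b: float) -> bool:
    return a < b if task == "regression" else a > b


def _as_xy(table, targets):
    X = table.to_numpy(dtype=float) if isinstance(table, pd.DataFrame) else np.asarray(table, float)
    y = targets.to_numpy() if isinstance(targets, (pd.Series, pd.DataFrame)) else np.asarray(targets)
    ids = (list(table.index) if isinstance(table, pd.DataFrame)
           else list(range(len(X))))
    return X, y, ids


def _outer_splitter(task, k, seed):
    if task == "classification":
        return StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return KFold(n_splits=k, shuffle=True, random_state=seed)


def _inner_search(X, y, task, model, k_inner, budget, rng_seed):
    """Randomized search scored by inner k-fold CV; returns best params."""
    est, space = model_space(model, task, seed=rng_seed)
    sampler = list(ParameterSampler(space, n_iter=budget,
                                    random_state=np.random.RandomState(rng_seed)))
    splitter = _outer_splitter(task, k_inner, rng_seed)
    best_params, best_score = None, None
    for params in sampler:
        scores = []
        try:
            for tr, te in splitter.split(X, y if task == "classification" else None):
                m = clone(est).set_params(**params)
                m.fit(X[tr], y[tr])
                scores.append(_score(task, y[te], m.predict(X[te])))
        except ValueError as exc:
            raise ValueError(
                "inner-fold stratification failed (a class is too rare for "
                "k-fold splitting); merge affinity bins or reduce k_inner"
            ) from exc
        s = float(np.mean(scores))
        if best_score is None or _better(task, s, best_score):
            best_params, best_score = params, s
    return best_params, best_score


def nested_cv(table, targets, task: str = "regression", model: str = "svm",
              k_outer: int = 5, k_inner: int = 5, seed: int = 0,
              budget: int = 50) -> ModelReport:
    """Nested cross-validation of one model family.

    Hyperparameters are chosen per outer fold by an inner-CV randomized
    search restricted to the outer-training portion, then scored once on the
    outer-test portion. Fully reproducible from ``seed``.
    """
    X, y, ids = _as_xy(table, targets)
    if len(X) < k_outer:
        raise ValueError(f"need at least k_outer={k_outer} rows")
    if task == "classification":
        _, counts = np.unique(y, return_counts=True)
        # every class must survive into every training AND inner fold
        if counts.min() < max(k_outer, k_inner):
            raise ValueError(
                f"rarest class has {counts.min()} members, fewer than the "
                f"{max(k_outer, k_inner)} folds require; merge affinity bins "
                "or reduce k")
    fold_seeds = np.random.SeedSequence(seed).generate_state(k_outer) % (2 ** 31)
    outer = _outer_splitter(task, k_outer, seed)
    fold_scores, trace, test_ids = [], [], []
    try:
        splits = list(outer.split(X, y if task == "classification" else None))
    except ValueError as exc:
        raise ValueError(
            "outer-fold stratification failed (a class is too rare); "
            "merge affinity bins or reduce k_outer") from exc
    for fold, (tr, te) in enumerate(splits):
        fseed = int(fold_seeds[fold])
        params, inner_score = _inner_search(X[tr], y[tr], task, model,
                                            k_inner, budget, fseed)
        est, _ = model_space(model, task, seed=fseed)
        m = clone(est).set_params(**params)
        m.fit(X[tr], y[tr])
        fold_scores.append(_score(task, y[te], m.predict(X[te])))
        trace.append({"fold": fold, "best_params": params,
                      "inner_score": inner_score, "seed": fseed})
        test_ids.append([ids[j] for j in te])
    return ModelReport(task=task, model=model,
                       metric="MAE" if task == "regression" else "balanced_accuracy",
                       fold_scores=fold_scores, seed=seed,
                       hyperparameter_trace=trace, fold_test_ids=test_ids)


def baselines(targets, task: str = "regression", k_outer: int = 5,
              seed: int = 0, n_permutations: int = 100) -> dict[str, ModelReport]:
    """Reference baselines under the same outer folds as :func:`nested_cv`.

    ``average`` predicts the training-fold mean (regression) or modal class
    (classification) for every test item. ``randomize`` draws test
    predictions uniformly without replacement from the training targets,
    averaging the score over ``n_permutations`` seeded permutations.
    """
    y = targets.to_numpy() if isinstance(targets, (pd.Series,)) else np.asarray(targets)
    outer = _outer_splitter(task, k_outer, seed)
    splits = list(outer.split(np.zeros((len(y), 1)),
                              y if task == "classification" else None))
    rng = np.random.default_rng(seed)
    avg_scores, rand_scores = [], []
    for tr, te in splits:
        if task == "regression":
            pred = np.full(len(te), y[tr].mean())
        else:
            vals, counts = np.unique(y[tr], return_counts=True)
            pred = np.full(len(te), vals[np.argmax(counts)])
        avg_scores.append(_score(task, y[te], pred))
        perm = [_score(task, y[te], rng.choice(y[tr], size=len(te), replace=False))
                for _ in range(n_permutations)]
        rand_scores.append(float(np.mean(perm)))
    metric = "MAE" if task == "regression" else "balanced_accuracy"
    return {"average": ModelReport(task, "baseline_average", metric, avg_scores, seed),
            "randomize": ModelReport(task, "baseline_randomize", metric, rand_scores, seed)}


def fit_screening_model(table, targets, task: str = "regression",
                        model: str = "svm", seed: int = 0, budget: int = 50,
                        k_inner: int = 5):
    """Final refit for screening: inner-CV hyperparameter search on the full
    table, then one fit on all rows. Returns (fitted estimator, best params)."""
    X, y, _ = _as_xy(table, targets)
    params, _ = _inner_search(X, y, task, model, k_inner, budget, seed)
    est, _ = model_space(model, task, seed=seed)
    m = clone(est).set_params(**params)
    m.fit(X, y)
    return m, params


def feature_importance(model, feature_names: Sequence[str],
                       X=None, y=None, kind: str = "impurity",
                       seed: int = 0) -> list[tuple[str, float]]:
    """Descending (name, importance) list, importances normalized to sum 1.

    ``impurity`` uses the fitted ensemble's own importances; ``permutation``
    scores feature shuffles on (X, y). Models without importances raise."""
    if kind == "impurity":
        if not hasattr(model, "feature_importances_"):
            raise TypeError(f"{type(model).__name__} exposes no impurity importances")
        imp = np.asarray(model.feature_importances_, dtype=float)
    elif kind == "permutation":
        if X is None or y is None:
            raise ValueError("permutation importance requires X and y")
        res = permutation_importance(model, np.asarray(X, float), np.asarray(y),
                                     n_repeats=10, random_state=seed)
        imp = np.clip(res.importances_mean, 0.0, None)
    else:
        raise ValueError("kind must be 'impurity' or 'permutation'")
    total = imp.sum()
    imp = imp / total if total > 0 else imp
    order = np.argsort(-imp)
    return [(feature_names[i], float(imp[i])) for i in order]


def rank_and_select(predictions: pd.Series | dict,
                    threshold_neglog: float | None = None,
                    top_n: int | None = None) -> list[str]:
    """Select screening candidates from predicted log10(Kd/M).

    Keeps ids with -log10(Kd/M) strictly above ``threshold_neglog`` (when
    given), then the ``top_n`` strongest binders (lowest predicted log Kd),
    ties broken by lexicographic ligand id. Both criteria optional.
    """
    s = pd.Series(predictions, dtype=float)
    if s.empty:
        raise ValueError("predictions must be nonempty")
    if threshold_neglog is not None:
        s = s[-s > threshold_neglog]
    order = sorted(s.items(), key=lambda kv: (kv[1], str(kv[0])))
    if top_n is not None:
        order = order[:top_n]
    return [str(k) for k, _ in order]
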