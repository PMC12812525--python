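"""The evaluation protocol: leakage-safe fold pipelines, repeated stratified
CV with top-5 model ensembling, grid search, and frozen cross-dataset tests.

Every preprocessing step (min-max rescaling, SVM-SMOTE oversampling, forward
feature selection) is fitted inside each training fold only and applied with
frozen parameters to validation and external data. The reference plan is
5-fold CV repeated 10 times with 5 models, i.e. metrics aggregated over
250 fold-level observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import MinMaxScaler
from sklearn.utils.validation import check_is_fitted, validate_data
from xgboost import XGBClassifier

from .metrics import evaluate
from .selection import ForwardFeatureSelector
from .smote import SVMSMOTE

__all__ = [
    "CVPlan",
    "MetricsReport",
    "GliomaModel",
    "TopKEnsembleClassifier",
    "make_base_model",
    "default_grid",
    "grid_search",
    "repeated_cv",
    "cross_dataset_eval",
    "minmax_fit",
    "minmax_apply",
]


def _derive_seed(*parts: int) -> int:
    """Deterministic sub-2^31 seed from a master seed and stream indices."""
    ss = np.random.SeedSequence([int(p) & 0x7FFFFFFF for p in parts])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# Min-max rescaling with frozen train statistics
# ---------------------------------------------------------------------------

def minmax_fit(X_train) -> MinMaxScaler:
    """Fit per-feature min/max on training rows only.

    Applied data is never clipped: validation/test values outside the train
    range extrapolate beyond [0, 1]. A constant training column maps to 0.
    """
    X_train = np.asarray(X_train, float)
    if X_train.shape[0] < 2:
        raise ValueError("min-max rescaling needs at least 2 training rows")
    return MinMaxScaler(clip=False).fit(X_train)


def minmax_apply(state: MinMaxScaler, X) -> np.ndarray:
    return state.transform(np.asarray(X, float))


# ---------------------------------------------------------------------------
# Base learners
# ---------------------------------------------------------------------------

def make_base_model(family: str, params: dict | None = None, seed: int = 0):
    params = dict(params or {})
    if family == "rf":
        params.setdefault("n_estimators", 100)
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if family == "xgb":
        params.setdefault("n_estimators", 100)
        params.setdefault("max_depth", 3)
        return XGBClassifier(
            random_state=seed, n_jobs=1, eval_metric="logloss", verbosity=0, **params
        )
    raise ValueError(f"unknown model family {family!r} (expected 'rf' or 'xgb')")


def default_grid() -> list[tuple[str, dict]]:
    """Modest default hyperparameter grid over both families."""
    grid: list[tuple[str, dict]] = []
    for n in (100, 300):
        for d in (None, 5):
            grid.append(("rf", {"n_estimators": n, "max_depth": d}))
    for n in (100, 300):
        for d in (3, 5):
            grid.append(("xgb", {"n_estimators": n, "max_depth": d, "learning_rate": 0.1}))
    return grid


# ---------------------------------------------------------------------------
# One model configuration = one leakage-safe fold pipeline
# ---------------------------------------------------------------------------

class GliomaModel(ClassifierMixin, BaseEstimator):
    """Min-max -> SVM-SMOTE -> forward selection -> classifier, as one unit.

    All fitted state carries the trailing underscore and is derived from the
    training data passed to :meth:`fit` alone. ``ffs_cap=None`` disables the
    selection stage (all features used).
    """

    def __init__(
        self,
        family: str = "rf",
        model_params: dict | None = None,
        ffs_cap: int | None = 10,
        inner_folds: int = 3,
        use_smote: bool = True,
        random_state: int = 0,
    ):
        self.family = family
        self.model_params = model_params
        self.ffs_cap = ffs_cap
        self.inner_folds = inner_folds
        self.use_smote = use_smote
        self.random_state = random_state

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        self.classes_ = np.unique(y)
        self.scaler_ = minmax_fit(X)
        Xs = minmax_apply(self.scaler_, X)

        if self.use_smote and len(self.classes_) == 2:
            counts = np.bincount(y.astype(int))
            if counts.min() != counts.max() and counts.min() >= 2:
                Xs, y = SVMSMOTE(random_state=_derive_seed(self.random_state, 1)).fit_resample(Xs, y)

        if self.ffs_cap is not None:
            self.selector_ = ForwardFeatureSelector(
                make_base_model(self.family, self.model_params, seed=self.random_state),
                cap=self.ffs_cap,
                inner_folds=self.inner_folds,
                random_state=_derive_seed(self.random_state, 2),
            ).fit(Xs, y)
            cols = self.selector_.support_
        else:
            self.selector_ = None
            cols = np.ones(Xs.shape[1], dtype=bool)
        self.support_ = cols

        self.model_ = make_base_model(self.family, self.model_params, seed=self.random_state)
        self.model_.fit(Xs[:, cols], y)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        X = validate_data(self, X, reset=False)
        Xs = minmax_apply(self.scaler_, X)
        return self.model_.predict_proba(Xs[:, self.support_])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    @property
    def selected_features_(self) -> list[int]:
        check_is_fitted(self, "support_")
        return list(np.flatnonzero(self.support_))


class TopKEnsembleClassifier(ClassifierMixin, BaseEstimator):
    """Unweighted probability average of the top-k fitted configurations."""

    def __init__(self, members: list | None = None):
        self.members = members

    def fit(self, X, y):
        if not self.members:
            raise ValueError("ensemble needs at least one member configuration")
        X, y = validate_data(self, X, y)
        self.classes_ = np.unique(y)
        self.members_ = [clone(m).fit(X, y) for m in self.members]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "members_")
        probs = [m.predict_proba(X) for m in self.members_]
        return np.mean(probs, axis=0)

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def ensemble_predict(ensemble: TopKEnsembleClassifier, X) -> np.ndarray:
    """Per-subject positive-class probability from a fitted ensemble."""
    return ensemble.predict_proba(X)[:, 1]


# ---------------------------------------------------------------------------
# Grid search and the repeated-CV harness
# ---------------------------------------------------------------------------

def grid_search(
    grid: list[tuple[str, dict]],
    X,
    y,
    n_folds: int = 3,
    seed: int = 0,
    ffs_cap: int | None = None,
) -> pd.DataFrame:
    """Score every configuration by stratified CV AUROC; rank descending.

    Ranking is deterministic: ties keep grid order. The top rows seed the
    final ensemble.
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    X = np.asarray(X, float)
    y = np.asarray(y).astype(int)
    cv = StratifiedKFold(n_folds, shuffle=True, random_state=_derive_seed(seed, 97))
    folds = list(cv.split(X, y))
    rows = []
    for gi, (family, params) in enumerate(grid):
        aurocs = []
        for fi, (tr, va) in enumerate(folds):
            model = GliomaModel(
                family=family,
                model_params=params,
                ffs_cap=ffs_cap,
                random_state=_derive_seed(seed, gi, fi),
            ).fit(X[tr], y[tr])
            aurocs.append(roc_auc_score(y[va], model.predict_proba(X[va])[:, 1]))
        rows.append({"family": family, "params": params, "auroc": float(np.mean(aurocs))})
    out = pd.DataFrame(rows)
    out = out.sort_values("auroc", ascending=False, kind="stable").reset_index(drop=True)
    return out


def top_k_members(ranked: pd.DataFrame, k: int = 5, ffs_cap: int | None = 10) -> list[GliomaModel]:
    """Instantiate the k best configurations as unfitted fold pipelines."""
    members = []
    for i in range(min(k, len(ranked))):
        members.append(
            GliomaModel(
                family=ranked.loc[i, "family"],
                model_params=dict(ranked.loc[i, "params"]),
                ffs_cap=ffs_cap,
                random_state=i,
            )
        )
    return members


@dataclass
class CVPlan:
    """Repeated stratified k-fold plan; the reference protocol is 10 x 5."""

    n_repeats: int = 10
    k: int = 5
    seed: int = 0
    stratified: bool = True

    def repeat_seed(self, repeat: int) -> int:
        return _derive_seed(self.seed, repeat)


@dataclass
class MetricsReport:
    """Per-observation metrics (one row per repeat x fold x model)."""

    observations: pd.DataFrame
    plan: CVPlan | None = None
    extra: dict = field(default_factory=dict)

    METRICS = ("auroc", "accuracy", "sensitivity", "specificity")

    @property
    def n_observations(self) -> int:
        return len(self.observations)

    def aggregate(self) -> pd.DataFrame:
        agg = self.observations[list(self.METRICS)].agg(["mean", "std"]).T
        agg.columns = ["mean", "sd"]
        agg["n"] = self.n_observations
        return agg

    def __str__(self) -> str:
        lines = [f"{self.n_observations} observations"]
        for name, row in self.aggregate().iterrows():
            lines.append(f"  {name:12s} {row['mean']:.3f} +/- {row['sd']:.3f}")
        return "\n".join(lines)


def repeated_cv(X, y, members: list[GliomaModel], plan: CVPlan | None = None) -> MetricsReport:
    """Run the repeated stratified CV harness over an ensemble's members.

    For each repeat and fold, every member pipeline is fitted on the
    training fold alone (rescaling, oversampling and selection included) and
    scored on the held-out fold; with the reference plan and 5 members this
    yields exactly 250 observations.
    """
    plan = plan or CVPlan()
    X = np.asarray(X, float)
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("repeated_cv requires both classes present")
    rows = []
    for rep in range(plan.n_repeats):
        cv = StratifiedKFold(plan.k, shuffle=True, random_state=plan.repeat_seed(rep))
        for fold, (tr, va) in enumerate(cv.split(X, y)):
            if len(np.unique(y[va])) < 2 or len(np.unique(y[tr])) < 2:
                raise ValueError(f"repeat {rep} fold {fold}: a split lost one class entirely")
            for mi, proto in enumerate(members):
                model = clone(proto)
                model.random_state = _derive_seed(plan.seed, rep, fold, mi)
                model.fit(X[tr], y[tr])
                scores = model.predict_proba(X[va])[:, 1]
                m = evaluate(scores, y[va])
                rows.append({"repeat": rep, "fold": fold, "model": mi, **m})
    return MetricsReport(observations=pd.DataFrame(rows), plan=plan)


def cross_dataset_eval(
    ensemble: TopKEnsembleClassifier,
    X_external,
    y_external,
    feature_names: list[str] | None = None,
    trained_feature_names: list[str] | None = None,
) -> dict[str, float]:
    """Score a frozen ensemble on an external cohort (no refitting).

    When feature-name lists are supplied the external schema must contain
    the training columns; missing ones are named in the error.
    """
    check_is_fitted(ensemble, "members_")
    if trained_feature_names is not None:
        if feature_names is None:
            raise ValueError("feature_names required to check the external schema")
        missing = [c for c in trained_feature_names if c not in feature_names]
        if missing:
            raise ValueError(f"external cohort is missing feature columns: {missing}")
        order = [feature_names.index(c) for c in trained_feature_names]
        X_external = np.asarray(X_external, float)[:, order]
    scores = ensemble.predict_proba(np.asarray(X_external, float))[:, 1]
    return evaluate(scores, np.asarray(y_external).astype(int))
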