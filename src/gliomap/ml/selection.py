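"""Greedy forward feature selection scored by inner-CV AUROC."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, clone
from sklearn.feature_selection import SelectorMixin
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted, validate_data


class ForwardFeatureSelector(SelectorMixin, BaseEstimator):
    """Add, at each step, the feature that maximizes inner-CV AUROC.

    Selection stops at ``cap`` features or as soon as no candidate strictly
    improves the score; exact ties break toward the lower column index.
    """

    def __init__(self, estimator, cap: int = 10, inner_folds: int = 3, random_state: int = 0):
        self.estimator = estimator
        self.cap = cap
        self.inner_folds = inner_folds
        self.random_state = random_state

    def _cv_auroc(self, X, y, cols, folds) -> float:
        scores = []
        for tr, va in folds:
            model = clone(self.estimator)
            model.fit(X[np.ix_(tr, cols)], y[tr])
            prob = model.predict_proba(X[np.ix_(va, cols)])[:, 1]
            scores.append(roc_auc_score(y[va], prob))
        return float(np.mean(scores))

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        if self.cap < 1:
            raise ValueError("cap must be >= 1")
        cv = StratifiedKFold(self.inner_folds, shuffle=True, random_state=self.random_state)
        folds = list(cv.split(X, y))

        selected: list[int] = []
        best_score = -np.inf
        remaining = list(range(X.shape[1]))
        while remaining and len(selected) < self.cap:
            cand_scores = [self._cv_auroc(X, y, selected + [j], folds) for j in remaining]
            k = int(np.argmax(cand_scores))  # first max -> lowest column index
            if cand_scores[k] <= best_score:
                break
            best_score = cand_scores[k]
            selected.append(remaining.pop(k))

        self.selected_ = list(selected)  # in order of addition
        self.score_ = best_score
        support = np.zeros(X.shape[1], dtype=bool)
        support[selected] = True
        self.support_ = support
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_


def forward_select(X, y, estimator, cap: int = 10, inner_folds: int = 3, seed: int = 0):
    """Functional wrapper: returns the ordered list of selected column indices."""
    sel = ForwardFeatureSelector(estimator, cap=cap, inner_folds=inner_folds, random_state=seed)
    sel.fit(np.asarray(X, float), np.asarray(y))
    return sel.selected_
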