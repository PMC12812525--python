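"""Borderline minority oversampling guided by a support-vector boundary.

The minority class is oversampled to parity. Candidate seeds are the
minority-class support vectors of an SVM fitted to the training data (the
points nearest the decision boundary — where synthetic examples matter
most); each synthetic row is a convex combination of a seed and one of its
k nearest minority neighbors, so every generated point lies on a segment
between two real minority rows.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC


class SVMSMOTE(BaseEstimator):
    """SVM-guided SMOTE oversampler with a ``fit_resample`` interface."""

    def __init__(self, k_neighbors: int = 5, random_state: int = 0):
        self.k_neighbors = k_neighbors
        self.random_state = random_state

    def fit_resample(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) != 2:
            raise ValueError(f"SVM-SMOTE needs exactly two classes, got {list(classes)}")
        if counts.min() == counts.max():
            return X.copy(), y.copy()
        minority = classes[np.argmin(counts)]
        n_new = int(counts.max() - counts.min())
        X_min = X[y == minority]
        if len(X_min) < 2:
            raise ValueError("SVM-SMOTE needs at least 2 minority samples")

        rng = np.random.default_rng(self.random_state)
        scaler = StandardScaler().fit(X)
        svc = SVC(kernel="rbf", gamma="scale", C=1.0).fit(scaler.transform(X), y)
        sv_idx = svc.support_[y[svc.support_] == minority]
        seeds = X[sv_idx] if len(sv_idx) else X_min

        k = min(self.k_neighbors, len(X_min) - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
        _, nbrs = nn.kneighbors(seeds)

        synth = np.empty((n_new, X.shape[1]))
        for i in range(n_new):
            s = i % len(seeds)
            j = int(rng.integers(1, k + 1))  # skip self at column 0
            u = float(rng.random())
            neighbor = X_min[nbrs[s, j]]
            synth[i] = seeds[s] + u * (neighbor - seeds[s])

        X_out = np.vstack([X, synth])
        y_out = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
        return X_out, y_out


def svm_smote(X, y, seed: int = 0, k_neighbors: int = 5):
    """Functional wrapper over :class:`SVMSMOTE`."""
    return SVMSMOTE(k_neighbors=k_neighbors, random_state=seed).fit_resample(X, y)
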