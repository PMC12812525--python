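"""Classification metrics, calibration, and the DeLong paired-AUROC test."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score


def evaluate(scores, labels, threshold: float = 0.5) -> dict[str, float]:
    """AUROC (Mann-Whitney, ties half-weighted) and thresholded metrics."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC is undefined with a single class present")
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    return {
        "auroc": float(roc_auc_score(labels, scores)),
        "accuracy": (tp + tn) / len(labels),
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
    }


def calibration_curve(scores, labels, n_bins: int = 10):
    """Equal-width reliability curve on [0, 1]; empty bins are omitted.

    Returns arrays (mean predicted score, observed frequency, count) per
    non-empty bin; counts sum to the sample size.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(scores, edges[1:-1]), 0, n_bins - 1)
    mean_score, observed, count = [], [], []
    for b in range(n_bins):
        m = which == b
        if m.any():
            mean_score.append(scores[m].mean())
            observed.append(labels[m].mean())
            count.append(int(m.sum()))
    return np.asarray(mean_score), np.asarray(observed), np.asarray(count)


@dataclass
class DeLongResult:
    auc1: float
    auc2: float
    difference: float
    variance: float
    z: float
    p_value: float


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Placement values (structural components) of the AUROC estimator."""
    m, n = len(pos), len(neg)
    all_s = np.concatenate([pos, neg])
    rank_all = stats.rankdata(all_s)
    rank_pos = stats.rankdata(pos)
    rank_neg = stats.rankdata(neg)
    v_pos = (rank_all[:m] - rank_pos) / n  # V10: P(score_neg < pos_i) with ties 1/2
    v_neg = 1.0 - (rank_all[m:] - rank_neg) / m  # V01
    auc = float(v_pos.mean())
    return v_pos, v_neg, auc


def delong_test(scores_a, scores_b, labels) -> DeLongResult:
    """Paired comparison of two correlated AUROCs (placement-value covariance).

    Identical scores (zero variance of the difference) yield p = 1 by
    convention.
    """
    scores_a = np.asarray(scores_a, float)
    scores_b = np.asarray(scores_b, float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("DeLong test is undefined with a single class present")
    pos, neg = labels == 1, labels == 0
    m, n = int(pos.sum()), int(neg.sum())

    v10 = np.empty((2, m))
    v01 = np.empty((2, n))
    aucs = np.empty(2)
    for i, s in enumerate((scores_a, scores_b)):
        v10[i], v01[i], aucs[i] = _placements(s[pos], s[neg])

    s10 = np.cov(v10, ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(v01, ddof=1) if n > 1 else np.zeros((2, 2))
    S = s10 / m + s01 / n
    diff = float(aucs[0] - aucs[1])
    var = float(S[0, 0] + S[1, 1] - 2 * S[0, 1])
    if var <= 0:
        z, p = 0.0, 1.0
    else:
        z = diff / np.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return DeLongResult(
        auc1=float(aucs[0]), auc2=float(aucs[1]), difference=diff, variance=var, z=float(z), p_value=p
    )
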