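"""Construction of binary class labels from clinical variables."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

IDH_VOCABULARY = {"wildtype", "mutated", "NOS/NEC", "negative", "unknown"}


def binarize_os(times, dataset: str = "") -> tuple[np.ndarray, np.ndarray]:
    """Median split of overall-survival times within one dataset.

    Returns ``(labels, known_mask)``: label 1 (long-term survivor) iff the
    time is >= the dataset median — a subject exactly at the median counts as
    long-term. Unknown times (NaN) are excluded via the mask and logged.
    """
    t = np.asarray(pd.to_numeric(pd.Series(times), errors="coerce"), dtype=float)
    known = np.isfinite(t)
    if known.sum() < 2:
        raise ValueError(f"dataset {dataset!r}: need >= 2 known survival times")
    if (~known).any():
        logger.info("dataset %s: excluded %d subjects with unknown OS", dataset, int((~known).sum()))
    med = np.median(t[known])
    labels = np.zeros(t.shape, dtype=int)
    labels[known & (t >= med)] = 1
    return labels, known


def binarize_idh(statuses) -> tuple[np.ndarray, np.ndarray]:
    """IDH-wildtype (label 1) against the rest (mutated, NOS/NEC, negative).

    Unknown statuses are excluded via the returned mask; an unrecognized
    status string raises.
    """
    s = pd.Series(statuses, dtype=object)
    bad = set(s.dropna().unique()) - IDH_VOCABULARY
    if bad:
        raise ValueError(f"unrecognized IDH statuses: {sorted(map(str, bad))}")
    known = (~s.isna() & (s != "unknown")).to_numpy()
    if (~known).any():
        logger.info("excluded %d subjects with unknown IDH status", int((~known).sum()))
    labels = (s == "wildtype").astype(int).to_numpy()
    labels[~known] = 0
    return labels, known


def binarize_mgmt(statuses) -> tuple[np.ndarray, np.ndarray]:
    """MGMT promoter methylation: methylated = 1, unmethylated = 0."""
    s = pd.Series(statuses, dtype=object)
    bad = set(s.dropna().unique()) - {"methylated", "unmethylated", "unknown"}
    if bad:
        raise ValueError(f"unrecognized MGMT statuses: {sorted(map(str, bad))}")
    known = (~s.isna() & (s != "unknown")).to_numpy()
    labels = (s == "methylated").astype(int).to_numpy()
    labels[~known] = 0
    return labels, known
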