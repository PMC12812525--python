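"""The spatial distribution pattern: per-structure tumor occupancy ratios.

For a repaired parcellation (``mask_final``) and a GTV mask, each of the 32
canonical structures gets the fraction of its volume overlapped by the tumor:

    ratio(s) = |{x : mask_final(x) = s and GTV(x) > 0}| / |{x : mask_final(x) = s}|

yielding a feature vector of length 32 with every entry in [0, 1]. Structures
absent from the parcellation report ratio 0 and are flagged for QC rather
than emitting missing values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .volumes import CANONICAL_LABELS, GTVMask, LabelVolume, canonical_label_ids, check_aligned

__all__ = [
    "SpatialFeatureVector",
    "structure_volumes",
    "occupancy_ratios",
    "cohort_summary",
    "spatial_feature_names",
]

MM3_PER_LITER = 1e6


def spatial_feature_names() -> list[str]:
    """Column names of the 32-vector, in canonical label order."""
    return [CANONICAL_LABELS[i] for i in canonical_label_ids()]


@dataclass
class SpatialFeatureVector:
    """Ordered 32-vector of occupancy ratios for one subject."""

    ratios: np.ndarray
    subject_id: str = ""
    zero_volume_structures: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ratios = np.asarray(self.ratios, float)
        if self.ratios.shape != (32,):
            raise ValueError(f"spatial feature vector must have length 32, got {self.ratios.shape}")
        if np.any(self.ratios < 0) or np.any(self.ratios > 1):
            raise ValueError("occupancy ratios must lie in [0, 1]")

    def as_series(self) -> pd.Series:
        return pd.Series(self.ratios, index=spatial_feature_names(), name=self.subject_id)


def structure_volumes(labels: LabelVolume, gtv: GTVMask | None = None) -> pd.DataFrame:
    """Physical volume per canonical structure, in liters.

    Returns a DataFrame indexed by structure name with columns ``volume_l``
    and (when a GTV is given) ``overlap_l``, the volume of the structure
    under the tumor. Structures absent from the grid get volume 0.
    """
    labels.validate_dictionary()
    unknown = set(labels.present_labels()) - set(CANONICAL_LABELS)
    if unknown:
        raise ValueError(f"grid contains non-canonical label ids: {sorted(unknown)}")
    if gtv is not None:
        check_aligned(labels, gtv, names=("labels", "gtv"))

    vox_l = labels.voxel_volume_mm3 / MM3_PER_LITER
    ids = canonical_label_ids()
    counts = np.bincount(labels.grid.ravel(), minlength=max(ids) + 1)
    rows = {"volume_l": [counts[i] * vox_l for i in ids]}
    if gtv is not None:
        tumor = gtv.union()
        over = np.bincount(labels.grid[tumor].ravel(), minlength=max(ids) + 1)
        rows["overlap_l"] = [over[i] * vox_l for i in ids]
    return pd.DataFrame(rows, index=[CANONICAL_LABELS[i] for i in ids])


def occupancy_ratios(
    mask_final: LabelVolume,
    gtv: GTVMask,
    subject_id: str = "",
    sub_label: int | None = None,
) -> SpatialFeatureVector:
    """Fraction of each structure's volume occupied by the GTV.

    The canonical feature uses the whole GTV (union of the three
    sub-labels); ``sub_label`` in {1, 2, 3} restricts the overlap to one
    tumor compartment instead. Denominators are structure volumes in the
    repaired parcellation itself. Zero-volume structures yield ratio 0
    (never NaN) and are recorded in ``zero_volume_structures``.
    """
    check_aligned(mask_final, gtv, names=("mask_final", "gtv"))
    if sub_label is not None:
        if sub_label not in (1, 2, 3):
            raise ValueError(f"sub_label must be 1, 2 or 3, got {sub_label}")
        gtv = GTVMask((gtv.grid == sub_label) * np.int16(sub_label), gtv.spacing)
    tab = structure_volumes(mask_final, gtv)
    vol = tab["volume_l"].to_numpy()
    over = tab["overlap_l"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = np.where(vol > 0, over / np.where(vol > 0, vol, 1.0), 0.0)
    zero = [name for name, v in zip(tab.index, vol) if v == 0]
    return SpatialFeatureVector(ratios=ratios, subject_id=subject_id, zero_volume_structures=zero)


def cohort_summary(vectors) -> pd.DataFrame:
    """Per-structure mean and population standard deviation of the ratios."""
    vectors = list(vectors)
    if not vectors:
        raise ValueError("cohort_summary requires at least one subject")
    mat = np.stack([v.ratios for v in vectors])
    return pd.DataFrame(
        {
            "mean": mat.mean(axis=0),
            "sd": mat.std(axis=0),  # population sd
            "n": len(vectors),
        },
        index=spatial_feature_names(),
    )
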