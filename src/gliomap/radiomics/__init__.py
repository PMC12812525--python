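"""Radiomics feature pool: 14 shape + per-sequence (18 first-order + 70
second-order) descriptors = 366 features over four structural sequences."""

from __future__ import annotations

import pandas as pd

from .firstorder import extract_first_order
from .manifest import (
    FIRST_ORDER_FEATURES,
    SEQUENCE_ORDER,
    SHAPE_FEATURES,
    DiscretizationConfig,
    build_manifest,
    second_order_names,
)
from .shape import EmptyROIError, extract_shape
from .texture import extract_second_order
from ..volumes import GTVMask, IntensityVolume

__all__ = [
    "DiscretizationConfig",
    "EmptyROIError",
    "extract_shape",
    "extract_first_order",
    "extract_second_order",
    "assemble_feature_table",
    "build_manifest",
]


def assemble_feature_table(
    sequences: dict[str, IntensityVolume],
    gtv: GTVMask,
    disc: DiscretizationConfig | None = None,
    subject_id: str = "",
) -> tuple[pd.Series, pd.DataFrame]:
    """One 366-long feature row plus the manifest describing every entry.

    Shape features come from the (sequence-invariant) GTV geometry and are
    attributed to T1CE; intensity and texture features are computed per
    sequence in the canonical order T1, T1CE, T2, FLAIR. A missing or
    misaligned sequence is a hard error naming the sequence — no imputation.
    """
    disc = disc or DiscretizationConfig()
    for name in SEQUENCE_ORDER:
        if name not in sequences:
            raise ValueError(f"missing sequence {name!r}")
        if sequences[name].shape != gtv.shape:
            raise ValueError(
                f"sequence {name!r} shape {sequences[name].shape} does not match GTV {gtv.shape}"
            )

    values: dict[str, float] = {}
    for k, v in extract_shape(gtv).items():
        values[f"shape__{k}"] = v
    for name in SEQUENCE_ORDER:
        img = sequences[name]
        for k, v in extract_first_order(img, gtv, disc).items():
            values[f"{name}__firstorder__{k}"] = v
        for k, v in extract_second_order(img, gtv, disc).items():
            values[f"{name}__{k}"] = v

    manifest = build_manifest()
    row = pd.Series([values[n] for n in manifest["feature_name"]],
                    index=manifest["feature_name"].tolist(), name=subject_id)
    return row, manifest
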