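"""Feature vocabulary of the radiomics pool.

The pool is 14 shape descriptors (computed once, on the T1CE-masked ROI),
plus 18 first-order and 70 second-order descriptors per sequence — for the
four structural sequences that is 14 + 4 x 88 = 366 features. The 70
second-order names are fixed here as data (24 co-occurrence, 16 run-length,
16 size-zone, 14 dependence) so the count contract is auditable and the
list swappable without touching the extractors.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

SHAPE_FEATURES = (
    "mesh_volume",
    "voxel_volume",
    "surface_area",
    "surface_volume_ratio",
    "sphericity",
    "maximum_3d_diameter",
    "maximum_2d_diameter_slice",
    "maximum_2d_diameter_column",
    "maximum_2d_diameter_row",
    "major_axis_length",
    "minor_axis_length",
    "least_axis_length",
    "elongation",
    "flatness",
)

FIRST_ORDER_FEATURES = (
    "mean",
    "variance",
    "skewness",
    "kurtosis",
    "median",
    "minimum",
    "percentile_10",
    "percentile_90",
    "maximum",
    "interquartile_range",
    "range",
    "mean_absolute_deviation",
    "robust_mean_absolute_deviation",
    "energy",
    "total_energy",
    "root_mean_squared",
    "entropy",
    "uniformity",
)

GLCM_FEATURES = (
    "autocorrelation",
    "cluster_prominence",
    "cluster_shade",
    "cluster_tendency",
    "contrast",
    "correlation",
    "difference_average",
    "difference_entropy",
    "difference_variance",
    "inverse_difference",
    "inverse_difference_moment",
    "inverse_difference_moment_normalized",
    "inverse_difference_normalized",
    "informational_measure_correlation_1",
    "informational_measure_correlation_2",
    "inverse_variance",
    "joint_average",
    "joint_energy",
    "joint_entropy",
    "maximal_correlation_coefficient",
    "maximum_probability",
    "sum_average",
    "sum_entropy",
    "sum_squares",
)

GLRLM_FEATURES = (
    "short_run_emphasis",
    "long_run_emphasis",
    "gray_level_non_uniformity",
    "gray_level_non_uniformity_normalized",
    "run_length_non_uniformity",
    "run_length_non_uniformity_normalized",
    "run_percentage",
    "gray_level_variance",
    "run_variance",
    "run_entropy",
    "low_gray_level_run_emphasis",
    "high_gray_level_run_emphasis",
    "short_run_low_gray_level_emphasis",
    "short_run_high_gray_level_emphasis",
    "long_run_low_gray_level_emphasis",
    "long_run_high_gray_level_emphasis",
)

GLSZM_FEATURES = (
    "small_area_emphasis",
    "large_area_emphasis",
    "gray_level_non_uniformity",
    "gray_level_non_uniformity_normalized",
    "size_zone_non_uniformity",
    "size_zone_non_uniformity_normalized",
    "zone_percentage",
    "gray_level_variance",
    "zone_variance",
    "zone_entropy",
    "low_gray_level_zone_emphasis",
    "high_gray_level_zone_emphasis",
    "small_area_low_gray_level_emphasis",
    "small_area_high_gray_level_emphasis",
    "large_area_low_gray_level_emphasis",
    "large_area_high_gray_level_emphasis",
)

GLDM_FEATURES = (
    "small_dependence_emphasis",
    "large_dependence_emphasis",
    "gray_level_non_uniformity",
    "dependence_non_uniformity",
    "dependence_non_uniformity_normalized",
    "gray_level_variance",
    "dependence_variance",
    "dependence_entropy",
    "low_gray_level_emphasis",
    "high_gray_level_emphasis",
    "small_dependence_low_gray_level_emphasis",
    "small_dependence_high_gray_level_emphasis",
    "large_dependence_low_gray_level_emphasis",
    "large_dependence_high_gray_level_emphasis",
)

SECOND_ORDER_FAMILIES = (
    ("glcm", GLCM_FEATURES),
    ("glrlm", GLRLM_FEATURES),
    ("glszm", GLSZM_FEATURES),
    ("gldm", GLDM_FEATURES),
)

SEQUENCE_ORDER = ("T1", "T1CE", "T2", "FLAIR")


@dataclass
class DiscretizationConfig:
    """Gray-level discretization of ROI intensities before texture analysis."""

    mode: str = "fixed_bin_count"
    value: float = 32
    resegment_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("fixed_bin_count", "fixed_bin_width"):
            raise ValueError(f"unknown discretization mode {self.mode!r}")
        if self.value <= 0:
            raise ValueError("discretization value must be > 0")


def second_order_names() -> list[str]:
    return [f"{fam}__{name}" for fam, names in SECOND_ORDER_FAMILIES for name in names]


def build_manifest() -> pd.DataFrame:
    """Canonical 366-row manifest: (feature_name, family, source_sequence)."""
    rows = [(f"shape__{n}", "shape", "T1CE") for n in SHAPE_FEATURES]
    for seq in SEQUENCE_ORDER:
        rows += [(f"{seq}__firstorder__{n}", "first_order", seq) for n in FIRST_ORDER_FEATURES]
        rows += [(f"{seq}__{n}", "second_order", seq) for n in second_order_names()]
    return pd.DataFrame(rows, columns=["feature_name", "family", "source_sequence"])
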