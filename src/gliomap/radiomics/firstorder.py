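"""First-order intensity statistics over the ROI.

Entropy and uniformity are computed on the discretized gray-level histogram
(same discretization the texture features use); everything else operates on
raw intensities. Degenerate (constant) ROIs yield zero dispersion, zero
skewness/kurtosis and zero entropy rather than NaNs.
"""

from __future__ import annotations

import numpy as np

from .manifest import FIRST_ORDER_FEATURES, DiscretizationConfig
from .shape import EmptyROIError
from ..volumes import GTVMask, IntensityVolume


def discretize(values: np.ndarray, disc: DiscretizationConfig) -> np.ndarray:
    """Map ROI intensities to gray levels 1..Ng."""
    if disc.resegment_range is not None:
        lo, hi = disc.resegment_range
        values = values[(values >= lo) & (values <= hi)]
    if values.size == 0:
        raise EmptyROIError("discretization left an empty ROI")
    if disc.mode == "fixed_bin_count":
        n = int(disc.value)
        lo, hi = values.min(), values.max()
        if hi == lo:
            return np.ones(values.shape, dtype=np.int64)
        lev = np.floor((values - lo) / (hi - lo) * n).astype(np.int64) + 1
        return np.clip(lev, 1, n)
    w = float(disc.value)
    return (np.floor(values / w) - np.floor(values.min() / w)).astype(np.int64) + 1


def extract_first_order(
    image: IntensityVolume,
    gtv: GTVMask,
    disc: DiscretizationConfig | None = None,
) -> dict[str, float]:
    """The 18 first-order descriptors (order per manifest)."""
    disc = disc or DiscretizationConfig()
    mask = gtv.union()
    if image.shape != gtv.shape:
        raise ValueError(f"image shape {image.shape} != GTV shape {gtv.shape}")
    if not mask.any():
        raise EmptyROIError("first-order features require a non-empty ROI")
    x = image.grid[mask].astype(float)
    n = x.size
    voxel_volume = float(np.prod(image.spacing))

    mean = x.mean()
    var = x.var()  # population variance
    sd = np.sqrt(var)
    p10, q1, med, q3, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    if sd > 0:
        skew = float(((x - mean) ** 3).mean() / sd**3)
        kurt = float(((x - mean) ** 4).mean() / var**2)  # non-excess (normal -> 3)
    else:
        skew, kurt = 0.0, 0.0
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0

    levels = discretize(x, disc)
    p = np.bincount(levels)[1:].astype(float)
    p = p[p > 0] / n
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p**2).sum())

    values = {
        "mean": mean,
        "variance": var,
        "skewness": skew,
        "kurtosis": kurt,
        "median": med,
        "minimum": x.min(),
        "percentile_10": p10,
        "percentile_90": p90,
        "maximum": x.max(),
        "interquartile_range": q3 - q1,
        "range": x.max() - x.min(),
        "mean_absolute_deviation": np.abs(x - mean).mean(),
        "robust_mean_absolute_deviation": rmad,
        "energy": (x**2).sum(),
        "total_energy": voxel_volume * (x**2).sum(),
        "root_mean_squared": np.sqrt((x**2).mean()),
        "entropy": entropy,
        "uniformity": uniformity,
    }
    return {name: float(values[name]) for name in FIRST_ORDER_FEATURES}
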