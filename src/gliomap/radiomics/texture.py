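"""Second-order (texture) descriptors: co-occurrence, run-length, size-zone
and dependence statistics on the discretized ROI.

Direction-dependent families (co-occurrence, run-length) use the 13 unique
3D offsets at distance 1 and average the feature value over directions.
Size zones use 26-connectivity; dependence counts equal-level 26-neighbors.
Degenerate single-level ROIs are well-defined throughout (entropies 0,
correlation-type quantities 1 by convention).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .firstorder import discretize
from .manifest import (
    GLCM_FEATURES,
    GLDM_FEATURES,
    GLRLM_FEATURES,
    GLSZM_FEATURES,
    DiscretizationConfig,
)
from .shape import EmptyROIError
from ..volumes import GTVMask, IntensityVolume

# the 13 unique direction offsets of a 26-neighborhood (one per +/- pair)
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (di, dj, dk)
    for di in (-1, 0, 1)
    for dj in (-1, 0, 1)
    for dk in (-1, 0, 1)
    if (di, dj, dk) > (0, 0, 0)
)

_EPS = np.finfo(float).eps


def discretized_roi(image: IntensityVolume, gtv: GTVMask, disc: DiscretizationConfig):
    """Gray-level array (0 outside ROI, 1..Ng inside) and the level count."""
    mask = gtv.union()
    if not mask.any():
        raise EmptyROIError("texture features require a non-empty ROI")
    if image.shape != gtv.shape:
        raise ValueError(f"image shape {image.shape} != GTV shape {gtv.shape}")
    levels = discretize(image.grid[mask], disc)
    arr = np.zeros(image.shape, dtype=np.int64)
    arr[mask] = levels
    return arr, int(levels.max())


# ---------------------------------------------------------------------------
# Gray-level co-occurrence
# ---------------------------------------------------------------------------

def glcm_matrix(arr: np.ndarray, offset: tuple[int, int, int], n_levels: int) -> np.ndarray:
    """Symmetric, normalized co-occurrence matrix for one offset.

    Counts pairs (arr[x], arr[x + offset]) with both voxels inside the ROI.
    Returns the (Ng, Ng) matrix; all-zero if the offset yields no pairs.
    """
    src = [slice(max(0, -o), arr.shape[a] - max(0, o)) for a, o in enumerate(offset)]
    dst = [slice(max(0, o), arr.shape[a] + min(0, o)) for a, o in enumerate(offset)]
    a, b = arr[tuple(src)], arr[tuple(dst)]
    ok = (a > 0) & (b > 0)
    if not ok.any():
        return np.zeros((n_levels, n_levels))
    pairs = np.bincount((a[ok] - 1) * n_levels + (b[ok] - 1), minlength=n_levels * n_levels)
    P = pairs.reshape(n_levels, n_levels).astype(float)
    P = P + P.T
    return P / P.sum()


def _glcm_features_single(P: np.ndarray) -> dict[str, float]:
    ng = P.shape[0]
    i = np.arange(1, ng + 1)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    mu = float((i * px).sum())
    sigma2 = float(((i - mu) ** 2 * px).sum())

    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.array([P[I + J == k].sum() for k in k_sum])
    k_diff = np.arange(0, ng)
    p_diff = np.array([P[np.abs(I - J) == k].sum() for k in k_diff])

    def ent(p):
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum())

    HXY = ent(P.ravel())
    pxpy = np.outer(px, px)
    nz = P > 0
    HXY1 = float(-(P[nz] * np.log2(pxpy[nz] + _EPS)).sum())
    nz2 = pxpy > 0
    HXY2 = float(-(pxpy[nz2] * np.log2(pxpy[nz2])).sum())
    HX = ent(px)

    da = float((k_diff * p_diff).sum())
    corr = 1.0 if sigma2 <= _EPS else float(((I * J * P).sum() - mu * mu) / sigma2)
    imc1 = 0.0 if HX <= _EPS else (HXY - HXY1) / HX
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (HXY2 - HXY)))))

    # maximal correlation coefficient: sqrt of 2nd largest eigenvalue of Q
    if ng < 2:
        mcc = 1.0
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            Q = np.einsum("ik,jk->ij", P / np.maximum(px[:, None], _EPS), P / np.maximum(px[None, :], _EPS))
        ev = np.sort(np.abs(np.linalg.eigvals(Q)).real)
        mcc = float(np.sqrt(np.clip(ev[-2], 0, 1)))

    off = I - J
    vals = {
        "autocorrelation": (I * J * P).sum(),
        "cluster_prominence": (((I + J - 2 * mu) ** 4) * P).sum(),
        "cluster_shade": (((I + J - 2 * mu) ** 3) * P).sum(),
        "cluster_tendency": (((I + J - 2 * mu) ** 2) * P).sum(),
        "contrast": ((off**2) * P).sum(),
        "correlation": corr,
        "difference_average": da,
        "difference_entropy": ent(p_diff),
        "difference_variance": (((k_diff - da) ** 2) * p_diff).sum(),
        "inverse_difference": (P / (1.0 + np.abs(off))).sum(),
        "inverse_difference_moment": (P / (1.0 + off**2)).sum(),
        "inverse_difference_moment_normalized": (P / (1.0 + (off / ng) ** 2)).sum(),
        "inverse_difference_normalized": (P / (1.0 + np.abs(off) / ng)).sum(),
        "informational_measure_correlation_1": imc1,
        "informational_measure_correlation_2": imc2,
        "inverse_variance": (P[off != 0] / (off[off != 0] ** 2)).sum(),
        "joint_average": mu,
        "joint_energy": (P**2).sum(),
        "joint_entropy": HXY,
        "maximal_correlation_coefficient": mcc,
        "maximum_probability": P.max(),
        "sum_average": (k_sum * p_sum).sum(),
        "sum_entropy": ent(p_sum),
        "sum_squares": sigma2,
    }
    return {k: float(v) for k, v in vals.items()}


def glcm_features(arr: np.ndarray, n_levels: int) -> dict[str, float]:
    """Co-occurrence features averaged over the 13 directions."""
    per_dir = []
    for off in DIRECTIONS_13:
        P = glcm_matrix(arr, off, n_levels)
        if P.sum() > 0:
            per_dir.append(_glcm_features_single(P))
    if not per_dir:  # single-voxel ROI: no pairs in any direction
        per_dir = [_glcm_features_single(np.ones((1, 1)))]
    return {name: float(np.mean([d[name] for d in per_dir])) for name in GLCM_FEATURES}


# ---------------------------------------------------------------------------
# Gray-level run length
# ---------------------------------------------------------------------------

def glrlm_matrix(arr: np.ndarray, offset: tuple[int, int, int], n_levels: int) -> np.ndarray:
    """Run-length matrix P(g, l) for one direction; ROI gaps break runs."""
    shape = np.asarray(arr.shape)
    off = np.asarray(offset)
    inside = arr > 0

    prev = np.zeros_like(inside)
    src = [slice(max(0, o), arr.shape[a] + min(0, o)) for a, o in enumerate(offset)]
    dst = [slice(max(0, -o), arr.shape[a] - max(0, o)) for a, o in enumerate(offset)]
    # prev[x] True if x - offset is in-ROI with the same level
    prev[tuple(src)] = (arr[tuple(src)] == arr[tuple(dst)]) & (arr[tuple(dst)] > 0)
    starts = np.argwhere(inside & ~prev)

    max_run = int(np.abs(shape).max())
    counts = np.zeros((n_levels, max_run), dtype=np.int64)
    for s in starts:
        g = arr[tuple(s)]
        length = 1
        p = s + off
        while np.all((p >= 0) & (p < shape)) and arr[tuple(p)] == g:
            length += 1
            p = p + off
        counts[g - 1, length - 1] += 1
    last = max(1, int(np.argwhere(counts.sum(axis=0) > 0).max()) + 1) if counts.any() else 1
    return counts[:, :last].astype(float)


def _weighted_stats(P: np.ndarray):
    """Shared machinery of the run/zone/dependence families."""
    N = P.sum()
    p = P / N
    g = np.arange(1, P.shape[0] + 1, dtype=float)
    l = np.arange(1, P.shape[1] + 1, dtype=float)
    G, L = np.meshgrid(g, l, indexing="ij")
    sg = P.sum(axis=1)
    sl = P.sum(axis=0)
    mu_g = (p * G).sum()
    mu_l = (p * L).sum()
    pz = p[p > 0]
    return dict(
        N=N, p=p, G=G, L=L, sg=sg, sl=sl,
        small=(p / L**2).sum(), large=(p * L**2).sum(),
        gln=(sg**2).sum() / N, glnn=(sg**2).sum() / N**2,
        lln=(sl**2).sum() / N, llnn=(sl**2).sum() / N**2,
        glv=(p * (G - mu_g) ** 2).sum(), lv=(p * (L - mu_l) ** 2).sum(),
        entropy=float(-(pz * np.log2(pz)).sum()),
        lgl=(p / G**2).sum(), hgl=(p * G**2).sum(),
        sl_lg=(p / (G**2 * L**2)).sum(), sl_hg=(p * G**2 / L**2).sum(),
        ll_lg=(p * L**2 / G**2).sum(), ll_hg=(p * G**2 * L**2).sum(),
    )


def _rlm_features_single(P: np.ndarray, n_roi_voxels: int) -> dict[str, float]:
    w = _weighted_stats(P)
    vals = {
        "short_run_emphasis": w["small"],
        "long_run_emphasis": w["large"],
        "gray_level_non_uniformity": w["gln"],
        "gray_level_non_uniformity_normalized": w["glnn"],
        "run_length_non_uniformity": w["lln"],
        "run_length_non_uniformity_normalized": w["llnn"],
        "run_percentage": w["N"] / n_roi_voxels,
        "gray_level_variance": w["glv"],
        "run_variance": w["lv"],
        "run_entropy": w["entropy"],
        "low_gray_level_run_emphasis": w["lgl"],
        "high_gray_level_run_emphasis": w["hgl"],
        "short_run_low_gray_level_emphasis": w["sl_lg"],
        "short_run_high_gray_level_emphasis": w["sl_hg"],
        "long_run_low_gray_level_emphasis": w["ll_lg"],
        "long_run_high_gray_level_emphasis": w["ll_hg"],
    }
    return {k: float(v) for k, v in vals.items()}


def glrlm_features(arr: np.ndarray, n_levels: int) -> dict[str, float]:
    """Run-length features averaged over the 13 directions."""
    n_vox = int((arr > 0).sum())
    per_dir = [
        _rlm_features_single(glrlm_matrix(arr, off, n_levels), n_vox) for off in DIRECTIONS_13
    ]
    return {name: float(np.mean([d[name] for d in per_dir])) for name in GLRLM_FEATURES}


# ---------------------------------------------------------------------------
# Gray-level size zone
# ---------------------------------------------------------------------------

def glszm_matrix(arr: np.ndarray, n_levels: int) -> np.ndarray:
    """Size-zone matrix P(g, s): 26-connected same-level zones."""
    structure = np.ones((3, 3, 3), dtype=int)
    zones: list[tuple[int, int]] = []
    for g in range(1, n_levels + 1):
        lab, n = ndimage.label(arr == g, structure=structure)
        if n:
            sizes = np.bincount(lab.ravel())[1:]
            zones += [(g, int(s)) for s in sizes]
    max_s = max(s for _, s in zones)
    P = np.zeros((n_levels, max_s))
    for g, s in zones:
        P[g - 1, s - 1] += 1
    return P


def glszm_features(arr: np.ndarray, n_levels: int) -> dict[str, float]:
    P = glszm_matrix(arr, n_levels)
    w = _weighted_stats(P)
    n_vox = int((arr > 0).sum())
    vals = {
        "small_area_emphasis": w["small"],
        "large_area_emphasis": w["large"],
        "gray_level_non_uniformity": w["gln"],
        "gray_level_non_uniformity_normalized": w["glnn"],
        "size_zone_non_uniformity": w["lln"],
        "size_zone_non_uniformity_normalized": w["llnn"],
        "zone_percentage": w["N"] / n_vox,
        "gray_level_variance": w["glv"],
        "zone_variance": w["lv"],
        "zone_entropy": w["entropy"],
        "low_gray_level_zone_emphasis": w["lgl"],
        "high_gray_level_zone_emphasis": w["hgl"],
        "small_area_low_gray_level_emphasis": w["sl_lg"],
        "small_area_high_gray_level_emphasis": w["sl_hg"],
        "large_area_low_gray_level_emphasis": w["ll_lg"],
        "large_area_high_gray_level_emphasis": w["ll_hg"],
    }
    return {k: float(v) for k, v in vals.items()}


# ---------------------------------------------------------------------------
# Gray-level dependence
# ---------------------------------------------------------------------------

def gldm_matrix(arr: np.ndarray, n_levels: int) -> np.ndarray:
    """Dependence matrix P(g, k): k = 1 + #equal-level 26-neighbors."""
    inside = arr > 0
    dep = np.zeros(arr.shape, dtype=np.int64)
    for off in DIRECTIONS_13:
        for sign in (1, -1):
            o = tuple(sign * c for c in off)
            src = [slice(max(0, -c), arr.shape[a] - max(0, c)) for a, c in enumerate(o)]
            dst = [slice(max(0, c), arr.shape[a] + min(0, c)) for a, c in enumerate(o)]
            eq = (arr[tuple(src)] == arr[tuple(dst)]) & (arr[tuple(dst)] > 0)
            dep[tuple(src)] += eq
    ks = dep[inside] + 1
    gs = arr[inside]
    P = np.zeros((n_levels, int(ks.max())))
    np.add.at(P, (gs - 1, ks - 1), 1.0)
    return P


def gldm_features(arr: np.ndarray, n_levels: int) -> dict[str, float]:
    P = gldm_matrix(arr, n_levels)
    w = _weighted_stats(P)
    vals = {
        "small_dependence_emphasis": w["small"],
        "large_dependence_emphasis": w["large"],
        "gray_level_non_uniformity": w["gln"],
        "dependence_non_uniformity": w["lln"],
        "dependence_non_uniformity_normalized": w["llnn"],
        "gray_level_variance": w["glv"],
        "dependence_variance": w["lv"],
        "dependence_entropy": w["entropy"],
        "low_gray_level_emphasis": w["lgl"],
        "high_gray_level_emphasis": w["hgl"],
        "small_dependence_low_gray_level_emphasis": w["sl_lg"],
        "small_dependence_high_gray_level_emphasis": w["sl_hg"],
        "large_dependence_low_gray_level_emphasis": w["ll_lg"],
        "large_dependence_high_gray_level_emphasis": w["ll_hg"],
    }
    return {k: float(v) for k, v in vals.items()}


def extract_second_order(
    image: IntensityVolume,
    gtv: GTVMask,
    disc: DiscretizationConfig | None = None,
) -> dict[str, float]:
    """All 70 second-order descriptors, keyed ``family__feature``."""
    disc = disc or DiscretizationConfig()
    arr, n_levels = discretized_roi(image, gtv, disc)
    out: dict[str, float] = {}
    out.update({f"glcm__{k}": v for k, v in glcm_features(arr, n_levels).items()})
    out.update({f"glrlm__{k}": v for k, v in glrlm_features(arr, n_levels).items()})
    out.update({f"glszm__{k}": v for k, v in glszm_features(arr, n_levels).items()})
    out.update({f"gldm__{k}": v for k, v in gldm_features(arr, n_levels).items()})
    return out
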