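"""Tumor-aware parcellation repair.

A whole-brain segmenter fails on and around a glioma. This module repairs
the failed region by atlas label propagation: the tumor is masked out of both
the subject segmentation and a rigidly pre-aligned parcellated atlas, a
deformable registration is estimated with the tumor excluded from the
similarity term (cost-function masking), and the *inverse* of that field
warps the full atlas labels back into subject space. The composed result
(``mask_final``) carries anatomical labels inside the tumor.

The deformable step is a multi-resolution demons registration on smoothed
label-embedding channels; the similarity force is zeroed under the ignore
mask so the field inside the tumor is purely the smooth continuation of the
field estimated from surrounding anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .volumes import DeformationField, GTVMask, LabelVolume, check_aligned

__all__ = [
    "RigidTransform",
    "RegistrationResult",
    "ParcellationCase",
    "RepairConfig",
    "mask_out_tumor",
    "rigid_register",
    "deformable_register",
    "invert_field",
    "warp_labels",
    "fill_tumor_labels",
]


class RegistrationError(RuntimeError):
    pass


class InversionError(RuntimeError):
    def __init__(self, msg: str, achieved_residual_vox: float):
        super().__init__(msg)
        self.achieved_residual_vox = achieved_residual_vox


@dataclass
class RigidTransform:
    """Maps fixed-space physical points to moving space: x -> R x + t (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, float).reshape(3, 3)
        self.translation = np.asarray(self.translation, float).reshape(3)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-3:
            raise ValueError("rotation must be a proper rotation (det = +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation

    def is_identity(self, tol: float = 1e-9) -> bool:
        return (
            np.allclose(self.rotation, np.eye(3), atol=tol)
            and np.allclose(self.translation, 0, atol=tol)
        )


@dataclass
class RegistrationResult:
    transform: object
    similarity_trace: list[float]
    converged: bool


@dataclass
class ParcellationCase:
    """Inputs, intermediate transforms and output of one repair run."""

    subject_seg: LabelVolume
    atlas_seg: LabelVolume
    gtv: GTVMask
    mask_final: LabelVolume
    rigid: RigidTransform
    field: DeformationField | None
    deformable_result: RegistrationResult | None = None


@dataclass
class RepairConfig:
    """Knobs of the repair pipeline.

    compose_mode "composite" keeps the subject's own labels outside the GTV
    and uses warped-atlas labels inside it; "full_warp" takes the warped
    atlas everywhere.

    ``ignore_dilation_mm`` grows the similarity-exclusion mask beyond the GTV
    during the deformable step: segmenter failures extend *around* the tumor,
    not just inside it, so labels in a rind outside the delineated GTV are
    untrustworthy and would mislead the registration if scored.
    """

    compose_mode: str = "composite"
    ignore_dilation_mm: float = 6.0
    demons_iterations: tuple[int, ...] = (60, 40, 20)
    demons_levels: tuple[int, ...] = (4, 2, 1)
    sigma_fluid_vox: float = 1.0
    sigma_elastic_vox: float = 1.0
    step: float = 2.0
    channel_sigma_vox: float = 1.0
    n_channels: int = 8
    do_rigid: bool = True

    def __post_init__(self) -> None:
        if self.compose_mode not in ("composite", "full_warp"):
            raise ValueError(f"unknown compose_mode {self.compose_mode!r}")


# ---------------------------------------------------------------------------
# Masking
# ---------------------------------------------------------------------------

def mask_out_tumor(seg: LabelVolume, gtv: GTVMask) -> LabelVolume:
    """Zero every voxel under the GTV (union of all three sub-labels)."""
    check_aligned(seg, gtv, names=("seg", "gtv"))
    out = seg.grid.copy()
    out[gtv.union()] = 0
    return LabelVolume(grid=out, spacing=seg.spacing, label_dict=dict(seg.label_dict))


# ---------------------------------------------------------------------------
# Rigid registration (SimpleITK backend on signed distance maps)
# ---------------------------------------------------------------------------

def _to_sitk(arr: np.ndarray, spacing) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in spacing))
    return img


def _foreground_sdm(vol: LabelVolume) -> np.ndarray:
    fg = vol.grid > 0
    inside = ndimage.distance_transform_edt(fg, sampling=vol.spacing)
    outside = ndimage.distance_transform_edt(~fg, sampling=vol.spacing)
    return (outside - inside).astype(np.float32)


def _mean_label_dice(a: np.ndarray, b: np.ndarray) -> float:
    labs = np.union1d(np.unique(a), np.unique(b))
    labs = labs[labs != 0]
    scores = []
    for lab in labs:
        ma, mb = a == lab, b == lab
        denom = ma.sum() + mb.sum()
        if denom:
            scores.append(2.0 * np.logical_and(ma, mb).sum() / denom)
    return float(np.mean(scores)) if scores else 0.0


def rigid_register(moving: LabelVolume, fixed: LabelVolume) -> RigidTransform:
    """Rigidly align ``moving`` to ``fixed`` on foreground signed-distance maps.

    Falls back to the identity if the recovered transform does not improve
    mean per-label Dice over no transform at all.
    """
    if not (moving.grid > 0).any() or not (fixed.grid > 0).any():
        raise RegistrationError("rigid_register requires non-empty foregrounds")
    check_aligned(moving, fixed, names=("moving", "fixed"))

    f_img = _to_sitk(_foreground_sdm(fixed), fixed.spacing)
    m_img = _to_sitk(_foreground_sdm(moving), moving.spacing)

    tx0 = sitk.CenteredTransformInitializer(
        f_img, m_img, sitk.Euler3DTransform(), sitk.CenteredTransformInitializerFilter.MOMENTS
    )
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    reg.SetMetricSamplingStrategy(reg.NONE)  # full sampling -> deterministic
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-4, numberOfIterations=100, relaxationFactor=0.6
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
    reg.SetInitialTransform(tx0, inPlace=True)
    tx = sitk.Euler3DTransform(reg.Execute(f_img, m_img))

    R = np.asarray(tx.GetMatrix()).reshape(3, 3)
    c = np.asarray(tx.GetCenter())
    t = np.asarray(tx.GetTranslation())
    rigid = RigidTransform(rotation=R, translation=R @ (-c) + c + t)

    # monotonicity guard: never worse than identity
    before = _mean_label_dice(moving.grid, fixed.grid)
    after = _mean_label_dice(warp_labels(moving, rigid=rigid).grid, fixed.grid)
    if after < before:
        return RigidTransform.identity()
    return rigid


# ---------------------------------------------------------------------------
# Masked demons deformable registration
# ---------------------------------------------------------------------------

_EMBED_SEED = 20240001


def _embed_channels(grid: np.ndarray, labels: np.ndarray, n_channels: int, sigma: float) -> np.ndarray:
    """Smoothed random-embedding encoding of a label map, shape (C, *grid)."""
    rng = np.random.default_rng(_EMBED_SEED)
    codes = rng.standard_normal((labels.max() + 1, n_channels))
    codes /= np.linalg.norm(codes, axis=1, keepdims=True)
    codes[0] = 0.0  # background
    chan = codes[grid].transpose(3, 0, 1, 2).astype(np.float32)
    if sigma > 0:
        for c in range(chan.shape[0]):
            chan[c] = ndimage.gaussian_filter(chan[c], sigma=sigma)
    return chan


def _downsample(arr: np.ndarray, f: int) -> np.ndarray:
    if f == 1:
        return arr
    return ndimage.gaussian_filter(arr, sigma=f / 2.0)[::f, ::f, ::f]


def _warp_channel(chan: np.ndarray, coords: np.ndarray) -> np.ndarray:
    return ndimage.map_coordinates(chan, coords, order=1, mode="nearest")


def deformable_register(
    moving: LabelVolume,
    fixed: LabelVolume,
    ignore: np.ndarray | None = None,
    config: RepairConfig | None = None,
) -> tuple[DeformationField, RegistrationResult]:
    """Estimate a dense field u with moving(x + u(x)) ~ fixed(x).

    ``ignore`` is a boolean mask on the fixed grid; voxels under it are
    excluded from the similarity force, so the field there is driven only by
    the smoothness regularizer (cost-function masking). The returned
    DeformationField stores mm displacements on the fixed grid and its
    fixed-point inverse.
    """
    cfg = config or RepairConfig()
    check_aligned(moving, fixed, names=("moving", "fixed"))
    shape = fixed.shape
    spacing = np.asarray(fixed.spacing, float)
    if ignore is None:
        ignore = np.zeros(shape, bool)
    ignore = np.asarray(ignore, bool)
    if ignore.shape != shape:
        raise ValueError(f"ignore mask shape {ignore.shape} != fixed shape {shape}")

    all_labels = np.union1d(np.unique(moving.grid), np.unique(fixed.grid))
    Fch0 = _embed_channels(fixed.grid, all_labels, cfg.n_channels, cfg.channel_sigma_vox)
    Mch0 = _embed_channels(moving.grid, all_labels, cfg.n_channels, cfg.channel_sigma_vox)

    trace: list[float] = []
    u = None  # voxel-unit displacement, shape (3, *level_shape)
    for level, n_iter in zip(cfg.demons_levels, cfg.demons_iterations):
        Fch = np.stack([_downsample(c, level) for c in Fch0])
        Mch = np.stack([_downsample(c, level) for c in Mch0])
        ign = _downsample(ignore.astype(np.float32), level) > 0.25
        lshape = Fch.shape[1:]

        if u is None:
            u = np.zeros((3,) + lshape, dtype=np.float32)
        else:
            zf = np.asarray(lshape) / np.asarray(u.shape[1:])
            u = np.stack(
                [ndimage.zoom(u[a], zf, order=1) * zf[a] for a in range(3)]
            ).astype(np.float32)
            # zoom may be off by a voxel; force exact shape
            u = np.stack([_fit_shape(u[a], lshape) for a in range(3)])

        gF = np.stack([np.stack(np.gradient(Fch[c]), axis=0) for c in range(len(Fch))])
        gnorm2 = (gF**2).sum(axis=(0, 1))  # sum over channels and axes
        idx = np.stack(
            np.meshgrid(*[np.arange(n, dtype=np.float32) for n in lshape], indexing="ij")
        )

        for _ in range(n_iter):
            coords = idx + u
            D = np.stack([Fch[c] - _warp_channel(Mch[c], coords) for c in range(len(Fch))])
            D[:, ign] = 0.0
            d2 = (D**2).sum(axis=0)
            trace.append(float(d2[~ign].mean()) if (~ign).any() else 0.0)
            den = gnorm2 + d2 + 1e-8
            v = np.einsum("c...,ca...->a...", D, gF) / den
            mag = np.sqrt((v**2).sum(axis=0))
            np.minimum(1.0, 1.0 / np.maximum(mag, 1e-8), out=mag)  # cap |v| at 1 voxel
            v *= mag
            for a in range(3):
                v[a] = ndimage.gaussian_filter(v[a], cfg.sigma_fluid_vox)
            u = u + cfg.step * v
            for a in range(3):
                u[a] = ndimage.gaussian_filter(u[a], cfg.sigma_elastic_vox)

    disp_mm = np.moveaxis(u.astype(float), 0, -1) * spacing
    fld = DeformationField(displacements=disp_mm, spacing=tuple(fixed.spacing))
    fld = invert_field(fld, store_forward_as_inverse=True, strict=False)

    n = len(trace)
    tail = trace[max(0, int(0.75 * n)) :]
    converged = bool(n >= 2 and tail[-1] <= tail[0] + 1e-12)
    return fld, RegistrationResult(transform=fld, similarity_trace=trace, converged=converged)


def _fit_shape(arr: np.ndarray, shape) -> np.ndarray:
    out = np.zeros(shape, dtype=arr.dtype)
    sl = tuple(slice(0, min(a, b)) for a, b in zip(arr.shape, shape))
    out[sl] = arr[sl]
    return out


# ---------------------------------------------------------------------------
# Field inversion
# ---------------------------------------------------------------------------

def invert_field(
    fld: DeformationField,
    max_iter: int = 50,
    tol_vox: float = 0.5,
    strict: bool = True,
    store_forward_as_inverse: bool = False,
) -> DeformationField:
    """Fixed-point inverse: find v with v(y) + u(y + v(y)) = 0.

    The composition residual (forward after inverse, in voxels) must fall
    below ``tol_vox`` at 99% of voxels; with ``strict`` an InversionError
    reporting the achieved residual is raised otherwise.
    """
    u = fld.displacements
    spacing = np.asarray(fld.spacing, float)
    shape = u.shape[:3]
    idx = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1).astype(float)

    def sample_u(at_vox: np.ndarray) -> np.ndarray:
        return np.stack(
            [
                ndimage.map_coordinates(u[..., c], np.moveaxis(at_vox, -1, 0), order=1, mode="nearest")
                for c in range(3)
            ],
            axis=-1,
        )

    v = np.zeros_like(u)
    for _ in range(max_iter):
        new_v = -sample_u(idx + v / spacing)
        if np.abs(new_v - v).max() / spacing.min() < 0.01:
            v = new_v
            break
        v = new_v

    residual = np.linalg.norm((v + sample_u(idx + v / spacing)) / spacing, axis=-1)
    p99 = float(np.percentile(residual, 99))
    if strict and p99 >= tol_vox:
        raise InversionError(
            f"field inversion residual p99 = {p99:.3f} voxels (tolerance {tol_vox})", p99
        )
    if store_forward_as_inverse:
        # caller asked for u with its inverse attached
        out = DeformationField(displacements=u, spacing=fld.spacing, inverse=v)
    else:
        out = DeformationField(displacements=v, spacing=fld.spacing, inverse=u.copy())
    out.inversion_residual_p99_vox = p99  # type: ignore[attr-defined]
    return out


# ---------------------------------------------------------------------------
# Label warping
# ---------------------------------------------------------------------------

def warp_labels(
    labels: LabelVolume,
    rigid: RigidTransform | None = None,
    fld: DeformationField | None = None,
) -> LabelVolume:
    """Resample a label map through (deformable then rigid) transforms.

    out[y] = labels(R (y·spacing + v(y)) + t), nearest-neighbor only; voxels
    mapping outside the grid become background. Exact half-voxel ties round
    toward the origin for cross-platform stability.
    """
    spacing = np.asarray(labels.spacing, float)
    shape = labels.shape
    pts = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1) * spacing
    if fld is not None:
        if fld.grid_shape != shape:
            raise ValueError(f"field grid {fld.grid_shape} != label grid {shape}")
        pts = pts + fld.displacements
    if rigid is not None and not rigid.is_identity():
        pts = pts @ rigid.rotation.T + rigid.translation
    coords = pts / spacing
    nn = np.ceil(coords - 0.5).astype(int)
    valid = np.all((nn >= 0) & (nn < np.asarray(shape)), axis=-1)
    nn = np.clip(nn, 0, np.asarray(shape) - 1)
    out = np.zeros_like(labels.grid)
    out[valid] = labels.grid[nn[..., 0], nn[..., 1], nn[..., 2]][valid]
    return LabelVolume(grid=out, spacing=labels.spacing, label_dict=dict(labels.label_dict))


# ---------------------------------------------------------------------------
# Full repair pipeline
# ---------------------------------------------------------------------------

def fill_tumor_labels(
    subject_seg: LabelVolume,
    atlas_seg: LabelVolume,
    gtv: GTVMask,
    config: RepairConfig | None = None,
) -> ParcellationCase:
    """Repair the subject parcellation inside the tumor.

    Stages: mask GTV out of the subject segmentation; rigidly align the atlas
    to the subject; mask the GTV out of the aligned atlas; deformably
    register the tumor-masked subject onto the tumor-masked atlas with the
    GTV excluded from the similarity; invert the field; warp the full atlas
    labels into subject space; compose per ``config.compose_mode``. Any
    in-brain GTV voxel still unlabeled afterwards takes its nearest
    non-background label.
    """
    cfg = config or RepairConfig()
    check_aligned(subject_seg, atlas_seg, gtv, names=("subject_seg", "atlas_seg", "gtv"))

    if not gtv.union().any():
        return ParcellationCase(
            subject_seg=subject_seg,
            atlas_seg=atlas_seg,
            gtv=gtv,
            mask_final=LabelVolume(
                grid=subject_seg.grid.copy(),
                spacing=subject_seg.spacing,
                label_dict=dict(subject_seg.label_dict),
            ),
            rigid=RigidTransform.identity(),
            field=None,
        )

    def _stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:  # annotate with the failing stage
            raise RegistrationError(f"stage {name!r} failed: {exc}") from exc

    subject_nt = _stage("mask_out_tumor(subject)", mask_out_tumor, subject_seg, gtv)
    rigid = (
        _stage("rigid_register", rigid_register, atlas_seg, subject_seg)
        if cfg.do_rigid
        else RigidTransform.identity()
    )
    atlas_reg = _stage("warp(rigid)", warp_labels, atlas_seg, rigid=rigid)
    atlas_reg_nt = _stage("mask_out_tumor(atlas)", mask_out_tumor, atlas_reg, gtv)

    ignore = gtv.union()
    if cfg.ignore_dilation_mm > 0:
        ignore = (
            ndimage.distance_transform_edt(~ignore, sampling=subject_seg.spacing)
            <= cfg.ignore_dilation_mm
        )
    fld, reg_result = _stage(
        "deformable_register", deformable_register, subject_nt, atlas_reg_nt, ignore, cfg
    )
    warped_atlas = _stage("warp(atlas)", warp_labels, atlas_seg, rigid=rigid,
                          fld=DeformationField(fld.inverse, fld.spacing))

    if cfg.compose_mode == "composite":
        final = subject_seg.grid.copy()
        tum = gtv.union()
        final[tum] = warped_atlas.grid[tum]
    else:
        final = warped_atlas.grid.copy()

    # fill contract: no background voxel inside GTV
    hole = (final == 0) & gtv.union()
    if hole.any():
        _, inds = ndimage.distance_transform_edt(
            final == 0, sampling=subject_seg.spacing, return_indices=True
        )
        final[hole] = final[inds[0][hole], inds[1][hole], inds[2][hole]]

    mask_final = LabelVolume(grid=final, spacing=subject_seg.spacing,
                             label_dict=dict(atlas_seg.label_dict))
    return ParcellationCase(
        subject_seg=subject_seg,
        atlas_seg=atlas_seg,
        gtv=gtv,
        mask_final=mask_final,
        rigid=rigid,
        field=fld,
        deformable_result=reg_result,
    )
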