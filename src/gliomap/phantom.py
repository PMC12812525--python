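"""Synthetic phantom generation: parcellated brains, tumors, deformations,
multi-sequence intensities, corrupted segmentations, and tabular ML cohorts.

The phantoms carry the statistical structure the parcellation-repair method
assumes — a 32-structure label map with 14 mirrored left/right pairs and four
midline structures, an implanted multi-compartment glioma (enhancing core,
necrotic core, peritumoral edema), a smooth invertible deformation between
atlas and subject, label-conditioned Gaussian-mixture intensities with bias
field / gamma / blur / downsampling corruption, and a segmenter whose output
is correct everywhere except on and around the tumor.

Every generator draws from its own named random stream derived from the user
seed, so adding a generator never perturbs the draws of another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import (
    CANONICAL_LABELS,
    CSF_LABEL,
    EDEMA,
    ENHANCING,
    NECROTIC,
    PAIR_PARTNER,
    DeformationField,
    GTVMask,
    IntensityVolume,
    LabelVolume,
    check_aligned,
)

__all__ = [
    "GenerativeParams",
    "PhantomSubject",
    "make_atlas_labels",
    "sample_deformation",
    "implant_tumor",
    "synthesize_intensities",
    "corrupt_parcellation",
    "make_phantom_subject",
    "make_ml_cohort",
]


def _stream(seed: int, op_name: str) -> np.random.Generator:
    """Independent, named random stream for one generator operation."""
    tag = zlib.crc32(op_name.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))


def _physical_grid(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


# ---------------------------------------------------------------------------
# Parcellated atlas phantom
# ---------------------------------------------------------------------------

def make_atlas_labels(
    shape: tuple[int, int, int] = (64, 64, 64),
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0),
    seed: int = 0,
) -> LabelVolume:
    """Ellipsoidal brain partitioned into the canonical 32 structures.

    The brain foreground is a single ellipsoid. The right half is split by a
    seeded Voronoi partition into 14 pair structures plus 4 midline
    structures whose seeds sit on the mid-sagittal plane; the left half is the
    exact mirror image, so paired structures are symmetric by construction and
    midline structures straddle the plane.
    """
    shape = tuple(int(n) for n in shape)
    if any(n < 32 for n in shape):
        raise ValueError(f"each axis must be >= 32 voxels to host 32 structures, got {shape}")
    rng = _stream(seed, "make_atlas_labels")

    X, Y, Z = _physical_grid(shape, spacing)
    center = [(n - 1) / 2 * s for n, s in zip(shape, spacing)]
    semi = [0.44 * n * s for n, s in zip(shape, spacing)]
    brain = (
        ((X - center[0]) / semi[0]) ** 2
        + ((Y - center[1]) / semi[1]) ** 2
        + ((Z - center[2]) / semi[2]) ** 2
    ) <= 1.0

    # Seeds in the right half (x >= mid-plane). Midline structures get seeds
    # pinned to the plane itself.
    mid_x = center[0]
    pair_ids = sorted(PAIR_PARTNER.values())  # right-side ids 19..32
    midline_ids = [15, 16, 17, 18]
    seeds, seed_ids = [], []
    for lab in pair_ids:
        while True:
            u = rng.uniform([0.08, -0.9, -0.9], [0.9, 0.9, 0.9])
            if u[0] ** 2 + u[1] ** 2 + u[2] ** 2 <= 0.8:
                break
        seeds.append([mid_x + u[0] * semi[0], center[1] + u[1] * semi[1], center[2] + u[2] * semi[2]])
        seed_ids.append(lab)
    for lab in midline_ids:
        while True:
            u = rng.uniform([-0.85, -0.85], [0.85, 0.85])
            if u[0] ** 2 + u[1] ** 2 <= 0.72:
                break
        seeds.append([mid_x, center[1] + u[0] * semi[1], center[2] + u[1] * semi[2]])
        seed_ids.append(lab)
    seeds = np.array(seeds)

    right = X >= mid_x - 1e-9
    grid = np.zeros(shape, dtype=np.int16)
    pts = np.stack([X[brain & right], Y[brain & right], Z[brain & right]], axis=1)
    d2 = ((pts[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    grid[brain & right] = np.asarray(seed_ids, dtype=np.int16)[np.argmin(d2, axis=1)]

    # Mirror the right half onto the left, swapping pair labels.
    flip = grid[::-1, :, :].copy()
    mirrored = flip.copy()
    for left, rightlab in PAIR_PARTNER.items():
        mirrored[flip == rightlab] = left
    left_half = X < mid_x - 1e-9
    grid[left_half] = mirrored[left_half]

    vol = LabelVolume(grid=grid, spacing=spacing, label_dict=dict(CANONICAL_LABELS))
    if len(vol.present_labels()) != 32:
        raise ValueError(
            f"shape {shape} too small: only {len(vol.present_labels())} of 32 structures realized"
        )
    return vol


# ---------------------------------------------------------------------------
# Random diffeomorphic deformations
# ---------------------------------------------------------------------------

def _invert_displacement(disp: np.ndarray, spacing, n_iter: int = 50, tol_vox: float = 0.05):
    """Fixed-point inverse of x -> x + u(x); returns inverse displacement."""
    spacing = np.asarray(spacing, float)
    shape = disp.shape[:3]
    idx = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1).astype(float)
    inv = np.zeros_like(disp)
    disp_vox = disp / spacing
    for _ in range(n_iter):
        coords = idx + inv / spacing
        sampled = np.stack(
            [
                ndimage.map_coordinates(disp_vox[..., c], coords.reshape(-1, 3).T, order=1, mode="nearest").reshape(shape)
                for c in range(3)
            ],
            axis=-1,
        )
        new_inv = -sampled * spacing
        delta = np.abs(new_inv - inv).max() / spacing.min()
        inv = new_inv
        if delta < tol_vox:
            break
    return inv


def sample_deformation(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0),
    amplitude: float = 3.0,
    smoothness: float = 10.0,
    seed: int = 0,
    affine_translation: tuple[float, float, float] | None = None,
) -> DeformationField:
    """Smooth random displacement field with guaranteed positive Jacobian.

    Gaussian-smoothed white noise is rescaled so the RMS displacement equals
    ``amplitude`` (mm); ``smoothness`` is the Gaussian kernel width in mm.
    ``affine_translation`` adds a constant offset (and when given alone with
    amplitude 0 the field is a pure translation with exact analytic inverse).
    """
    if amplitude < 0 or smoothness <= 0:
        raise ValueError("amplitude must be >= 0 and smoothness > 0")
    rng = _stream(seed, "sample_deformation")
    spacing_arr = np.asarray(spacing, float)

    disp = np.zeros(tuple(shape) + (3,), dtype=float)
    if amplitude > 0:
        sigma_vox = smoothness / spacing_arr
        noise = rng.standard_normal(tuple(shape) + (3,))
        for c in range(3):
            disp[..., c] = ndimage.gaussian_filter(noise[..., c], sigma=sigma_vox)
        rms = np.sqrt((disp**2).sum(axis=-1).mean())
        disp *= amplitude / max(rms, 1e-12)
    if affine_translation is not None:
        disp += np.asarray(affine_translation, float)

    fld = DeformationField(displacements=disp, spacing=tuple(spacing))
    if amplitude > 0:
        jac = fld.jacobian_determinant()
        if jac.min() <= 0:
            raise ValueError(
                f"amplitude {amplitude} mm too large for smoothness {smoothness} mm: "
                f"min Jacobian {jac.min():.3f} <= 0"
            )
    if amplitude == 0 and affine_translation is not None:
        fld.inverse = -disp  # analytic inverse of a translation
    else:
        fld.inverse = _invert_displacement(disp, spacing)
    return fld


# ---------------------------------------------------------------------------
# Tumor implantation
# ---------------------------------------------------------------------------

def implant_tumor(
    labels: LabelVolume,
    center: tuple[int, int, int],
    radii: tuple[float, float, float] = (12.0, 10.0, 10.0),
    edema_margin: float = 6.0,
    perturbation: float = 0.15,
    necrotic_fraction: float = 0.5,
    seed: int = 0,
) -> GTVMask:
    """Implant a blobby multi-compartment tumor at ``center`` (voxel index).

    Nested perturbed ellipsoids: necrotic core strictly inside the enhancing
    core, which is surrounded by an edema shell of width ``edema_margin`` mm.
    The whole GTV is clipped to the brain foreground.
    """
    grid = labels.grid
    spacing = np.asarray(labels.spacing, float)
    center = tuple(int(c) for c in center)
    if grid[center] == 0:
        raise ValueError(f"tumor center {center} lies outside the brain foreground")
    rng = _stream(seed, "implant_tumor")

    out = np.zeros_like(grid, dtype=np.int16)
    radii = np.asarray(radii, float)
    if np.all(radii <= 0):
        return GTVMask(grid=out, spacing=labels.spacing)

    X, Y, Z = _physical_grid(grid.shape, spacing)
    c_mm = np.asarray(center) * spacing
    q = (
        ((X - c_mm[0]) / max(radii[0], 1e-9)) ** 2
        + ((Y - c_mm[1]) / max(radii[1], 1e-9)) ** 2
        + ((Z - c_mm[2]) / max(radii[2], 1e-9)) ** 2
    )
    if perturbation > 0:
        noise = ndimage.gaussian_filter(rng.standard_normal(grid.shape), sigma=8.0 / spacing)
        noise /= max(np.abs(noise).max(), 1e-12)
        q = q * np.exp(perturbation * noise)

    brain = grid > 0
    core = (q <= 1.0) & brain
    necro = (q <= necrotic_fraction**2) & brain
    # edema: within edema_margin mm of the core, outside it
    dist_out = ndimage.distance_transform_edt(~core, sampling=spacing)
    edema = (dist_out <= edema_margin) & ~core & brain

    out[edema] = EDEMA
    out[core] = ENHANCING
    out[necro] = NECROTIC
    return GTVMask(grid=out, spacing=labels.spacing)


# ---------------------------------------------------------------------------
# Label-conditioned generative intensities
# ---------------------------------------------------------------------------

@dataclass
class GenerativeParams:
    """Parameters of the label-conditioned Gaussian-mixture image generator.

    Class means and standard deviations are drawn once per (class, sequence)
    from the uniform ranges below; the image is then corrupted by a smooth
    multiplicative bias field, a random gamma transform, Gaussian blurring
    (slice-thickness surrogate) and downsample/upsample (slice-spacing
    surrogate).
    """

    mean_range: tuple[float, float] = (25.0, 225.0)
    std_range: tuple[float, float] = (5.0, 25.0)
    bias_amplitude: float = 0.3
    bias_smoothness_mm: float = 40.0
    gamma_log_range: tuple[float, float] = (-0.3, 0.3)
    blur_sigma_range_mm: tuple[float, float] = (0.5, 1.5)
    downsample_range: tuple[float, float] = (1.0, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mean_range", "std_range", "gamma_log_range", "blur_sigma_range_mm", "downsample_range"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"{name} is degenerate: ({lo}, {hi})")
        if self.std_range[0] < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.bias_amplitude < 0:
            raise ValueError("bias_amplitude must be >= 0")


def synthesize_intensities(
    labels: LabelVolume,
    gtv: GTVMask,
    params: GenerativeParams,
    sequence_name: str,
) -> IntensityVolume:
    """Sample one MRI sequence from the generative model.

    Tumor sub-labels are treated as three extra intensity classes on top of
    the 32 anatomical classes, so the implanted glioma is visible in every
    synthesized sequence.
    """
    check_aligned(labels, gtv, names=("labels", "gtv"))
    rng = _stream(params.seed, f"synthesize_intensities/{sequence_name}")
    spacing = np.asarray(labels.spacing, float)

    # effective class id: anatomy, overridden by tumor sub-label (+100)
    classes = labels.grid.astype(np.int32).copy()
    classes[gtv.grid > 0] = 100 + gtv.grid[gtv.grid > 0]

    ids = np.unique(classes)
    means = {int(i): rng.uniform(*params.mean_range) for i in ids if i != 0}
    stds = {int(i): rng.uniform(*params.std_range) for i in ids if i != 0}
    means[0], stds[0] = 0.0, 0.0

    img = np.zeros(classes.shape, dtype=float)
    noise = rng.standard_normal(classes.shape)
    for i in ids:
        m = classes == i
        img[m] = means[int(i)] + stds[int(i)] * noise[m]

    if params.bias_amplitude > 0:
        bias = ndimage.gaussian_filter(
            rng.standard_normal(classes.shape), sigma=params.bias_smoothness_mm / spacing
        )
        bias /= max(np.abs(bias).max(), 1e-12)
        img = img * np.exp(params.bias_amplitude * bias)

    gamma = float(np.exp(rng.uniform(*params.gamma_log_range)))
    if gamma != 1.0:
        lo, hi = img.min(), img.max()
        if hi > lo:
            img = (np.clip((img - lo) / (hi - lo), 0, 1) ** gamma) * (hi - lo) + lo

    sig = float(rng.uniform(*params.blur_sigma_range_mm))
    if sig > 0:
        img = ndimage.gaussian_filter(img, sigma=sig / spacing)

    factor = float(rng.uniform(*params.downsample_range))
    if factor > 1.0:
        img = ndimage.zoom(ndimage.zoom(img, 1.0 / factor, order=1), factor, order=1)
        # zoom rounding can change shape by a voxel; crop/pad back
        img = _match_shape(img, classes.shape)

    return IntensityVolume(grid=img, spacing=labels.spacing, sequence_name=sequence_name)


def _match_shape(arr: np.ndarray, shape) -> np.ndarray:
    out = np.zeros(shape, dtype=arr.dtype)
    sl = tuple(slice(0, min(a, b)) for a, b in zip(arr.shape, shape))
    out[sl] = arr[sl]
    return out


# ---------------------------------------------------------------------------
# Segmenter failure simulation
# ---------------------------------------------------------------------------

def corrupt_parcellation(
    truth: LabelVolume,
    gtv: GTVMask,
    halo: float = 4.0,
    corruption_prob: float = 0.9,
    seed: int = 0,
) -> LabelVolume:
    """Simulate a segmenter that fails on and around the tumor.

    Inside GTV dilated by ``halo`` mm, each voxel is (with probability
    ``corruption_prob``) reassigned among {CSF, the two cortical/white-matter
    labels most represented near the tumor, background} — mimicking CSF
    over-segmentation and cortex/white-matter mislabeling. Voxels outside the
    halo are bitwise unchanged.
    """
    check_aligned(truth, gtv, names=("truth", "gtv"))
    rng = _stream(seed, "corrupt_parcellation")
    out = truth.grid.copy()

    tumor = gtv.union()
    if not tumor.any():
        return LabelVolume(grid=out, spacing=truth.spacing, label_dict=dict(truth.label_dict))
    region = ndimage.distance_transform_edt(~tumor, sampling=truth.spacing) <= halo

    # cortical / white-matter labels: L/R cerebral white matter (1, 19) and
    # L/R cerebral cortex (2, 20); keep the two most frequent in the region
    cw = [1, 2, 19, 20]
    counts = [(int((truth.grid[region] == lab).sum()), lab) for lab in cw]
    counts.sort(reverse=True)
    near = [lab for _, lab in counts[:2]]
    choices = np.array([CSF_LABEL, near[0], near[1], 0], dtype=out.dtype)

    idx = np.flatnonzero(region.ravel())
    hit = rng.random(idx.size) < corruption_prob
    repl = choices[rng.integers(0, len(choices), size=int(hit.sum()))]
    flat = out.ravel()
    flat[idx[hit]] = repl
    return LabelVolume(grid=out, spacing=truth.spacing, label_dict=dict(truth.label_dict))


# ---------------------------------------------------------------------------
# Whole-subject phantom
# ---------------------------------------------------------------------------

@dataclass
class PhantomSubject:
    """One synthetic subject: truth, corrupted segmentation, GTV, sequences."""

    truth_labels: LabelVolume
    corrupted_labels: LabelVolume
    gtv: GTVMask
    sequences: dict[str, IntensityVolume]
    true_field: DeformationField
    metadata: dict = field(default_factory=dict)


def _warp_labels_nn(grid: np.ndarray, disp_mm: np.ndarray, spacing) -> np.ndarray:
    """out[x] = grid(x + u(x)) with nearest-neighbor sampling."""
    spacing = np.asarray(spacing, float)
    shape = grid.shape
    idx = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1).astype(float)
    coords = idx + disp_mm / spacing
    nn = np.ceil(coords - 0.5).astype(int)  # round half toward origin
    valid = np.all((nn >= 0) & (nn < np.asarray(shape)), axis=-1)
    out = np.zeros_like(grid)
    nn_c = np.clip(nn, 0, np.asarray(shape) - 1)
    out[valid] = grid[nn_c[..., 0], nn_c[..., 1], nn_c[..., 2]][valid]
    return out


def make_phantom_subject(
    atlas: LabelVolume,
    seed: int = 0,
    amplitude: float = 3.0,
    smoothness: float = 10.0,
    tumor_radii: tuple[float, float, float] = (14.0, 12.0, 12.0),
    edema_margin: float = 6.0,
    halo: float = 4.0,
    with_intensities: bool = True,
    params: GenerativeParams | None = None,
) -> PhantomSubject:
    """Derive a subject from the atlas: deform, implant tumor, corrupt, image.

    The subject's ground-truth parcellation is the atlas warped by a random
    smooth field (the stored ``true_field`` maps subject grid points into
    atlas space, i.e. ``subject[x] = atlas(x + u(x))``).
    """
    rng = _stream(seed, "make_phantom_subject")
    fld = sample_deformation(atlas.shape, atlas.spacing, amplitude, smoothness, seed=seed)
    truth_grid = _warp_labels_nn(atlas.grid, fld.displacements, atlas.spacing)
    truth = LabelVolume(grid=truth_grid, spacing=atlas.spacing, label_dict=dict(atlas.label_dict))

    # tumor center: random voxel well inside the brain (off the boundary)
    interior = ndimage.binary_erosion(truth.grid > 0, iterations=6)
    cand = np.argwhere(interior)
    center = tuple(cand[rng.integers(len(cand))])
    gtv = implant_tumor(truth, center, tumor_radii, edema_margin, seed=seed)
    corrupted = corrupt_parcellation(truth, gtv, halo=halo, seed=seed)

    sequences: dict[str, IntensityVolume] = {}
    if with_intensities:
        p = params or GenerativeParams(seed=seed)
        if p.seed != seed:
            p = GenerativeParams(**{**p.__dict__, "seed": seed})
        for name in IntensityVolume.VALID_SEQUENCES:
            sequences[name] = synthesize_intensities(truth, gtv, p, name)

    return PhantomSubject(
        truth_labels=truth,
        corrupted_labels=corrupted,
        gtv=gtv,
        sequences=sequences,
        true_field=fld,
        metadata={"seed": seed, "center": tuple(int(c) for c in center), "radii": tuple(tumor_radii)},
    )


# ---------------------------------------------------------------------------
# Tabular ML cohorts
# ---------------------------------------------------------------------------

def make_ml_cohort(
    n_subjects: int = 400,
    n_spatial: int = 32,
    n_radiomic: int = 0,
    n_informative: int = 5,
    effect_size: float = 3.0,
    class_balance: float = 0.5,
    seed: int = 0,
):
    """Feature table with planted class-informative columns.

    Informative columns get a class-conditional mean shift of ``effect_size``
    standard deviations; all other columns are pure N(0, 1) noise. Returns a
    DataFrame (subject_id, features..., label) whose ``attrs['informative']``
    records the planted column names.
    """
    if n_informative > n_spatial + n_radiomic:
        raise ValueError("n_informative exceeds the number of features")
    n1 = int(round(n_subjects * class_balance))
    if n1 < 1 or n_subjects - n1 < 1:
        raise ValueError(
            f"class_balance {class_balance} leaves an empty class at n={n_subjects}"
        )
    rng = _stream(seed, "make_ml_cohort")

    names = [f"spatial_{i:02d}" for i in range(n_spatial)] + [
        f"radiomic_{i:03d}" for i in range(n_radiomic)
    ]
    p = len(names)
    y = np.zeros(n_subjects, dtype=int)
    y[rng.choice(n_subjects, size=n1, replace=False)] = 1
    X = rng.standard_normal((n_subjects, p))
    info_idx = rng.choice(p, size=n_informative, replace=False)
    X[np.ix_(y == 1, info_idx)] += effect_size

    df = pd.DataFrame(X, columns=names)
    df.insert(0, "subject_id", [f"S{i:04d}" for i in range(n_subjects)])
    df["label"] = y
    df.attrs["informative"] = [names[i] for i in sorted(info_idx)]
    return df
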