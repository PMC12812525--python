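"""Core in-memory containers for volumes, masks and deformation fields.

All volumes live on a regular 3D grid indexed ``[i, j, k]`` with physical
coordinates ``x = index * spacing`` (mm, origin at the first voxel center).
Axis 0 is the left--right axis; the mid-sagittal plane sits at
``(shape[0] - 1) / 2 * spacing[0]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

# Canonical parcellation vocabulary: 14 left/right structure pairs plus four
# midline structures (32 total). Ids 1..14 left, 15..18 midline, 19..32 right;
# the canonical feature order is exactly this id order.
_PAIR_NAMES = (
    "cerebral white matter",
    "cerebral cortex",
    "lateral ventricle",
    "inferior lateral ventricle",
    "cerebellum white matter",
    "cerebellum cortex",
    "thalamus",
    "caudate",
    "putamen",
    "pallidum",
    "hippocampus",
    "amygdala",
    "accumbens area",
    "ventral DC",
)
_MIDLINE_NAMES = ("CSF", "3rd ventricle", "4th ventricle", "brain-stem")

CANONICAL_LABELS: dict[int, str] = {}
for _i, _n in enumerate(_PAIR_NAMES):
    CANONICAL_LABELS[1 + _i] = f"L {_n}"
for _i, _n in enumerate(_MIDLINE_NAMES):
    CANONICAL_LABELS[15 + _i] = _n
for _i, _n in enumerate(_PAIR_NAMES):
    CANONICAL_LABELS[19 + _i] = f"R {_n}"

#: left id -> right id for the 14 mirrored pairs
PAIR_PARTNER: dict[int, int] = {1 + i: 19 + i for i in range(14)}

CSF_LABEL = 15

# GTV sub-label codes
ENHANCING, NECROTIC, EDEMA = 1, 2, 3


def canonical_label_ids() -> list[int]:
    """The 32 structure ids in canonical feature order."""
    return sorted(CANONICAL_LABELS)


@dataclass
class LabelVolume:
    """3D integer parcellation with voxel spacing and a label dictionary."""

    grid: np.ndarray
    spacing: tuple[float, float, float]
    label_dict: Mapping[int, str] = field(default_factory=lambda: dict(CANONICAL_LABELS))

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError(f"label grid must be 3D, got shape {self.grid.shape}")
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise ValueError("label grid must be integer-typed")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def present_labels(self) -> list[int]:
        return [int(v) for v in np.unique(self.grid) if v != 0]

    def validate_dictionary(self) -> None:
        """Every non-zero id in the grid must be named in label_dict."""
        unknown = set(self.present_labels()) - set(self.label_dict)
        if unknown:
            raise ValueError(f"grid contains ids missing from label_dict: {sorted(unknown)}")


@dataclass
class GTVMask:
    """Gross tumor volume with sub-labels 1=enhancing, 2=necrotic, 3=edema."""

    grid: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError(f"GTV grid must be 3D, got shape {self.grid.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        bad = set(np.unique(self.grid)) - {0, ENHANCING, NECROTIC, EDEMA}
        if bad:
            raise ValueError(f"GTV sub-labels must be in {{0,1,2,3}}, got extra {sorted(bad)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    def union(self) -> np.ndarray:
        """Boolean mask of the whole GTV (all three sub-labels)."""
        return self.grid > 0


@dataclass
class IntensityVolume:
    """A single structural MRI sequence on the common grid."""

    grid: np.ndarray
    spacing: tuple[float, float, float]
    sequence_name: str

    VALID_SEQUENCES = ("T1", "T1CE", "T2", "FLAIR")

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 3:
            raise ValueError(f"intensity grid must be 3D, got shape {self.grid.shape}")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("intensity grid contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.sequence_name not in self.VALID_SEQUENCES:
            raise ValueError(
                f"sequence_name must be one of {self.VALID_SEQUENCES}, got {self.sequence_name!r}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape


@dataclass
class DeformationField:
    """Dense displacement field u (mm) sampled on a grid; maps x -> x + u(x).

    ``displacements`` has shape ``(*grid_shape, 3)`` with components along the
    grid axes in mm. ``inverse`` (if present) is the displacement of the
    inverse map sampled on the same grid.
    """

    displacements: np.ndarray
    spacing: tuple[float, float, float]
    inverse: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.displacements = np.asarray(self.displacements, dtype=float)
        if self.displacements.ndim != 4 or self.displacements.shape[-1] != 3:
            raise ValueError(
                f"displacements must have shape (*grid, 3), got {self.displacements.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.displacements.shape[:3]

    def magnitude_mm(self) -> np.ndarray:
        return np.linalg.norm(self.displacements, axis=-1)

    def jacobian_determinant(self) -> np.ndarray:
        """det(I + du/dx) per voxel, gradients in physical units."""
        J = np.empty(self.grid_shape + (3, 3))
        for c in range(3):
            for ax in range(3):
                J[..., c, ax] = np.gradient(
                    self.displacements[..., c], self.spacing[ax], axis=ax
                )
            J[..., c, c] += 1.0
        return np.linalg.det(J)


def check_aligned(*vols, names: tuple[str, ...] | None = None) -> None:
    """Raise if companion volumes disagree on shape or spacing."""
    shapes = [tuple(v.shape) for v in vols]
    spacings = [tuple(np.round(v.spacing, 9)) for v in vols]
    if len(set(shapes)) > 1 or len(set(spacings)) > 1:
        labels = names or tuple(f"volume{i}" for i in range(len(vols)))
        detail = ", ".join(f"{n}: shape {s} spacing {sp}" for n, s, sp in zip(labels, shapes, spacings))
        raise ValueError(f"volumes are not aligned ({detail})")
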