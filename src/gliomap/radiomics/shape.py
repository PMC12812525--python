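"""3D morphological descriptors of the tumor ROI.

Mesh-based quantities (volume, surface area) come from a marching-cubes
triangulation of the binary ROI; axis lengths derive from the eigenvalues of
the physical coordinate covariance (principal-axes convention: axis length
= 4 sqrt(lambda)); the maximum diameters are largest pairwise distances of
ROI surface voxels in 3D and in the three orthogonal plane families.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import pdist
from skimage import measure

from .manifest import SHAPE_FEATURES
from ..volumes import GTVMask


class EmptyROIError(ValueError):
    pass


def _surface_voxel_coords(mask: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(mask)
    surf = mask & ~eroded
    return np.argwhere(surf) * spacing


def _max_pairwise(coords: np.ndarray) -> float:
    if len(coords) < 2:
        return 0.0
    if len(coords) > 2000:  # hull reduces the candidate set without changing the max
        from scipy.spatial import ConvexHull

        try:
            coords = coords[ConvexHull(coords).vertices]
        except Exception:
            pass
    return float(pdist(coords).max())


def extract_shape(gtv: GTVMask, spacing=None) -> dict[str, float]:
    """The 14 shape descriptors of the whole-GTV ROI (order per manifest)."""
    mask = gtv.union()
    if not mask.any():
        raise EmptyROIError("shape features require a non-empty ROI")
    sp = np.asarray(spacing if spacing is not None else gtv.spacing, float)

    padded = np.pad(mask, 1).astype(float)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=tuple(sp))
    surface_area = float(measure.mesh_surface_area(verts, faces))
    # signed tetrahedron sum; orientation of skimage faces gives negative volume
    v0, v1, v2 = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    mesh_volume = float(abs(np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum()) / 6.0)

    voxel_volume = float(mask.sum() * sp.prod())
    sphericity = float((36.0 * np.pi * mesh_volume**2) ** (1.0 / 3.0) / surface_area)

    coords = np.argwhere(mask) * sp
    surf = _surface_voxel_coords(mask, sp)
    max3d = _max_pairwise(surf)

    def _planar_max(drop_axis: int) -> float:
        keep = [a for a in range(3) if a != drop_axis]
        best = 0.0
        for val in np.unique(surf[:, drop_axis]):
            pts = surf[surf[:, drop_axis] == val][:, keep]
            best = max(best, _max_pairwise(pts))
        return best

    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / len(coords)
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]  # major, minor, least
    eig = np.clip(eig, 0, None)
    major, minor, least = (4.0 * np.sqrt(eig)).tolist()
    elongation = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 0.0
    flatness = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 0.0

    values = {
        "mesh_volume": mesh_volume,
        "voxel_volume": voxel_volume,
        "surface_area": surface_area,
        "surface_volume_ratio": surface_area / mesh_volume,
        "sphericity": sphericity,
        "maximum_3d_diameter": max3d,
        "maximum_2d_diameter_slice": _planar_max(2),
        "maximum_2d_diameter_column": _planar_max(1),
        "maximum_2d_diameter_row": _planar_max(0),
        "major_axis_length": major,
        "minor_axis_length": minor,
        "least_axis_length": least,
        "elongation": elongation,
        "flatness": flatness,
    }
    return {name: float(values[name]) for name in SHAPE_FEATURES}
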