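"""NIfTI, TSV and CSV round-trip I/O for every artifact the tool touches."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .volumes import CANONICAL_LABELS, DeformationField, GTVMask, IntensityVolume, LabelVolume


class FormatError(ValueError):
    pass


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_volume(volume, path) -> None:
    """Write a LabelVolume / GTVMask / IntensityVolume as NIfTI-1 (.nii.gz)."""
    path = Path(path)
    if isinstance(volume, (LabelVolume, GTVMask)):
        data = volume.grid.astype(np.int16)
    elif isinstance(volume, IntensityVolume):
        data = volume.grid.astype(np.float64)
    else:
        raise TypeError(f"cannot write object of type {type(volume).__name__}")
    nib.save(nib.Nifti1Image(data, _affine(volume.spacing)), str(path))


def read_volume(path, kind: str | None = None, sequence_name: str = "T1"):
    """Load a NIfTI volume; integer payloads become labels, floats intensities.

    ``kind`` in {"labels", "gtv", "intensity"} overrides the dtype heuristic.
    Volumes are reoriented to canonical (RAS) axis order on load.
    """
    path = Path(path)
    try:
        img = nib.as_closest_canonical(nib.load(str(path)))
    except Exception as exc:
        raise FormatError(f"{path} is not a readable NIfTI file: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D payload, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])

    integral = np.issubdtype(data.dtype, np.integer) or np.allclose(data, np.round(data))
    if kind is None:
        kind = "labels" if integral else "intensity"
    if kind == "labels":
        grid = np.round(data).astype(np.int16)
        present = set(int(v) for v in np.unique(grid)) - {0}
        label_dict = {i: CANONICAL_LABELS.get(i, f"label {i}") for i in sorted(present)}
        return LabelVolume(grid=grid, spacing=spacing, label_dict=label_dict)
    if kind == "gtv":
        return GTVMask(grid=np.round(data).astype(np.int16), spacing=spacing)
    if kind == "intensity":
        return IntensityVolume(grid=data.astype(float), spacing=spacing, sequence_name=sequence_name)
    raise ValueError(f"unknown kind {kind!r}")


def write_field(field: DeformationField, path) -> None:
    """Displacement field as 5D NIfTI (x, y, z, 1, vector)."""
    data = field.displacements[:, :, :, np.newaxis, :].astype(np.float64)
    nib.save(nib.Nifti1Image(data, _affine(field.spacing)), str(path))


def read_field(path) -> DeformationField:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 5 or data.shape[-1] != 3:
        raise FormatError(f"{path}: expected a 5D vector NIfTI, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return DeformationField(displacements=data[:, :, :, 0, :], spacing=spacing)


def write_label_dict(label_dict, path) -> None:
    pd.DataFrame(
        {"id": list(label_dict), "name": [label_dict[k] for k in label_dict]}
    ).to_csv(path, sep="\t", index=False)


def read_label_dict(path) -> dict[int, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["id"].astype(int), df["name"]))


def write_feature_table(df: pd.DataFrame, path) -> None:
    """Cohort CSV: first column subject_id, last column label."""
    cols = list(df.columns)
    if cols[0] != "subject_id" or cols[-1] != "label":
        raise ValueError("feature table must start with 'subject_id' and end with 'label'")
    df.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.columns[0] != "subject_id" or df.columns[-1] != "label":
        raise FormatError(f"{path}: feature table must start with 'subject_id' and end with 'label'")
    if df.isna().any().any():
        raise FormatError(f"{path}: feature table contains missing values")
    return df


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=float) + "\n")
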