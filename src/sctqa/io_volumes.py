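"""Reading, writing, and pairing of HU-valued 3D volumes.

Volumes are held as float arrays indexed ``(x, y, z)`` with the *last* axis
axial (craniocaudal), so ``volume[..., i]`` is the i-th axial slice.  NIfTI
(.nii/.nii.gz) is the primary on-disk format, MetaImage (.mha/.mhd) the
secondary; both are standard in radiotherapy research.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import nibabel as nib
import numpy as np
import SimpleITK as sitk

#: spacing/origin agreement required when pairing two volumes, in mm
GEOMETRY_TOL_MM = 1e-3

Modality = Literal["CBCT", "MR"]


@dataclass
class Geometry:
    """Voxel geometry: spacing (mm), origin (mm) and axis direction matrix.

    The direction matrix maps array axes (x, y, z) to physical axes,
    row-major as in ITK.  Identity means the array is already aligned with
    the physical frame.
    """

    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, ...] = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0)

    def close_to(self, other: "Geometry", tol: float = GEOMETRY_TOL_MM) -> bool:
        return (
            np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.direction, other.direction, atol=1e-6)
        )

    @property
    def affine(self) -> np.ndarray:
        """4x4 affine equivalent (direction * diag(spacing), origin)."""
        aff = np.eye(4)
        d = np.asarray(self.direction, dtype=float).reshape(3, 3)
        aff[:3, :3] = d @ np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff


@dataclass
class VolumePair:
    """A pre-registered ground-truth CT / synthetic CT pair.

    Both grids share shape and geometry; slice ``i`` along the last axis is
    the i-th axial (craniocaudal) plane in both.
    """

    patient_id: str
    modality: Modality
    gt: np.ndarray
    sct: np.ndarray
    geometry: Geometry = field(default_factory=Geometry)

    def __post_init__(self) -> None:
        if self.gt.shape != self.sct.shape:
            raise ValueError(
                f"shape mismatch: gt {self.gt.shape} vs sct {self.sct.shape}"
            )
        if self.gt.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.gt.ndim}D")

    @property
    def n_slices(self) -> int:
        return self.gt.shape[2]


def _infer_format(path: str | Path) -> str:
    name = str(path).lower()
    if name.endswith((".nii", ".nii.gz")):
        return "NIfTI"
    if name.endswith((".mha", ".mhd")):
        return "MetaImage"
    raise ValueError(f"cannot infer volume format from filename: {path}")


def load_volume(
    path: str | Path, format: str | None = None
) -> tuple[np.ndarray, Geometry]:
    """Load a 3D HU volume; returns ``(grid, geometry)`` with axial last.

    Parameters
    ----------
    path
        File path of a NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) image.
    format
        "NIfTI" or "MetaImage"; inferred from the suffix when omitted.

    Raises
    ------
    FileNotFoundError, ValueError
        Unreadable file, non-3D image, or missing spacing metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    fmt = format or _infer_format(path)
    if fmt == "NIfTI":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
        if data.ndim != 3:
            raise ValueError(f"expected 3D volume, got {data.ndim}D: {path}")
        zooms = img.header.get_zooms()[:3]
        if any(z == 0 for z in zooms):
            raise ValueError(f"missing or zero voxel spacing in header: {path}")
        aff = img.affine
        rot = aff[:3, :3]
        sp = np.linalg.norm(rot, axis=0)
        direction = tuple((rot / sp).T.flatten())
        geom = Geometry(
            spacing=tuple(float(z) for z in zooms),
            origin=tuple(float(v) for v in aff[:3, 3]),
            direction=tuple(float(v) for v in np.asarray(direction)),
        )
        return data, geom
    if fmt == "MetaImage":
        img = sitk.ReadImage(str(path))
        if img.GetDimension() != 3:
            raise ValueError(f"expected 3D volume, got {img.GetDimension()}D: {path}")
        # SimpleITK arrays come back (z, y, x); normalize to (x, y, z)
        data = sitk.GetArrayFromImage(img).astype(np.float64).transpose(2, 1, 0)
        geom = Geometry(
            spacing=tuple(img.GetSpacing()),
            origin=tuple(img.GetOrigin()),
            direction=tuple(img.GetDirection()),
        )
        return data, geom
    raise ValueError(f"unknown volume format: {fmt}")


def save_volume(
    grid: np.ndarray,
    geometry: Geometry,
    path: str | Path,
    dtype: np.dtype | type = np.float32,
) -> Path:
    """Write a 3D grid (axial-last) to NIfTI or MetaImage, by suffix."""
    grid = np.asarray(grid)
    if grid.ndim != 3:
        raise ValueError(f"expected 3D volume, got {grid.ndim}D")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fmt = _infer_format(path)
    if fmt == "NIfTI":
        img = nib.Nifti1Image(grid.astype(dtype), geometry.affine)
        img.header.set_zooms(geometry.spacing)
        nib.save(img, str(path))
    else:
        img = sitk.GetImageFromArray(grid.astype(dtype).transpose(2, 1, 0))
        img.SetSpacing(geometry.spacing)
        img.SetOrigin(geometry.origin)
        img.SetDirection(geometry.direction)
        sitk.WriteImage(img, str(path))
    return path


def make_pair(
    gt_path: str | Path,
    sct_path: str | Path,
    modality: Modality,
    patient_id: str | None = None,
    tol_mm: float = GEOMETRY_TOL_MM,
) -> VolumePair:
    """Load and pair a ground-truth CT and a synthetic CT.

    Shapes must match exactly; spacing and origin must agree within
    ``tol_mm`` (default 1e-3 mm) — strict bit equality is too brittle after
    resampling.
    """
    gt, gt_geom = load_volume(gt_path)
    sct, sct_geom = load_volume(sct_path)
    if gt.shape != sct.shape:
        raise ValueError(f"shape mismatch: gt {gt.shape} vs sct {sct.shape}")
    if not gt_geom.close_to(sct_geom, tol=tol_mm):
        raise ValueError(
            f"geometry mismatch beyond {tol_mm} mm: "
            f"gt {gt_geom.spacing}/{gt_geom.origin} vs "
            f"sct {sct_geom.spacing}/{sct_geom.origin}"
        )
    if patient_id is None:
        patient_id = os.path.basename(str(gt_path)).split(".")[0]
    return VolumePair(
        patient_id=patient_id, modality=modality, gt=gt, sct=sct, geometry=gt_geom
    )


def extract_axial_slices(volume: np.ndarray) -> list[np.ndarray]:
    """Return the ordered axial planes of an axial-last 3D grid.

    ``extract_axial_slices(v)[i][x, y] == v[x, y, i]``; an empty axial
    extent yields an empty list.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError(f"expected 3D volume, got {volume.ndim}D")
    return [volume[:, :, i] for i in range(volume.shape[2])]


def stack_axial_slices(slices: Sequence[np.ndarray]) -> np.ndarray:
    """Inverse of :func:`extract_axial_slices`."""
    return np.stack(slices, axis=2)


def write_pmae_volume(
    predictions: Sequence[float],
    source_shape: tuple[int, int, int],
    geometry: Geometry,
    path: str | Path,
) -> Path:
    """Assemble and write the predicted-MAE overlay volume.

    The output has the source sCT's shape and geometry; axial plane ``i``
    is constant at ``predictions[i]``.  Written float32 as NIfTI or
    MetaImage depending on the suffix (conventional suffix
    ``_pmae.nii.gz``).
    """
    grid = build_pmae_grid(predictions, source_shape)
    return save_volume(grid, geometry, path, dtype=np.float32)


def build_pmae_grid(
    predictions: Sequence[float], source_shape: tuple[int, int, int]
) -> np.ndarray:
    """Slice-constant 3D grid from per-slice MAE scalars."""
    preds = np.asarray(predictions, dtype=np.float32)
    if preds.ndim != 1 or len(preds) != source_shape[2]:
        raise ValueError(
            f"need one prediction per axial slice: got {preds.size} "
            f"for axial extent {source_shape[2]}"
        )
    grid = np.empty(source_shape, dtype=np.float32)
    grid[:, :, :] = preds[np.newaxis, np.newaxis, :]
    return grid
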