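"""Volumetric containers for dose distributions and regions of interest.

Arrays are indexed ``values[i, j, k]`` with axis order (x, y, z); ``spacing``
gives the physical voxel size in mm per axis and ``origin`` the physical
position (mm) of voxel (0, 0, 0).  File I/O goes through SimpleITK (NRRD,
NIfTI) and pydicom (DICOM RTDOSE); SimpleITK's native (z, y, x) array order
is transposed on the way in and out so the in-memory convention is uniform.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

ROI_LABELS = ("GTV", "PTV", "Heart", "Lung")


@dataclass
class DoseGrid:
    """A 3D absorbed-dose distribution in Gy on a regular axis-aligned grid."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (2.5, 2.5, 2.5)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"dose grid must be 3D, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dose grid contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("dose grid contains negative dose")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive numbers, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in mm^3."""
        return float(np.prod(self.spacing))

    def copy_with(self, values: np.ndarray) -> "DoseGrid":
        return DoseGrid(values, self.spacing, self.origin)


@dataclass
class RoiMask:
    """A binary region-of-interest mask aligned with a :class:`DoseGrid`."""

    values: np.ndarray
    label: str = "GTV"
    spacing: tuple[float, float, float] = (2.5, 2.5, 2.5)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {self.values.shape}")
        if not self.values.any():
            raise ValueError(f"mask {self.label!r} is empty")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())


def _check_axis_aligned(img: sitk.Image, path: str) -> None:
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        raise ValueError(
            f"{path}: volume is not axis-aligned (direction matrix {direction.tolist()}); "
            "resample it to an identity orientation before loading"
        )


def read_volume(path: str, kind: str = "dose", label: str = "GTV"):
    """Read an NRRD/NIfTI scalar volume as a :class:`DoseGrid` or :class:`RoiMask`.

    Parameters
    ----------
    path:
        File ending in ``.nrrd``, ``.nii`` or ``.nii.gz``.
    kind:
        ``"dose"`` or ``"mask"``.  Masks are thresholded at 0.5.
    label:
        ROI label attached when ``kind == "mask"``.
    """
    img = sitk.ReadImage(path)
    _check_axis_aligned(img, path)
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)  # (z,y,x) -> (x,y,z)
    spacing = tuple(img.GetSpacing())
    origin = tuple(img.GetOrigin())
    if kind == "dose":
        return DoseGrid(np.ascontiguousarray(arr, dtype=np.float64), spacing, origin)
    if kind == "mask":
        return RoiMask(arr > 0.5, label, spacing, origin)
    raise ValueError(f"kind must be 'dose' or 'mask', got {kind!r}")


def write_volume(obj, path: str) -> None:
    """Write a :class:`DoseGrid` or :class:`RoiMask` to NRRD/NIfTI."""
    if isinstance(obj, RoiMask):
        arr = obj.values.astype(np.uint8)
    else:
        arr = obj.values
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
    img.SetSpacing(obj.spacing)
    img.SetOrigin(obj.origin)
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    sitk.WriteImage(img, path)


def read_rtdose(path: str) -> DoseGrid:
    """Read a single-file DICOM RTDOSE object (GRID dose).

    Dose in Gy is the stored pixel values multiplied by the DoseGridScaling
    tag; a missing scaling factor is an error rather than an assumed 1.0.
    """
    import pydicom

    ds = pydicom.dcmread(path)
    scaling = getattr(ds, "DoseGridScaling", None)
    if scaling is None:
        raise ValueError(f"{path}: RTDOSE has no DoseGridScaling tag")
    frames = ds.pixel_array.astype(np.float64) * float(scaling)  # (z, y, x)
    arr = frames.transpose(2, 1, 0)
    row_spacing, col_spacing = (float(v) for v in ds.PixelSpacing)
    offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector])
    dz = float(np.diff(offsets)[0]) if offsets.size > 1 else 1.0
    if offsets.size > 2 and not np.allclose(np.diff(offsets), dz):
        raise ValueError(f"{path}: non-uniform GridFrameOffsetVector is unsupported")
    origin = tuple(float(v) for v in ds.ImagePositionPatient)
    return DoseGrid(arr, spacing=(col_spacing, row_spacing, abs(dz)), origin=origin)
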