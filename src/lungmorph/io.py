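"""Read CT volumes from DICOM series or NIfTI; write masks as NIfTI.

DICOM slices are ordered by Image Position Patient projected onto the
slice normal (cross product of the row/column direction cosines), never
by filename. The rescale slope/intercept is applied so values are HU.
Missing spacing metadata is an error, never a silent default.
"""

from __future__ import annotations

import os
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom

from .volume import ImageVolume, VoxelMask


def read_volume(path: str | os.PathLike, format_hint: str = "auto") -> ImageVolume:
    """Load a CT volume in HU from a NIfTI file or a DICOM series directory.

    Parameters
    ----------
    path
        A ``.nii``/``.nii.gz`` file or a directory holding one DICOM series.
    format_hint
        ``auto`` (by path type), ``dicom_dir``, or ``nifti``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such path: {path}")
    if format_hint == "auto":
        format_hint = "dicom_dir" if path.is_dir() else "nifti"
    if format_hint == "nifti":
        return _read_nifti(path)
    if format_hint == "dicom_dir":
        return _read_dicom_dir(path)
    raise ValueError(f"unknown format_hint {format_hint!r}")


def _read_nifti(path: Path) -> ImageVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected a 3D NIfTI, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise ValueError(f"NIfTI header has invalid voxel spacing {zooms}")
    return ImageVolume(values=data, spacing=tuple(float(z) for z in zooms),
                       source_id=str(path))


def _read_dicom_dir(path: Path) -> ImageVolume:
    files = sorted(p for p in path.iterdir() if p.is_file())
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except pydicom.errors.InvalidDicomError:
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise ValueError(f"no DICOM slices found in {path}")

    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in slices}
    if len(uids) > 1:
        raise ValueError(f"directory {path} mixes {len(uids)} DICOM series")

    first = slices[0]
    if not hasattr(first, "PixelSpacing"):
        raise ValueError("DICOM series lacks PixelSpacing metadata")
    if not hasattr(first, "ImageOrientationPatient") or not hasattr(
        first, "ImagePositionPatient"
    ):
        raise ValueError("DICOM series lacks orientation/position metadata")

    orient = np.asarray(first.ImageOrientationPatient, dtype=float)
    normal = np.cross(orient[:3], orient[3:])
    # Scalar position of each slice along the stack normal.
    pos = np.array(
        [np.dot(np.asarray(ds.ImagePositionPatient, dtype=float), normal)
         for ds in slices]
    )
    order = np.argsort(pos)
    pos = pos[order]
    slices = [slices[i] for i in order]
    deltas = np.diff(pos)
    if len(deltas) and np.any(deltas <= 1e-6):
        raise ValueError("non-monotone or duplicate slice positions in series")

    if len(deltas):
        if np.ptp(deltas) > 1e-3:
            raise ValueError("non-uniform slice spacing in series")
        dz = float(deltas.mean())
    elif hasattr(first, "SliceThickness"):
        dz = float(first.SliceThickness)
    else:
        raise ValueError("cannot determine slice spacing from a single slice")

    row_sp, col_sp = (float(v) for v in first.PixelSpacing)
    planes = []
    for ds in slices:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        planes.append(arr * slope + intercept)
    stack = np.stack(planes, axis=-1)  # (rows, cols, z) = (y, x, z)
    values = np.transpose(stack, (1, 0, 2))  # -> (x, y, z)
    # PixelSpacing is (row spacing, column spacing) = (dy, dx).
    return ImageVolume(values=values, spacing=(col_sp, row_sp, dz),
                       source_id=str(path))


def write_mask(mask: VoxelMask, path: str | os.PathLike) -> None:
    """Write a binary mask as NIfTI with values in {0,1} and its spacing."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    affine = np.diag(list(mask.spacing) + [1.0])
    img = nib.Nifti1Image(mask.foreground.astype(np.uint8), affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def read_mask(path: str | os.PathLike) -> VoxelMask:
    """Load a NIfTI mask; any nonzero voxel is foreground."""
    vol = read_volume(path, format_hint="nifti")
    return VoxelMask(foreground=vol.values != 0, spacing=vol.spacing)
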