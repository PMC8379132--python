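"""Reading and writing CT volumes (NIfTI and DICOM series) in Hounsfield units.

The canonical in-memory orientation is fixed by :class:`~uldct.volume.CTVolume`
(axis-aligned LPS-like axes, mm, voxel-center origin); readers must deliver
volumes in that convention. Only axis-aligned geometries are supported —
oblique acquisitions raise :class:`~uldct.errors.FormatError` rather than
being silently resampled.

DICOM slices are ordered by projecting ``ImagePositionPatient`` onto the
slice normal (the cross product of the row/column direction cosines), never
by file name, and stored values are mapped to HU with the rescale
slope/intercept tags.
"""

from __future__ import annotations

import os
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

from .errors import FormatError
from .volume import CTVolume

__all__ = ["read_volume", "write_volume"]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _is_nifti_path(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def read_volume(path, format: str | None = None) -> CTVolume:
    """Read a CT volume from a NIfTI file or a DICOM series directory.

    Parameters
    ----------
    path
        A ``.nii``/``.nii.gz`` file, or a directory containing one DICOM
        series (one file per slice).
    format
        ``"nifti"`` or ``"dicom_series"``; inferred from ``path`` when None.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such path: {path}")
    if format is None:
        format = "nifti" if _is_nifti_path(path) else "dicom_series"
    if format == "nifti":
        return _read_nifti(path)
    if format == "dicom_series":
        return _read_dicom_series(path)
    raise FormatError(f"unknown format {format!r}")


def write_volume(volume: CTVolume, path, format: str | None = None) -> None:
    """Write a CT volume as NIfTI or as a DICOM series directory.

    NIfTI preserves HU values losslessly (float32). DICOM stores HU as
    integers (slope 1, intercept −1024), so non-integer HU are rounded to
    the nearest integer — the format's precision.
    """
    path = Path(path)
    if format is None:
        format = "nifti" if _is_nifti_path(path) else "dicom_series"
    if format == "nifti":
        _write_nifti(volume, path)
    elif format == "dicom_series":
        _write_dicom_series(volume, path)
    else:
        raise FormatError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# NIfTI


def _read_nifti(path: Path) -> CTVolume:
    img = nib.load(str(path))
    affine = img.affine
    rot = affine[:3, :3]
    # accept axis-aligned affines only (possibly with negative direction)
    perm = np.argmax(np.abs(rot), axis=0)
    if sorted(perm.tolist()) != [0, 1, 2]:
        raise FormatError(f"oblique NIfTI affine not supported:\n{rot}")
    off_axis = rot.copy()
    for j, i in enumerate(perm):
        off_axis[i, j] = 0.0
    if np.max(np.abs(off_axis)) > 1e-3 * max(1.0, np.max(np.abs(rot))):
        raise FormatError(f"oblique NIfTI affine not supported:\n{rot}")

    data = np.asanyarray(img.dataobj)
    # reorder data axes so that data axis a advances along world axis a
    inv_perm = np.argsort(perm)
    data = np.transpose(data, inv_perm)
    spacing = [abs(rot[i, j]) for i, j in zip(range(3), inv_perm)]
    origin = affine[:3, 3].astype(float).copy()
    # flip axes with negative direction so spacing is positive everywhere
    for i, j in zip(range(3), inv_perm):
        if rot[i, j] < 0:
            data = np.flip(data, axis=i)
            origin[i] = origin[i] + rot[i, j] * (data.shape[i] - 1)
    return CTVolume(np.ascontiguousarray(data), tuple(spacing), tuple(origin))


def _write_nifti(volume: CTVolume, path: Path) -> None:
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = volume.spacing_mm
    affine[:3, 3] = volume.origin_mm
    img = nib.Nifti1Image(np.asarray(volume.values, dtype=np.float32), affine)
    img.header.set_zooms(volume.spacing_mm)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# DICOM series


def _read_dicom_series(path: Path) -> CTVolume:
    if not path.is_dir():
        raise FormatError(f"DICOM series path must be a directory: {path}")
    files = sorted(p for p in path.iterdir() if p.is_file() and p.suffix != ".json")
    if not files:
        raise FormatError(f"no files in DICOM directory {path}")
    slices = [pydicom.dcmread(str(f)) for f in files]

    ref = slices[0]
    orient = tuple(float(v) for v in ref.ImageOrientationPatient)
    pix_sp = tuple(float(v) for v in ref.PixelSpacing)
    for ds in slices[1:]:
        if tuple(float(v) for v in ds.ImageOrientationPatient) != orient:
            raise FormatError("mixed-orientation DICOM series")
        if tuple(float(v) for v in ds.PixelSpacing) != pix_sp:
            raise FormatError("mixed pixel spacing in DICOM series")

    row_dir = np.asarray(orient[:3])  # direction of increasing column index
    col_dir = np.asarray(orient[3:])  # direction of increasing row index
    if not (np.allclose(np.abs(row_dir), [1, 0, 0]) and np.allclose(np.abs(col_dir), [0, 1, 0])):
        raise FormatError("only axial axis-aligned DICOM orientations are supported")
    normal = np.cross(row_dir, col_dir)

    # geometric slice order, independent of file naming
    slices.sort(key=lambda ds: float(np.dot(np.asarray(ds.ImagePositionPatient, dtype=float), normal)))

    positions = np.array([ds.ImagePositionPatient for ds in slices], dtype=float)
    if len(slices) > 1:
        steps = np.diff(positions @ normal)
        dz = float(np.mean(steps))
        if np.max(np.abs(steps - dz)) > 1e-3 * abs(dz):
            raise FormatError("non-uniform slice spacing in DICOM series")
    else:
        dz = float(getattr(ref, "SliceThickness", 1.0))

    planes = []
    for ds in slices:
        if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
            raise FormatError(
                "DICOM slice lacks RescaleSlope/RescaleIntercept; cannot convert stored values to HU"
            )
        hu = ds.pixel_array.astype(np.float32) * float(ds.RescaleSlope) + float(ds.RescaleIntercept)
        planes.append(hu)
    stack = np.stack(planes, axis=0)  # (z, rows, cols) = (z, y, x)
    values = np.ascontiguousarray(np.transpose(stack, (2, 1, 0)))  # -> (x, y, z)
    if row_dir[0] < 0:
        values = np.flip(values, axis=0)
    if col_dir[1] < 0:
        values = np.flip(values, axis=1)
    if normal[2] < 0:
        values = np.flip(values, axis=2)
    origin = positions[0].copy()
    spacing = (pix_sp[1], pix_sp[0], abs(dz))  # PixelSpacing is (row, col) = (y, x)
    return CTVolume(values, spacing, tuple(origin))


def _write_dicom_series(volume: CTVolume, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    stored = np.round(np.asarray(volume.values, dtype=np.float64)) + 1024.0
    stored = np.clip(stored, 0, 65535).astype(np.uint16)
    series_uid = generate_uid()
    study_uid = generate_uid()
    nx, ny, nz = volume.shape
    for k in range(nz):
        ds = Dataset()
        ds.file_meta = FileMetaDataset()
        ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta.MediaStorageSOPClassUID = CTImageStorage
        ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.Modality = "CT"
        ds.InstanceNumber = k + 1
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [
            volume.origin_mm[0],
            volume.origin_mm[1],
            volume.origin_mm[2] + k * volume.spacing_mm[2],
        ]
        ds.PixelSpacing = [volume.spacing_mm[1], volume.spacing_mm[0]]
        ds.SliceThickness = volume.spacing_mm[2]
        ds.Rows, ds.Columns = ny, nx
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = 1
        ds.RescaleIntercept = -1024
        ds.PixelData = np.ascontiguousarray(stored[:, :, k].T).tobytes()  # (rows, cols)
        ds.save_as(str(path / f"slice_{k:04d}.dcm"), enforce_file_format=True)
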