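"""CT volume containers, file I/O, and stored-value scaling conventions.

A CT slice is stored as 12-bit integer "stored values" in [0, 4095]
(Hounsfield units are stored value plus a rescale intercept, typically
-1024).  The generative models traffic in real-valued images on one of
two scales:

``signed_unit``
    [-1, 1], the network input/output range: ``x' = x / 2047.5 - 1``.
``unit``
    [0, 1], used for residual (difference-image) arithmetic:
    ``x = stored / 4095``.

Both maps send the range endpoints to the scale endpoints exactly, and
``unit = (signed_unit + 1) / 2`` holds as an algebraic identity.  All
scaling arithmetic is done in float64; stored values are integers.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np

STORED_MAX = 4095
_SIGNED_DIVISOR = STORED_MAX / 2.0  # 2047.5: maps 0 -> -1 and 4095 -> +1

ScaleTag = Literal["signed_unit", "unit"]


def round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves away from zero (platform-stable)."""
    x = np.asarray(x, dtype=np.float64)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass(frozen=True)
class CTVolume:
    """A 3D stack of CT slices with acquisition geometry.

    Parameters
    ----------
    voxels : ndarray of int, shape (slices, rows, cols)
        Stored values in [0, 4095].  Slice index 0 is the lowest
        position along the slice axis.
    thickness : float
        Slice thickness in mm (axial extent averaged into one slice).
    interval : float
        Scanning interval in mm (distance between consecutive slice
        positions).  Equal to ``thickness`` for standard acquisition.
    pixel_spacing : (float, float)
        In-plane (row, col) spacing in mm.
    rescale_intercept : float
        HU offset metadata; stored values are not shifted by it.
    source_id : str
        Free-form provenance identifier.
    """

    voxels: np.ndarray
    thickness: float
    interval: float
    pixel_spacing: tuple[float, float] = (0.5, 0.5)
    rescale_intercept: float = -1024.0
    source_id: str = ""

    def __post_init__(self):
        v = np.asarray(self.voxels)
        if v.ndim != 3:
            raise ValueError(f"voxels must be 3D (slices, rows, cols), got shape {v.shape}")
        if v.size == 0:
            raise ValueError("empty volume")
        if not np.issubdtype(v.dtype, np.integer):
            raise TypeError(f"stored values must be integers, got dtype {v.dtype}")
        if v.min() < 0 or v.max() > STORED_MAX:
            raise ValueError(
                f"stored values must lie in [0, {STORED_MAX}]; got "
                f"[{v.min()}, {v.max()}]"
            )
        if self.thickness <= 0 or self.interval <= 0:
            raise ValueError("thickness and interval must be positive")
        object.__setattr__(self, "voxels", v.astype(np.uint16))

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def slice(self, idx: int) -> np.ndarray:
        return self.voxels[idx]

    def with_voxels(self, voxels: np.ndarray, **changes) -> "CTVolume":
        return replace(self, voxels=voxels, **changes)


@dataclass(frozen=True)
class NormalizedImage:
    """A 2D real-valued image tagged with its scale convention."""

    array: np.ndarray
    scale: ScaleTag

    def __post_init__(self):
        a = np.asarray(self.array, dtype=np.float64)
        if a.ndim != 2:
            raise ValueError("NormalizedImage is 2D")
        lo, hi = (-1.0, 1.0) if self.scale == "signed_unit" else (0.0, 1.0)
        if a.size and (a.min() < lo - 1e-12 or a.max() > hi + 1e-12):
            raise ValueError(f"values outside [{lo}, {hi}] for scale {self.scale!r}")
        object.__setattr__(self, "array", a)


# ---------------------------------------------------------------------------
# Scaling operations
# ---------------------------------------------------------------------------

def _check_stored(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.size and (x.min() < 0 or x.max() > STORED_MAX):
        raise ValueError(f"stored values must lie in [0, {STORED_MAX}]")
    return x


def to_signed_unit(stored: np.ndarray) -> NormalizedImage:
    """Map stored values [0, 4095] onto [-1, 1]: ``x / 2047.5 - 1``."""
    x = _check_stored(stored)
    return NormalizedImage(x / _SIGNED_DIVISOR - 1.0, "signed_unit")


def to_unit(stored: np.ndarray) -> NormalizedImage:
    """Map stored values [0, 4095] onto [0, 1]: ``x / 4095``."""
    x = _check_stored(stored)
    return NormalizedImage(x / STORED_MAX, "unit")


def from_signed_unit(img: NormalizedImage | np.ndarray) -> np.ndarray:
    """Map [-1, 1] back to integer stored values, clipping overshoot.

    ``stored = round(clip((x' + 1) * 2047.5, 0, 4095))``.  Model output
    may leave [-1, 1] slightly; clipping absorbs it.
    """
    a = img.array if isinstance(img, NormalizedImage) else np.asarray(img, dtype=np.float64)
    stored = round_half_away(np.clip((a + 1.0) * _SIGNED_DIVISOR, 0, STORED_MAX))
    return stored.astype(np.uint16)


def from_unit(img: NormalizedImage | np.ndarray) -> np.ndarray:
    """Map [0, 1] back to integer stored values, clipping overshoot."""
    a = img.array if isinstance(img, NormalizedImage) else np.asarray(img, dtype=np.float64)
    stored = round_half_away(np.clip(a, 0.0, 1.0) * STORED_MAX)
    return stored.astype(np.uint16)


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------

def _write_nifti(volume: CTVolume, path: Path) -> None:
    import nibabel as nib

    # NIfTI axis order (i, j, k) = (col, row, slice)
    data = np.ascontiguousarray(volume.voxels.T.astype(np.int16))
    ps_r, ps_c = volume.pixel_spacing
    affine = np.diag([ps_c, ps_r, volume.interval, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((ps_c, ps_r, volume.interval))
    nib.save(img, str(path))


def _read_nifti(path: Path) -> CTVolume:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3D NIfTI, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError("missing or non-positive voxel spacing in NIfTI header")
    voxels = np.clip(data.T, 0, STORED_MAX).astype(np.uint16)
    return CTVolume(
        voxels=voxels,
        thickness=float(zooms[2]),
        interval=float(zooms[2]),
        pixel_spacing=(float(zooms[1]), float(zooms[0])),
        source_id=os.fspath(path),
    )


# ---------------------------------------------------------------------------
# DICOM series (one file per slice; geometry + pixel module subset)
# ---------------------------------------------------------------------------

def _write_dicom_series(volume: CTVolume, directory: Path) -> None:
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    directory.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    for idx in range(volume.n_slices):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian

        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.PatientID = volume.source_id or "phantom"
        ds.PatientName = ds.PatientID
        ds.InstanceNumber = idx + 1
        ds.ImagePositionPatient = [0.0, 0.0, idx * volume.interval]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.SliceThickness = volume.thickness
        ds.SpacingBetweenSlices = volume.interval
        ds.PixelSpacing = [volume.pixel_spacing[0], volume.pixel_spacing[1]]
        ds.RescaleIntercept = volume.rescale_intercept
        ds.RescaleSlope = 1.0
        ds.Rows, ds.Columns = volume.voxels.shape[1:]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 12
        ds.HighBit = 11
        ds.PixelRepresentation = 0  # unsigned
        ds.PixelData = volume.voxels[idx].astype("<u2").tobytes()
        ds.save_as(directory / f"slice_{idx:04d}.dcm", enforce_file_format=True)


def _read_dicom_series(directory: Path) -> CTVolume:
    import pydicom

    files = sorted(p for p in directory.iterdir() if p.suffix.lower() == ".dcm")
    if not files:
        raise FileNotFoundError(f"no .dcm files in {directory}")
    datasets = [pydicom.dcmread(f) for f in files]

    first = datasets[0]
    for ds in datasets:
        if ds.SeriesInstanceUID != first.SeriesInstanceUID:
            raise ValueError("mixed series in one directory")
        if (ds.Rows, ds.Columns) != (first.Rows, first.Columns):
            raise ValueError("mixed in-plane dimensions in series")
        if "PixelSpacing" not in ds:
            raise ValueError("missing PixelSpacing; refusing to guess geometry")
        if list(ds.PixelSpacing) != list(first.PixelSpacing):
            raise ValueError("mixed pixel spacing in series")

    # order by position along the slice axis, not by filename
    datasets.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    voxels = np.stack([
        np.clip(ds.pixel_array, 0, STORED_MAX).astype(np.uint16) for ds in datasets
    ])
    if len(datasets) > 1:
        zs = [float(ds.ImagePositionPatient[2]) for ds in datasets]
        interval = float(np.mean(np.diff(zs)))
    else:
        interval = float(getattr(first, "SpacingBetweenSlices", first.SliceThickness))
    if interval <= 0:
        raise ValueError("non-positive scanning interval in series")
    return CTVolume(
        voxels=voxels,
        thickness=float(first.SliceThickness),
        interval=interval,
        pixel_spacing=(float(first.PixelSpacing[0]), float(first.PixelSpacing[1])),
        rescale_intercept=float(getattr(first, "RescaleIntercept", -1024.0)),
        source_id=str(directory),
    )


# ---------------------------------------------------------------------------
# Public I/O surface
# ---------------------------------------------------------------------------

def write_volume(volume: CTVolume, path: str | Path, format: str | None = None) -> None:
    """Write a volume as NIfTI (``.nii``/``.nii.gz``) or a DICOM series.

    ``format`` is inferred from the path when omitted: a ``.nii``/
    ``.nii.gz`` suffix selects NIfTI, otherwise a DICOM series directory
    is written.
    """
    path = Path(path)
    fmt = format or ("nifti" if path.name.endswith((".nii", ".nii.gz")) else "dicom_series")
    if fmt == "nifti":
        path.parent.mkdir(parents=True, exist_ok=True)
        _write_nifti(volume, path)
    elif fmt == "dicom_series":
        _write_dicom_series(volume, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_volume(path: str | Path, format: str | None = None) -> CTVolume:
    """Read a volume written by :func:`write_volume` (or compatible).

    Slices are ordered by ascending position along the slice axis;
    stored values are clipped into [0, 4095].
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("nifti" if path.is_file() else "dicom_series")
    if fmt == "nifti":
        return _read_nifti(path)
    if fmt == "dicom_series":
        return _read_dicom_series(path)
    raise ValueError(f"unknown format {fmt!r}")


def export_png(slice2d: np.ndarray, path: str | Path,
               window: float = 4095.0, level: float = 2047.5) -> None:
    """Render one slice to an 8-bit PNG with a window/level transform."""
    from PIL import Image

    x = np.asarray(slice2d, dtype=np.float64)
    lo = level - window / 2.0
    y = np.clip((x - lo) / window, 0.0, 1.0)
    Image.fromarray((y * 255.0 + 0.5).astype(np.uint8)).save(os.fspath(path))
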