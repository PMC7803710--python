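"""Reading and writing of volumes and surfaces.

NIfTI-1 (single file, exact voxel round-trip) is the working format; DICOM
series directories are the export format for downstream 3D-rendering
viewers; bone masks are NIfTI with values {0, 1}; surfaces are binary STL.

Geometry is never invented: a DICOM series without orientation tags is a
hard error, and all writers round-trip spacing within 1e-4 mm and
orientation within 1e-6.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
import SimpleITK as sitk
import trimesh
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
from skimage import measure

from .core import BinaryMask, GeometryError, Grid, ImageVolume

log = logging.getLogger(__name__)

#: nibabel affines are RAS; the package convention is LPS (DICOM)
_RAS_FROM_LPS = np.diag([-1.0, -1.0, 1.0, 1.0])


class IOError_(OSError):
    """Raised for unreadable/unwritable volumes or inconsistent series."""


@dataclass
class SeriesMetadata:
    """Descriptive and geometric metadata carried alongside a volume."""

    patient_id: str = "ANON"
    modality: str = "OT"
    series_description: str = "ztebone derived volume"
    spacing: tuple[float, float, float] | None = None
    direction: np.ndarray | None = None
    rescale_slope: float = 1.0
    rescale_intercept: float = 0.0


def _lps_affine(grid: Grid) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = grid.direction @ np.diag(grid.spacing)
    aff[:3, 3] = grid.origin
    return aff


def _grid_from_lps_affine(aff: np.ndarray, shape) -> Grid:
    m = aff[:3, :3]
    spacing = np.linalg.norm(m, axis=0)
    direction = m / spacing
    return Grid(shape=tuple(int(s) for s in shape[:3]),
                spacing=tuple(spacing), origin=tuple(aff[:3, 3]),
                direction=direction)


# --------------------------------------------------------------------------- #
# reading
# --------------------------------------------------------------------------- #

def read_volume(path, kind: str = "auto",
                modality: str = "DERIVED") -> tuple[ImageVolume, SeriesMetadata]:
    """Read a NIfTI file or DICOM series directory into an ImageVolume.

    DICOM slices are sorted by position along the slice normal (never by
    filename); a directory holding more than one series is an explicit error
    listing the series UIDs.
    """
    path = Path(path)
    if not path.exists():
        raise IOError_(f"no such path: {path}")
    if kind == "auto":
        kind = "dicom_dir" if path.is_dir() else "nifti"
    if kind == "nifti":
        return _read_nifti(path, modality)
    if kind == "dicom_dir":
        return _read_dicom_dir(path, modality)
    raise ValueError(f"unknown kind {kind!r}")


def _read_nifti(path: Path, modality: str) -> tuple[ImageVolume, SeriesMetadata]:
    img = nib.load(str(path))
    voxels = np.asanyarray(img.dataobj)
    if voxels.ndim == 4 and voxels.shape[3] == 1:
        voxels = voxels[..., 0]
    if voxels.ndim != 3:
        raise IOError_(f"expected a 3D volume, got shape {voxels.shape}")
    aff_lps = _RAS_FROM_LPS @ img.affine
    grid = _grid_from_lps_affine(aff_lps, voxels.shape)
    vol = ImageVolume(np.ascontiguousarray(voxels), grid, modality)
    meta = SeriesMetadata(spacing=grid.spacing, direction=grid.direction,
                          series_description=str(path.name))
    return vol, meta


def _read_dicom_dir(path: Path, modality: str) -> tuple[ImageVolume, SeriesMetadata]:
    reader = sitk.ImageSeriesReader()
    series_ids = reader.GetGDCMSeriesIDs(str(path))
    if not series_ids:
        raise IOError_(f"no DICOM series found in {path}")
    if len(series_ids) > 1:
        raise IOError_("directory contains multiple DICOM series: "
                       + ", ".join(series_ids))
    files = reader.GetGDCMSeriesFileNames(str(path), series_ids[0])
    first = pydicom.dcmread(files[0], stop_before_pixels=True)
    if "ImageOrientationPatient" not in first:
        raise IOError_("DICOM series lacks ImageOrientationPatient; "
                       "refusing to invent an orientation")
    reader.SetFileNames(files)
    img = reader.Execute()
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0).astype(np.float32)
    grid = Grid(shape=tuple(img.GetSize()), spacing=tuple(img.GetSpacing()),
                origin=tuple(img.GetOrigin()),
                direction=np.asarray(img.GetDirection()).reshape(3, 3))
    vol = ImageVolume(arr, grid, modality)
    meta = SeriesMetadata(
        patient_id=str(getattr(first, "PatientID", "ANON")),
        modality=str(getattr(first, "Modality", "OT")),
        series_description=str(getattr(first, "SeriesDescription", "")),
        spacing=grid.spacing, direction=grid.direction,
        rescale_slope=float(getattr(first, "RescaleSlope", 1.0)),
        rescale_intercept=float(getattr(first, "RescaleIntercept", 0.0)))
    return vol, meta


# --------------------------------------------------------------------------- #
# writing
# --------------------------------------------------------------------------- #

def write_volume(volume: ImageVolume | BinaryMask, path,
                 kind: str = "auto", meta: SeriesMetadata | None = None) -> None:
    """Write a volume (or mask, as {0,1}) to NIfTI or a DICOM series dir."""
    path = Path(path)
    if kind == "auto":
        kind = "nifti" if path.suffix in (".nii", ".gz") or str(path).endswith(".nii.gz") \
            else "dicom_dir"
    if isinstance(volume, BinaryMask):
        volume = ImageVolume(volume.voxels.astype(np.uint8), volume.grid, "DERIVED")
    if kind == "nifti":
        _write_nifti(volume, path)
    elif kind == "dicom_dir":
        _write_dicom_dir(volume, path, meta or SeriesMetadata())
    else:
        raise ValueError(f"unknown kind {kind!r}")


def _write_nifti(volume: ImageVolume, path: Path) -> None:
    aff_ras = _RAS_FROM_LPS @ _lps_affine(volume.grid)
    data = volume.voxels
    if data.dtype not in (np.uint8, np.int16, np.float32):
        data = data.astype(np.float32)
    img = nib.Nifti1Image(data, aff_ras)
    img.header.set_zooms(volume.grid.spacing)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))


def dicom_rescale(voxels: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Map intensities onto 16-bit storage: stored = (v - intercept)/slope.

    The slope/intercept are chosen so the maximum maps to 32767; applying the
    recorded slope/intercept recovers intensities within one quantisation
    step.
    """
    lo, hi = float(voxels.min()), float(voxels.max())
    slope = (hi - lo) / 32767.0 if hi > lo else 1.0
    intercept = lo
    stored = np.rint((voxels - intercept) / slope).astype(np.int32)
    if stored.min() < -32768 or stored.max() > 32767:
        raise IOError_("intensity range exceeds 16-bit storage after rescale")
    return stored.astype(np.int16), slope, intercept


def _write_dicom_dir(volume: ImageVolume, path: Path,
                     meta: SeriesMetadata) -> None:
    path.mkdir(parents=True, exist_ok=True)
    stored, slope, intercept = dicom_rescale(np.asarray(volume.voxels, dtype=np.float64))
    grid = volume.grid
    content_hash = hashlib.sha256(stored.tobytes()).hexdigest()
    series_uid = generate_uid(entropy_srcs=[content_hash, "series"])
    study_uid = generate_uid(entropy_srcs=[content_hash, "study"])
    frame_uid = generate_uid(entropy_srcs=[content_hash, "frame"])
    row_dir = grid.direction[:, 0]      # direction of increasing column index = x
    col_dir = grid.direction[:, 1]

    nz = grid.shape[2]
    for k in range(nz):
        ds = Dataset()
        ds.SOPClassUID = pydicom.uid.SecondaryCaptureImageStorage
        ds.SOPInstanceUID = generate_uid(entropy_srcs=[content_hash, f"slice{k}"])
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.PatientID = meta.patient_id
        ds.PatientName = meta.patient_id
        ds.Modality = meta.modality
        ds.SeriesDescription = meta.series_description
        ds.InstanceNumber = k + 1
        ds.ImageOrientationPatient = [float(v) for v in np.concatenate([row_dir, col_dir])]
        pos = grid.index_to_physical((0, 0, k))
        ds.ImagePositionPatient = [float(v) for v in pos]
        ds.SliceThickness = float(grid.spacing[2])
        ds.SpacingBetweenSlices = float(grid.spacing[2])
        ds.PixelSpacing = [float(grid.spacing[1]), float(grid.spacing[0])]  # row, col
        ds.RescaleSlope = slope
        ds.RescaleIntercept = intercept
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        sl = np.ascontiguousarray(stored[:, :, k].T)   # rows = y, cols = x
        ds.Rows, ds.Columns = sl.shape
        ds.PixelData = sl.tobytes()

        fm = FileMetaDataset()
        fm.TransferSyntaxUID = ExplicitVRLittleEndian
        fm.MediaStorageSOPClassUID = ds.SOPClassUID
        fm.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        ds.file_meta = fm
        pydicom.dcmwrite(str(path / f"slice_{k:04d}.dcm"), ds,
                         enforce_file_format=True)


# --------------------------------------------------------------------------- #
# surface export
# --------------------------------------------------------------------------- #

def mask_to_mesh(mask: BinaryMask, smoothing_iters: int = 0) -> trimesh.Trimesh:
    """Triangulate the 0.5-level surface of a mask in physical coordinates."""
    if mask.count == 0:
        raise ValueError("cannot mesh an empty mask")
    padded = np.pad(mask.voxels.astype(np.float32), 1)
    verts, faces, _, _ = measure.marching_cubes(
        padded, level=0.5, spacing=mask.grid.spacing)
    shift = np.asarray(mask.grid.spacing)  # undo the one-voxel pad
    verts_phys = (verts - shift) @ mask.grid.direction.T + np.asarray(mask.grid.origin)
    mesh = trimesh.Trimesh(vertices=verts_phys, faces=faces, process=False)
    if smoothing_iters > 0:
        trimesh.smoothing.filter_taubin(mesh, iterations=int(smoothing_iters))
    return mesh


def export_mesh(mask: BinaryMask, path, smoothing_iters: int = 0) -> int:
    """Write a binary STL of the mask surface; returns the triangle count.

    Smoothing defaults to 0: heavy smoothing improves aesthetics at the cost
    of geometric accuracy, so it is opt-in.
    """
    mesh = mask_to_mesh(mask, smoothing_iters)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    mesh.export(str(path), file_type="stl")
    return int(len(mesh.faces))
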