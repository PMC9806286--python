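"""Reading and writing the pipeline's standard formats.

DICOM series in and out (one file per slice, geometry from PixelSpacing /
SliceThickness / SpacingBetweenSlices), binary masks as NIfTI, cohort tables
as CSV.  Every linear DICOM attribute is millimetres; it is converted to the
package's internal centimetre convention exactly once, here.  Slice index 0
is the first slice in ascending order along the slicing axis; indices are
0-based throughout.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, MRImageStorage, generate_uid

from .records import CSV_COLUMNS, SubjectRecord

logger = logging.getLogger(__name__)

MM_PER_CM = 10.0

MASK_LABELS = ("spleen", "L1_body", "spinal_canal", "abdomen")


@dataclass
class ImageSeries:
    """An ordered stack of 2-D intensity slices with geometry in cm.

    ``pixels`` has shape (n_slices, rows, cols); rows run along the
    anterior–posterior image axis (spacing ``dy``), columns along the
    left–right axis (spacing ``dx``).  ``d`` is the center-to-center slice
    spacing: slice thickness plus inter-slice gap.
    """

    pixels: np.ndarray
    dx: float
    dy: float
    slice_thickness: float
    slice_gap: float = 0.0
    subject_id: str = ""
    z_positions: Optional[np.ndarray] = None  # slice-center z (cm), ascending
    provenance: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3:
            raise ValueError("pixels must be a (n_slices, rows, cols) stack")
        if self.dx <= 0 or self.dy <= 0 or self.slice_thickness <= 0:
            raise ValueError("pixel spacing and slice thickness must be positive")
        if self.slice_gap < 0:
            raise ValueError("slice_gap must be non-negative")
        if self.z_positions is not None:
            self.z_positions = np.asarray(self.z_positions, dtype=float)
            if len(self.z_positions) != self.n_slices:
                raise ValueError("z_positions length must match slice count")
            if self.n_slices > 1 and np.any(np.diff(self.z_positions) <= 0):
                raise ValueError("z_positions must be strictly ascending")
        if abs(self.dx - self.dy) > 0.01 * self.dx:
            logger.warning(
                "anisotropic in-plane spacing dx=%g, dy=%g cm", self.dx, self.dy
            )

    @property
    def n_slices(self) -> int:
        return self.pixels.shape[0]

    @property
    def d(self) -> float:
        """Center-to-center slice spacing (cm)."""
        return self.slice_thickness + self.slice_gap

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape


@dataclass
class SegmentationMask:
    """Binary voxel mask congruent with an :class:`ImageSeries`."""

    data: np.ndarray
    label: str = "spleen"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be a (n_slices, rows, cols) stack")
        if self.label not in MASK_LABELS:
            raise ValueError(f"label must be one of {MASK_LABELS}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def check_congruent(mask: SegmentationMask, series: ImageSeries) -> None:
    if mask.shape != series.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match series shape {series.shape}"
        )


# ---------------------------------------------------------------------------
# DICOM


def write_dicom_series(series: ImageSeries, directory: str | Path) -> list[Path]:
    """Write one DICOM file per slice with geometry metadata in mm."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    zs = series.z_positions
    if zs is None:
        zs = np.arange(series.n_slices) * series.d
    pixels = np.ascontiguousarray(series.pixels.astype(np.uint16))

    paths = []
    for k in range(series.n_slices):
        ds = Dataset()
        ds.file_meta = FileMetaDataset()
        ds.file_meta.MediaStorageSOPClassUID = MRImageStorage
        ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
        ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.SOPClassUID = MRImageStorage
        ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.Modality = "MR"
        ds.PatientID = series.subject_id or "anon"
        ds.SeriesNumber = 1
        ds.InstanceNumber = k + 1
        ds.Rows, ds.Columns = pixels.shape[1:]
        # DICOM PixelSpacing is (row spacing, column spacing) in mm
        ds.PixelSpacing = [series.dy * MM_PER_CM, series.dx * MM_PER_CM]
        ds.SliceThickness = series.slice_thickness * MM_PER_CM
        ds.SpacingBetweenSlices = series.d * MM_PER_CM
        ds.ImagePositionPatient = [0.0, 0.0, float(zs[k]) * MM_PER_CM]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.SliceLocation = float(zs[k]) * MM_PER_CM
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.PixelData = pixels[k].tobytes()
        path = directory / f"slice_{k:04d}.dcm"
        pydicom.dcmwrite(path, ds, enforce_file_format=True)
        paths.append(path)
    return paths


def read_dicom_series(directory: str | Path) -> ImageSeries:
    """Read one coherent single-frame series from a directory.

    Slices are sorted by position along the normal.  The center-to-center
    spacing tag (SpacingBetweenSlices), when present, takes precedence as d;
    otherwise d comes from the inter-position spacing; otherwise d falls back
    to the slice thickness with a logged warning.  All mm are converted to cm.
    """
    directory = Path(directory)
    files = sorted(directory.glob("*.dcm")) or sorted(
        p for p in directory.iterdir() if p.is_file()
    )
    if not files:
        raise FileNotFoundError(f"no DICOM files in {directory}")
    datasets = [pydicom.dcmread(str(p)) for p in files]

    uids = {str(getattr(ds, "SeriesInstanceUID", "<missing>")) for ds in datasets}
    if len(uids) != 1:
        raise ValueError(f"directory mixes multiple series: {sorted(uids)}")

    def z_of(ds: Dataset) -> float:
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=z_of)
    first = datasets[0]
    if not hasattr(first, "PixelSpacing"):
        raise ValueError("series is missing PixelSpacing metadata")
    dy = float(first.PixelSpacing[0]) / MM_PER_CM
    dx = float(first.PixelSpacing[1]) / MM_PER_CM
    thickness = float(getattr(first, "SliceThickness", 0.0)) / MM_PER_CM

    zs_mm = np.array([z_of(ds) for ds in datasets], dtype=float)
    d = None
    if hasattr(first, "SpacingBetweenSlices"):
        d = float(first.SpacingBetweenSlices) / MM_PER_CM
    elif len(datasets) > 1:
        d = float(np.median(np.diff(zs_mm))) / MM_PER_CM
    elif thickness > 0:
        d = thickness
        logger.warning("single slice without spacing tag: using d = slice thickness")
    if d is None or d <= 0:
        raise ValueError("cannot determine slice spacing d from metadata")

    if len(datasets) > 1:
        deltas = np.diff(zs_mm) / MM_PER_CM
        if np.any(np.abs(deltas - d) > 0.01 * d):
            raise ValueError(
                f"inconsistent inter-slice distances {np.round(deltas, 4)} cm "
                f"vs d = {d} cm (beyond 1% tolerance)"
            )

    if thickness <= 0:
        thickness = d
        logger.warning("missing SliceThickness: assuming thickness = d")
    gap = max(d - thickness, 0.0)
    pixels = np.stack([ds.pixel_array for ds in datasets])
    return ImageSeries(
        pixels=pixels,
        dx=dx,
        dy=dy,
        slice_thickness=thickness,
        slice_gap=gap,
        subject_id=str(getattr(first, "PatientID", "")),
        z_positions=zs_mm / MM_PER_CM,
        provenance=f"DICOM:{directory}",
    )


# ---------------------------------------------------------------------------
# NIfTI masks


def write_mask(mask: SegmentationMask, path: str | Path, series: ImageSeries) -> Path:
    """Write a binary mask as NIfTI with voxel sizes (mm) from the series."""
    check_congruent(mask, series)
    path = Path(path)
    affine = np.diag(
        [series.dx * MM_PER_CM, series.dy * MM_PER_CM, series.d * MM_PER_CM, 1.0]
    )
    # store as (cols, rows, slices) so the affine's voxel sizes are (dx, dy, d)
    data = np.transpose(mask.data.astype(np.uint8), (2, 1, 0))
    nib.save(nib.Nifti1Image(data, affine), str(path))
    return path


def read_mask(
    path: str | Path, series: Optional[ImageSeries] = None, label: str = "spleen"
) -> SegmentationMask:
    """Read a NIfTI mask; verifies congruence when a series is given."""
    img = nib.load(str(path))
    data = np.transpose(np.asarray(img.dataobj), (2, 1, 0)) > 0
    mask = SegmentationMask(data=data, label=label)
    if series is not None:
        check_congruent(mask, series)
    return mask


# ---------------------------------------------------------------------------
# cohort CSV


def write_cohort_csv(records: list[SubjectRecord], path: str | Path) -> Path:
    """Write subject records to CSV, canonically sorted, missing as empty.

    Raises on duplicate (subject, rater) keys — each rater contributes at
    most one measurement row per subject.
    """
    df = pd.DataFrame([r.to_dict() for r in records], columns=CSV_COLUMNS)
    dup = df.duplicated(subset=["subject_id", "rater_id"])
    if dup.any():
        keys = df.loc[dup, ["subject_id", "rater_id"]].to_records(index=False).tolist()
        raise ValueError(f"duplicate (subject, rater) rows: {keys}")
    df = df.sort_values(["subject_id", "rater_id"], kind="stable").reset_index(drop=True)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, na_rep="")
    return path


def read_cohort_csv(path: str | Path) -> list[SubjectRecord]:
    """Read subject records; empty cells come back as missing, never zero."""
    df = pd.read_csv(path, dtype={"subject_id": str, "rater_id": str})
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV is missing columns: {sorted(missing)}")
    dup = df.duplicated(subset=["subject_id", "rater_id"])
    if dup.any():
        keys = df.loc[dup, ["subject_id", "rater_id"]].to_records(index=False).tolist()
        raise ValueError(f"duplicate (subject, rater) rows: {keys}")
    records = []
    for _, row in df.iterrows():
        records.append(SubjectRecord.from_dict(row.to_dict()))
    return records


def cohort_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """Records as a DataFrame in canonical column order."""
    return pd.DataFrame([r.to_dict() for r in records], columns=CSV_COLUMNS)
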