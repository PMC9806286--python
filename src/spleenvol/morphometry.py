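"""Single-slice morphometry: boundary circumference, AP/transverse
diameters, region areas, and craniocaudal spleen length.

These are the measurements taken on one axial slice at the L1 vertebral
level (abdomen and vertebral metrics) plus the spleen's slice-count length
— the candidate shortcuts the cohort regression weighs against the full
Cavalieri volume.
"""
from __future__ import annotations

import logging
import math

import numpy as np
from scipy import ndimage

from .imaging_io import ImageSeries, SegmentationMask, check_congruent

logger = logging.getLogger(__name__)

# Interior pixels keep their full 4-neighbourhood inside; the complement is
# the outer contour, which is one pixel wide and 8-connected as a curve.
_EROSION_STRUCT = ndimage.generate_binary_structure(2, 1)


def _pixel_length(dx: float, dy: float) -> float:
    # A single "pixel length" only exists for isotropic pixels; fall back to
    # the geometric mean and warn when they differ by more than 1%.
    if abs(dx - dy) <= 0.01 * dx:
        return dx
    logger.warning(
        "anisotropic pixels dx=%g, dy=%g cm: using sqrt(dx*dy) as pixel length",
        dx,
        dy,
    )
    return math.sqrt(dx * dy)


def boundary_circumference(mask_slice: np.ndarray, dx: float, dy: float) -> float:
    """Circumference (cm) from the one-pixel-wide outer boundary.

    Holes are filled first so only the outer contour counts; the boundary is
    the mask minus its one-pixel erosion, which is exactly one pixel wide and
    8-connected as a curve.  Circumference = boundary pixel count × pixel
    length.  Pixel-count perimeters of rasterized shapes carry a known
    shape-dependent bias relative to the true Euclidean perimeter (about
    −11% on a disk at typical resolutions; exact on axis-aligned squares).
    """
    mask_slice = np.asarray(mask_slice).astype(bool)
    if not mask_slice.any():
        logger.warning("boundary_circumference: empty mask slice")
        return 0.0
    filled = ndimage.binary_fill_holes(mask_slice)
    eroded = ndimage.binary_erosion(filled, structure=_EROSION_STRUCT, border_value=0)
    boundary = filled & ~eroded
    return float(np.count_nonzero(boundary)) * _pixel_length(dx, dy)


def axis_diameters(mask_slice: np.ndarray, dx: float, dy: float) -> tuple[float, float]:
    """(AP, transverse) diameters (cm) as tight bounding-box extents.

    AP runs along image rows (spacing dy), transverse along columns (dx);
    in supine axial imaging these are the anatomical axes.  The extent is
    (max − min + 1) occupied pixels times the spacing.
    """
    mask_slice = np.asarray(mask_slice).astype(bool)
    if not mask_slice.any():
        raise ValueError("axis_diameters: empty mask slice")
    rows = np.nonzero(mask_slice.any(axis=1))[0]
    cols = np.nonzero(mask_slice.any(axis=0))[0]
    ap = (rows[-1] - rows[0] + 1) * dy
    tv = (cols[-1] - cols[0] + 1) * dx
    return float(ap), float(tv)


def region_area(mask_slice: np.ndarray, dx: float, dy: float) -> float:
    """Area (cm²) of a single-slice region: pixel count × pixel area.

    The same computation as the stereology slice area, applied to L1-body
    and spinal-canal masks; it does not depend on the region's label.
    """
    mask_slice = np.asarray(mask_slice)
    return float(np.count_nonzero(mask_slice)) * dx * dy


def spleen_length(mask: SegmentationMask, series: ImageSeries) -> float:
    """Craniocaudal spleen length (cm): slices with spleen present × d.

    A slice-count extent, per the usual radiological convention for axial
    stacks; on a convex organ aligned with the slicing axis the error is at
    most one slice spacing.
    """
    check_congruent(mask, series)
    n = int(np.count_nonzero(mask.data.reshape(mask.data.shape[0], -1).any(axis=1)))
    if n == 0:
        raise ValueError("spleen_length: empty mask")
    return n * series.d
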