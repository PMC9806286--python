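"""Intensity-threshold segmentation within a region of interest.

The original workflow segmented the spleen manually; this module is its
scriptable stand-in — threshold inside an operator-supplied ROI, then keep
the largest connected component.  A fully manual mask can always be supplied
through imaging_io instead.
"""
from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Optional, Union

import numpy as np
from scipy import ndimage
from skimage.draw import polygon2mask
from skimage.filters import threshold_otsu

from .imaging_io import ImageSeries, SegmentationMask

logger = logging.getLogger(__name__)

# ROI forms: None (whole image), a rectangle (r0, c0, r1, c1) half-open in
# pixel coordinates applied to every slice, a polygon [(r, c), ...], or a
# {slice_index: rectangle-or-polygon} mapping (slices absent -> excluded).
Rect = tuple[int, int, int, int]
Polygon = list[tuple[float, float]]
ROI = Optional[Union[Rect, Polygon, dict]]


def _slice_roi_mask(shape: tuple[int, int], roi) -> np.ndarray:
    if roi is None:
        return np.ones(shape, dtype=bool)
    roi = list(roi)
    if len(roi) == 4 and all(np.isscalar(v) for v in roi):
        r0, c0, r1, c1 = (int(v) for v in roi)
        if not (0 <= r0 < r1 <= shape[0] and 0 <= c0 < c1 <= shape[1]):
            raise ValueError(f"rectangle {roi} outside raster bounds {shape}")
        m = np.zeros(shape, dtype=bool)
        m[r0:r1, c0:c1] = True
        return m
    verts = np.asarray(roi, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 3:
        raise ValueError("polygon ROI needs >= 3 (row, col) vertices")
    if verts.min() < -0.5 or (verts[:, 0] > shape[0] - 0.5).any() or (
        verts[:, 1] > shape[1] - 0.5
    ).any():
        raise ValueError("polygon ROI outside raster bounds")
    return polygon2mask(shape, verts)


def roi_mask(series: ImageSeries, roi: ROI) -> np.ndarray:
    """Expand an ROI description into a boolean stack congruent with the series."""
    n, rows, cols = series.shape
    if roi is None or not isinstance(roi, dict):
        one = _slice_roi_mask((rows, cols), roi)
        return np.broadcast_to(one, (n, rows, cols)).copy()
    out = np.zeros((n, rows, cols), dtype=bool)
    for key, slice_roi in roi.items():
        k = int(key)
        if not 0 <= k < n:
            raise ValueError(f"ROI slice index {k} outside [0, {n})")
        out[k] = _slice_roi_mask((rows, cols), slice_roi)
    return out


def load_roi_json(path: str | Path) -> ROI:
    """Load a per-slice ROI sidecar: {"slices": {"0": [r0,c0,r1,c1], ...}}
    or {"all": rect-or-polygon}; pixel coordinates, 0-based."""
    doc = json.loads(Path(path).read_text())
    if "slices" in doc:
        return {int(k): v for k, v in doc["slices"].items()}
    return doc.get("all")


def threshold_segment(
    series: ImageSeries,
    roi: ROI = None,
    low: float = -math.inf,
    high: float = math.inf,
    label: str = "spleen",
) -> SegmentationMask:
    """Voxel in mask iff inside the ROI and low <= intensity <= high."""
    if low > high:
        raise ValueError(f"low {low} exceeds high {high}")
    region = roi_mask(series, roi)
    if not region.any():
        raise ValueError("empty ROI")
    pix = series.pixels.astype(float)
    return SegmentationMask(data=region & (pix >= low) & (pix <= high), label=label)


def auto_threshold(series: ImageSeries, roi: ROI = None) -> tuple[float, float]:
    """Otsu between-class-variance split of the ROI histogram.

    Stands in for the human operator's threshold choice on a bimodal
    organ/background histogram; deterministic for fixed input.  Returns
    (t, max intensity) for use as a [t, ∞)-style band.
    """
    region = roi_mask(series, roi)
    if not region.any():
        raise ValueError("empty ROI")
    values = series.pixels[region].astype(float)
    if values.min() == values.max():
        raise ValueError("constant-intensity ROI: no threshold exists")
    t = float(threshold_otsu(values))
    return t, float(values.max())


def keep_largest_component(
    mask: SegmentationMask, connectivity: int = 3
) -> SegmentationMask:
    """Retain only the largest 3-D connected component (26-connected default).

    Emulates the operator painting only the spleen when the threshold also
    catches nearby structures.  Size ties break toward the component whose
    first voxel comes earliest in (slice, row, col) order, logged.  An empty
    mask passes through with a warning.
    """
    if connectivity not in (1, 2, 3):
        raise ValueError("connectivity must be 1, 2 or 3")
    if not mask.data.any():
        logger.warning("keep_largest_component: empty mask")
        return SegmentationMask(data=mask.data.copy(), label=mask.label)
    structure = ndimage.generate_binary_structure(3, connectivity)
    labels, n = ndimage.label(mask.data, structure=structure)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    best = np.nonzero(sizes == sizes.max())[0] + 1
    if len(best) > 1:
        # tie: earliest first voxel in flat (slice, row, col) order wins
        firsts = [int(np.argmax(labels.ravel() == lab)) for lab in best]
        logger.info("component size tie among labels %s; keeping earliest", list(best))
        keep = int(best[int(np.argmin(firsts))])
    else:
        keep = int(best[0])
    return SegmentationMask(data=labels == keep, label=mask.label)


def segment_organ(
    series: ImageSeries,
    roi: ROI = None,
    low: Optional[float] = None,
    high: float = math.inf,
    label: str = "spleen",
) -> SegmentationMask:
    """Threshold (auto when ``low`` is None) then keep the largest component."""
    if low is None:
        low, _ = auto_threshold(series, roi)
    mask = threshold_segment(series, roi=roi, low=low, high=high, label=label)
    return keep_largest_component(mask)
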