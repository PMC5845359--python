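"""Region-of-interest segmentation.

The ROI restricts where axons are counted.  It comes from one of four
sources: the entire image, automatic segmentation of a dedicated fluorescence
channel (e.g. a labeled cell graft or NeuN-stained grey matter), or a
user-supplied polygon (one or two axon channels).

Automatic detection mirrors the classic particle-analysis recipe: contrast
stretch → global threshold → small-particle removal → hole filling → a
dilate/erode sequence that fuses fragmented graft signal into one continuous
region while pruning fragments too small to merge.  "Enlarge/reduce by N
pixels" is realized as Euclidean-distance morphology (keep every pixel within
inclusive distance N of the set, resp. drop every pixel within N of the
background), which fuses fragments across gaps up to 2·enlarge_px wide and,
with the default enlarge 60 / reduce 90, eliminates isolated fragments of
half-width below 30 px.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import scipy.ndimage as ndi
import shapely
from skimage.filters import threshold_otsu

from .errors import ParameterError, PolygonError
from .image_io import ImageEntry

logger = logging.getLogger("axontracer")

#: fraction of pixels saturated at each tail by the automatic contrast stretch
CONTRAST_SATURATION = 0.0035

#: 8-connected structuring element for foreground component labeling
STRUCT_8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class RoiParams:
    """Parameters of the automatic ROI sequence, shared by every image in a batch.

    enlarge_px / reduce_px are the dilate/erode distances of the merge step
    (defaults 60 and 90); min_particle_px is the debris-removal area floor;
    adjust_px grows (>0) or shrinks (<0) the final ROI by that distance.
    """

    enlarge_px: float = 60.0
    reduce_px: float = 90.0
    min_particle_px: int = 100
    adjust_px: int = 0

    def __post_init__(self) -> None:
        if self.enlarge_px < 0 or self.reduce_px < 0:
            raise ParameterError("enlarge_px and reduce_px must be >= 0")
        if not -255 <= self.adjust_px <= 255:
            raise ParameterError(f"adjust_px must lie in [-255, 255], got {self.adjust_px}")
        if self.min_particle_px < 0:
            raise ParameterError("min_particle_px must be >= 0")


@dataclass
class RoiMask:
    """Binary mask restricting axon detection, with its provenance mode."""

    mask: np.ndarray
    source_mode: str

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ParameterError(f"ROI mask must be 2-D, got shape {self.mask.shape}")

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    @property
    def is_empty(self) -> bool:
        return not self.mask.any()


# ---------------------------------------------------------------------------
# distance morphology

def dilate_by_distance(mask: np.ndarray, distance: float) -> np.ndarray:
    """Add every pixel within inclusive Euclidean distance of the foreground."""
    mask = np.asarray(mask, dtype=bool)
    if distance <= 0 or not mask.any():
        return mask.copy()
    return ndi.distance_transform_edt(~mask) <= distance


def erode_by_distance(mask: np.ndarray, distance: float) -> np.ndarray:
    """Drop every pixel within inclusive Euclidean distance of the background.

    The image border counts as background, as in padded binary erosion.
    """
    mask = np.asarray(mask, dtype=bool)
    if distance <= 0 or not mask.any():
        return mask.copy()
    padded = np.pad(mask, 1, mode="constant", constant_values=False)
    eroded = ndi.distance_transform_edt(padded) > distance
    return eroded[1:-1, 1:-1]


# ---------------------------------------------------------------------------
# automatic ROI pipeline

def preprocess_roi_channel(plane: np.ndarray) -> np.ndarray:
    """Contrast-stretch the ROI channel and binarize it (Otsu).

    The stretch saturates a small fixed fraction of pixels at each tail
    (0.35%), emulating an automatic display-contrast adjustment.  A constant
    plane carries no ROI signal and yields an empty mask.
    """
    plane = np.asarray(plane)
    if plane.ndim != 2:
        raise ParameterError("ROI plane must be single-channel")
    if plane.max() == plane.min():
        return np.zeros(plane.shape, dtype=bool)
    lo, hi = np.percentile(plane, [100 * CONTRAST_SATURATION, 100 * (1 - CONTRAST_SATURATION)])
    if hi <= lo:
        lo, hi = float(plane.min()), float(plane.max())
    stretched = np.clip((plane.astype(np.float64) - lo) / (hi - lo), 0.0, 1.0) * 255.0
    threshold = threshold_otsu(stretched)
    return stretched > threshold


def clean_mask(mask: np.ndarray, min_particle_px: int) -> np.ndarray:
    """Remove components smaller than ``min_particle_px`` and fill interior holes.

    Foreground components are 8-connected; holes are background regions
    4-disconnected from the image border.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    labels, n = ndi.label(mask, structure=STRUCT_8)
    sizes = ndi.sum_labels(np.ones(mask.shape, dtype=np.int64), labels, np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= min_particle_px) + 1
    cleaned = np.isin(labels, keep)
    return ndi.binary_fill_holes(cleaned)


def merge_and_prune(mask: np.ndarray, p: RoiParams) -> np.ndarray:
    """Dilate by enlarge_px then erode by reduce_px.

    Fragments separated by gaps up to 2·enlarge_px become one component; when
    reduce_px > enlarge_px, isolated fragments of half-width below
    (reduce_px − enlarge_px) vanish.  The sequence acts in the unbounded
    plane (the dilation extends virtually past the frame before the erosion
    pulls back in), so an ROI spanning the whole frame ends up inset by
    reduce_px − enlarge_px, not by reduce_px.
    """
    mask = np.asarray(mask, dtype=bool)
    pad = int(np.ceil(p.enlarge_px)) + 1
    padded = np.pad(mask, pad, mode="constant", constant_values=False)
    out = erode_by_distance(dilate_by_distance(padded, p.enlarge_px), p.reduce_px)
    return out[pad:-pad, pad:-pad]


def adjust_roi(mask: np.ndarray, adjust_px: int) -> np.ndarray:
    """Grow (adjust_px > 0) or shrink (< 0) the ROI by a pixel distance."""
    if not -255 <= adjust_px <= 255:
        raise ParameterError(f"adjust_px must lie in [-255, 255], got {adjust_px}")
    mask = np.asarray(mask, dtype=bool)
    if adjust_px > 0:
        return dilate_by_distance(mask, adjust_px)
    if adjust_px < 0:
        return erode_by_distance(mask, -adjust_px)
    return mask.copy()


def detect_roi(plane: np.ndarray, p: RoiParams, source_mode: str = "automatic_roi") -> RoiMask:
    """Full automatic ROI detection on one ROI-channel plane."""
    mask = preprocess_roi_channel(plane)
    mask = clean_mask(mask, p.min_particle_px)
    mask = merge_and_prune(mask, p)
    mask = adjust_roi(mask, p.adjust_px)
    roi = RoiMask(mask=mask, source_mode=source_mode)
    if roi.is_empty:
        logger.warning("automatic ROI detection produced an empty mask; "
                       "image will be reported with zero axon length")
    return roi


def select_parameter_image(
    entries: Sequence[ImageEntry],
    roi_plane_of: Callable[[ImageEntry], np.ndarray],
) -> ImageEntry:
    """Pick the image whose ROI-channel mean intensity is the batch median.

    This image represents typical ROI signal and is the one shown when
    detection parameters are tuned.  Even counts take the lower median; ties
    on mean intensity break toward the lowest numeric id.
    """
    if not entries:
        raise ValueError("need at least one entry")
    means = {e.numeric_id: float(roi_plane_of(e).mean()) for e in entries}
    ranked = sorted(entries, key=lambda e: (means[e.numeric_id], e.numeric_id))
    median_mean = means[ranked[(len(ranked) - 1) // 2].numeric_id]
    return min(
        (e for e in entries if means[e.numeric_id] == median_mean),
        key=lambda e: e.numeric_id,
    )


# ---------------------------------------------------------------------------
# manual ROIs

def read_polygon_file(path: Path | str) -> np.ndarray:
    """Read a vertex list CSV (``x,y`` per line, 0-based, origin top-left)."""
    vertices = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise PolygonError(f"{path}:{lineno}: expected 'x,y', got {line!r}")
        try:
            vertices.append((float(parts[0]), float(parts[1])))
        except ValueError as exc:
            raise PolygonError(f"{path}:{lineno}: non-numeric vertex {line!r}") from exc
    return np.asarray(vertices, dtype=float)


def rasterize_polygon(vertices: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Fill a polygon on the pixel grid, boundary-inclusive.

    A pixel is inside when its center (x=col, y=row) lies in or on the
    polygon; vertices outside the image are clipped by the grid itself.
    """
    vertices = np.asarray(vertices, dtype=float)
    if vertices.ndim != 2 or vertices.shape[0] < 3 or vertices.shape[1] != 2:
        raise PolygonError(f"polygon needs >= 3 x,y vertices, got shape {vertices.shape}")
    poly = shapely.Polygon(vertices)
    if poly.is_empty or poly.area == 0:
        raise PolygonError("polygon is degenerate (zero area)")
    h, w = shape
    c0 = max(0, int(np.floor(vertices[:, 0].min())))
    c1 = min(w - 1, int(np.ceil(vertices[:, 0].max())))
    r0 = max(0, int(np.floor(vertices[:, 1].min())))
    r1 = min(h - 1, int(np.ceil(vertices[:, 1].max())))
    mask = np.zeros(shape, dtype=bool)
    if c1 < c0 or r1 < r0:
        return mask
    rows, cols = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
    shapely.prepare(poly)
    inside = shapely.intersects_xy(poly, cols.ravel(), rows.ravel())
    mask[r0 : r1 + 1, c0 : c1 + 1] = inside.reshape(rows.shape)
    return mask


def load_manual_roi(
    polygon_path: Path | str, shape: tuple[int, int], source_mode: str = "manual_roi_1ch"
) -> RoiMask:
    """Rasterize a polygon vertex file into an ROI mask."""
    vertices = read_polygon_file(polygon_path)
    if vertices.ndim != 2 or len(vertices) < 3:
        raise PolygonError(f"polygon file {polygon_path} has fewer than 3 vertices")
    return RoiMask(mask=rasterize_polygon(vertices, shape), source_mode=source_mode)


def full_image_roi(shape: tuple[int, int]) -> RoiMask:
    """Whole-image ROI used by the entire-image analysis mode."""
    return RoiMask(mask=np.ones(shape, dtype=bool), source_mode="entire_image")
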