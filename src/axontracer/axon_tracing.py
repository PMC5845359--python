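"""Axon detection, skeletonization and length measurement inside an ROI.

Axons appear as bright curvilinear ridges.  Detection follows the ridge
recipe of Gaussian-scaled second derivatives: the axon plane is cropped to
the ROI, tissue holes (near-black voids whose sharp rims would masquerade as
ridges) are filled with the image mean, the second-order Gaussian derivative
is taken separately along x and y, sign-inverted so ridges respond
positively, normalized, thresholded by the user's sensitivity, recombined by
union, thinned to a one-pixel-wide topological skeleton, and cleaned of
components at or below the cleanup size.  Axon length is the surviving
skeleton pixel count — the raw quantity reported per image (a known ~√2
undercount on diagonal runs, accepted for comparability).
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from skimage.morphology import thin

from .errors import DegenerateImageError, EmptyRoiSignal, ParameterError
from .roi_detection import STRUCT_8, RoiMask


@dataclass(frozen=True)
class DetectionParams:
    """User-tunable axon detection parameters, frozen for a whole batch.

    sensitivity (0–1) is detection leniency: the normalized ridge response is
    thresholded at 1 − sensitivity, so larger values pick up fainter axons.
    cleanup_px removes skeleton fragments of that many pixels or fewer.
    derivative_scale is the Gaussian scale (px) of the ridge filter.
    hole_intensity_max / hole_min_area_px define what counts as a tissue hole.
    """

    sensitivity: float = 0.30
    cleanup_px: int = 30
    derivative_scale: float = 1.0
    hole_min_area_px: int = 500
    hole_intensity_max: int = 5

    def __post_init__(self) -> None:
        if not 0.0 <= self.sensitivity <= 1.0:
            raise ParameterError(f"sensitivity must lie in [0, 1], got {self.sensitivity}")
        if self.cleanup_px < 0:
            raise ParameterError("cleanup_px must be >= 0")
        if self.derivative_scale <= 0:
            raise ParameterError("derivative_scale must be > 0")


@dataclass(frozen=True)
class AxonRecord:
    """One individually detected fibrous structure (detail mode)."""

    component_id: int
    length_px: int
    color: tuple[int, int, int]


@dataclass
class TraceResult:
    """Skeleton and length measurements for one image/channel."""

    skeleton: np.ndarray
    crop_offset: tuple[int, int]
    total_length_px: int
    normalized_length: float | None = None
    axons: list[AxonRecord] | None = None
    cropped_plane: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]


def empty_trace_result(detail: bool = False) -> TraceResult:
    return TraceResult(
        skeleton=np.zeros((0, 0), dtype=bool),
        crop_offset=(0, 0),
        total_length_px=0,
        axons=[] if detail else None,
        cropped_plane=np.zeros((0, 0), dtype=np.uint8),
    )


# ---------------------------------------------------------------------------
# cropping and tissue holes

def apply_roi_and_crop(plane: np.ndarray, roi: RoiMask) -> tuple[np.ndarray, tuple[int, int]]:
    """Zero pixels outside the ROI and crop to its tight bounding box."""
    if roi.is_empty:
        raise EmptyRoiSignal("ROI mask is empty")
    plane = np.asarray(plane)
    if plane.shape != roi.mask.shape:
        raise ParameterError(f"plane shape {plane.shape} != ROI shape {roi.mask.shape}")
    rows = np.flatnonzero(roi.mask.any(axis=1))
    cols = np.flatnonzero(roi.mask.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    cropped = plane[r0:r1, c0:c1].copy()
    cropped[~roi.mask[r0:r1, c0:c1]] = 0
    return cropped, (int(r0), int(c0))


def detect_tissue_holes(plane: np.ndarray, p: DetectionParams) -> np.ndarray:
    """Flag large near-black regions (tissue voids, or the area outside the ROI)."""
    plane = np.asarray(plane)
    candidates = plane <= p.hole_intensity_max
    if candidates.all():
        raise DegenerateImageError("entire image qualifies as a tissue hole")
    if not candidates.any():
        return np.zeros(plane.shape, dtype=bool)
    labels, n = ndi.label(candidates, structure=STRUCT_8)
    if n == 0:
        return np.zeros(plane.shape, dtype=bool)
    sizes = ndi.sum_labels(np.ones(plane.shape, dtype=np.int64), labels, np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= p.hole_min_area_px) + 1
    return np.isin(labels, keep)


def fill_holes_with_mean(plane: np.ndarray, holes: np.ndarray) -> np.ndarray:
    """Replace hole pixels by the mean of non-hole pixels (round half up)."""
    plane = np.asarray(plane)
    holes = np.asarray(holes, dtype=bool)
    if holes.shape != plane.shape:
        raise ParameterError("hole mask shape must match the plane")
    if not holes.any():
        return plane.copy()
    if holes.all():
        raise DegenerateImageError("hole mask covers the entire image")
    mean = float(plane[~holes].mean())
    fill = int(np.floor(mean + 0.5))  # round half up
    out = plane.copy()
    out[holes] = fill
    return out


# ---------------------------------------------------------------------------
# ridge response

def invert_8bit(plane: np.ndarray) -> np.ndarray:
    """Pixelwise 8-bit inversion (255 − v); applying it twice is the identity."""
    return (255 - np.asarray(plane, dtype=np.uint8)).astype(np.uint8)


def ridge_response(plane: np.ndarray, axis: str, scale: float) -> np.ndarray:
    """Normalized bright-ridge response along one axis.

    Second-order Gaussian-scaled derivative along ``axis``, sign-inverted so
    a bright ridge responds positively, then min–max normalized to [0, 1].
    A constant plane gives an all-zero response.
    """
    if scale <= 0:
        raise ParameterError("derivative scale must be > 0")
    if axis not in ("x", "y"):
        raise ParameterError(f"axis must be 'x' or 'y', got {axis!r}")
    order = (0, 2) if axis == "x" else (2, 0)
    resp = -ndi.gaussian_filter(np.asarray(plane, dtype=np.float64), sigma=scale, order=order)
    lo, hi = resp.min(), resp.max()
    if hi <= lo:
        return np.zeros(plane.shape, dtype=np.float64)
    return (resp - lo) / (hi - lo)


def binarize_response(resp: np.ndarray, sensitivity: float) -> np.ndarray:
    """Threshold a normalized ridge response at 1 − sensitivity.

    Zero-response pixels never fire, so sensitivity 1 selects exactly the
    pixels with any positive response.
    """
    if not 0.0 <= sensitivity <= 1.0:
        raise ParameterError(f"sensitivity must lie in [0, 1], got {sensitivity}")
    resp = np.asarray(resp, dtype=np.float64)
    return (resp >= 1.0 - sensitivity) & (resp > 0.0)


# ---------------------------------------------------------------------------
# skeleton

def _neighbor_cycle(skel: np.ndarray, r: int, c: int) -> list[bool]:
    h, w = skel.shape
    order = ((-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1))
    return [
        bool(skel[r + dr, c + dc]) if 0 <= r + dr < h and 0 <= c + dc < w else False
        for dr, dc in order
    ]


def _is_simple(skel: np.ndarray, r: int, c: int) -> bool:
    """True when removing (r, c) cannot disconnect its 8-neighborhood."""
    cycle = _neighbor_cycle(skel, r, c)
    transitions = sum(
        1 for a, b in zip(cycle, cycle[1:] + cycle[:1]) if not a and b
    )
    return transitions == 1 and sum(cycle) > 1


def _resolve_2x2_blocks(skel: np.ndarray) -> np.ndarray:
    """Deterministically delete one simple pixel from every remaining 2×2 block."""
    skel = skel.copy()
    while True:
        blocks = skel[:-1, :-1] & skel[1:, :-1] & skel[:-1, 1:] & skel[1:, 1:]
        if not blocks.any():
            return skel
        r, c = np.argwhere(blocks)[0]
        for dr, dc in ((0, 0), (0, 1), (1, 0), (1, 1)):
            if _is_simple(skel, r + dr, c + dc):
                skel[r + dr, c + dc] = False
                break
        else:  # fully surrounded block corner; removal cannot disconnect
            skel[r, c] = False


def extract_skeleton(bin_x: np.ndarray, bin_y: np.ndarray) -> np.ndarray:
    """Union the per-axis detections and thin to a topological skeleton.

    Morphological thinning (skimage) does most of the work; a deterministic
    simple-point pass removes the rare residual 2×2 blocks so the skeleton
    is strictly one pixel wide.
    """
    bin_x = np.asarray(bin_x, dtype=bool)
    bin_y = np.asarray(bin_y, dtype=bool)
    if bin_x.shape != bin_y.shape:
        raise ParameterError("per-axis binary images must share a shape")
    combined = bin_x | bin_y
    if not combined.any():
        return combined
    return _resolve_2x2_blocks(thin(combined))


def cleanup_skeleton(skel: np.ndarray, cleanup_px: int) -> np.ndarray:
    """Keep only 8-connected skeleton components strictly larger than cleanup_px."""
    skel = np.asarray(skel, dtype=bool)
    if cleanup_px < 0:
        raise ParameterError("cleanup_px must be >= 0")
    if not skel.any():
        return skel.copy()
    labels, n = ndi.label(skel, structure=STRUCT_8)
    sizes = ndi.sum_labels(np.ones(skel.shape, dtype=np.int64), labels, np.arange(1, n + 1))
    keep = np.flatnonzero(sizes > cleanup_px) + 1
    return np.isin(labels, keep)


def label_individual_axons(skel: np.ndarray) -> list[AxonRecord]:
    """One record per 8-connected skeleton component, with a distinct color.

    Colors are evenly spaced hues in component (scan) order, so the labeling
    is deterministic for a given skeleton.
    """
    skel = np.asarray(skel, dtype=bool)
    labels, n = ndi.label(skel, structure=STRUCT_8)
    if n == 0:
        return []
    sizes = ndi.sum_labels(np.ones(skel.shape, dtype=np.int64), labels, np.arange(1, n + 1))
    records = []
    for i, size in enumerate(sizes):
        r, g, b = colorsys.hsv_to_rgb(i / n, 1.0, 1.0)
        records.append(
            AxonRecord(
                component_id=i + 1,
                length_px=int(size),
                color=(int(round(r * 255)), int(round(g * 255)), int(round(b * 255))),
            )
        )
    return records


def component_labels(skel: np.ndarray) -> np.ndarray:
    """8-connected component label image matching ``label_individual_axons`` order."""
    labels, _ = ndi.label(np.asarray(skel, dtype=bool), structure=STRUCT_8)
    return labels


# ---------------------------------------------------------------------------
# full per-image pipeline

def trace_axons(
    plane: np.ndarray,
    roi: RoiMask,
    p: DetectionParams,
    *,
    detail: bool = False,
    fill_holes: bool = True,
) -> TraceResult:
    """Run the full detection pipeline on one axon plane within an ROI.

    crop → hole detect/fill → ridge response (x, y) → threshold → union →
    thin → cleanup → measure.  An empty ROI or a fully dark crop yields a
    zero-length result rather than an error.  ``fill_holes=False`` disables
    the hole-suppression stage (diagnostics only).
    """
    if roi.is_empty:
        return empty_trace_result(detail)
    cropped, offset = apply_roi_and_crop(plane, roi)
    roi_crop = roi.mask[
        offset[0] : offset[0] + cropped.shape[0], offset[1] : offset[1] + cropped.shape[1]
    ]
    working = cropped
    if fill_holes:
        try:
            holes = detect_tissue_holes(cropped, p)
        except DegenerateImageError:
            # a fully dark crop has no axons
            result = empty_trace_result(detail)
            result.cropped_plane = cropped
            result.crop_offset = offset
            result.skeleton = np.zeros(cropped.shape, dtype=bool)
            return result
        working = fill_holes_with_mean(cropped, holes)
    resp_x = ridge_response(working, "x", p.derivative_scale)
    resp_y = ridge_response(working, "y", p.derivative_scale)
    bin_x = binarize_response(resp_x, p.sensitivity) & roi_crop
    bin_y = binarize_response(resp_y, p.sensitivity) & roi_crop
    skeleton = cleanup_skeleton(extract_skeleton(bin_x, bin_y), p.cleanup_px)
    result = TraceResult(
        skeleton=skeleton,
        crop_offset=offset,
        total_length_px=int(skeleton.sum()),
        cropped_plane=cropped,
    )
    if detail:
        result.axons = label_individual_axons(skeleton)
    return result


# ---------------------------------------------------------------------------
# rendering

def render_overlay(
    original: np.ndarray,
    skel: np.ndarray,
    offset: tuple[int, int] = (0, 0),
    color: tuple[int, int, int] = (255, 255, 0),
) -> np.ndarray:
    """Superimpose skeleton pixels in a solid color on an image.

    A 2-D original is promoted to RGB; only skeleton pixels change.
    """
    original = np.asarray(original)
    if original.ndim == 2:
        rgb = np.stack([original] * 3, axis=-1).astype(np.uint8)
    else:
        rgb = original.astype(np.uint8).copy()
    skel = np.asarray(skel, dtype=bool)
    r0, c0 = offset
    if skel.any():
        if r0 + skel.shape[0] > rgb.shape[0] or c0 + skel.shape[1] > rgb.shape[1]:
            raise ParameterError("skeleton does not fit within the original at this offset")
        view = rgb[r0 : r0 + skel.shape[0], c0 : c0 + skel.shape[1]]
        view[skel] = color
    return rgb


def render_detail_overlay(
    original: np.ndarray,
    skel: np.ndarray,
    axons: list[AxonRecord],
    offset: tuple[int, int] = (0, 0),
) -> np.ndarray:
    """Multicolor overlay: every individually detected axon in its own color."""
    original = np.asarray(original)
    if original.ndim == 2:
        rgb = np.stack([original] * 3, axis=-1).astype(np.uint8)
    else:
        rgb = original.astype(np.uint8).copy()
    labels = component_labels(skel)
    r0, c0 = offset
    view = rgb[r0 : r0 + labels.shape[0], c0 : c0 + labels.shape[1]]
    for record in axons:
        view[labels == record.component_id] = record.color
    return rgb
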