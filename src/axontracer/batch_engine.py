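"""Batch orchestration: mode dispatch, normalization, outputs, summary.

A batch run applies one frozen parameter set to every image in an analysis
folder, so quantification is identical across experimental groups.  Raw axon
length (skeleton pixels) is optionally normalized by the mean intensity of a
reference region drawn on the brightest axon-channel image, correcting for
labeling efficiency between animals.

Outputs mirror the folder conventions of the original tool: a ``traced
images`` subfolder holds per-image products lettered a–e (original with ROI
outline, cropped axon channel(s), cropped channel(s) with superimposed
traces), the analysis folder gains a ``tracing data summary`` spreadsheet
(.xlsx and .csv), and detail mode adds per-image multicolor tracings plus
per-axon datasheets under ``Traced Images Detailed Results``.
"""

from __future__ import annotations

import dataclasses
import datetime
import logging
import re
import zipfile
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Callable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .axon_tracing import (
    DetectionParams,
    TraceResult,
    empty_trace_result,
    render_detail_overlay,
    render_overlay,
    trace_axons,
)
from .errors import ChannelAssignmentError, NormalizationError, PolygonError
from .image_io import (
    ChannelAssignment,
    ImageEntry,
    MultiChannelImage,
    load_image,
    scan_analysis_folder,
    split_channels,
)
from .roi_detection import (
    RoiMask,
    RoiParams,
    detect_roi,
    full_image_roi,
    load_manual_roi,
    rasterize_polygon,
    read_polygon_file,
    select_parameter_image,
)

logger = logging.getLogger("axontracer")

SUMMARY_STEM = "tracing data summary"
TRACED_DIR = "traced images"
DETAIL_DIR = "Traced Images Detailed Results"

#: fixed workbook metadata timestamp so spreadsheets are byte-reproducible
_EPOCH = datetime.datetime(1980, 1, 1)

TRACE_COLOR = (255, 255, 0)  # yellow
ROI_OUTLINE_COLOR = (255, 255, 255)  # white


class AnalysisMode(str, Enum):
    ENTIRE_IMAGE = "entire_image"
    AUTOMATIC_ROI = "automatic_roi"
    MANUAL_ROI_1CH = "manual_roi_1ch"
    MANUAL_ROI_2CH = "manual_roi_2ch"


@dataclass
class BatchConfig:
    """Everything a batch run needs; validated against the selected mode."""

    mode: AnalysisMode
    assignment: ChannelAssignment
    detection: DetectionParams = field(default_factory=DetectionParams)
    roi_params: RoiParams = field(default_factory=RoiParams)
    normalize: bool = False
    norm_roi_path: Path | None = None
    manual_roi_paths: dict[int, Path] = field(default_factory=dict)
    detail: bool = False

    def __post_init__(self) -> None:
        self.mode = AnalysisMode(self.mode)
        if self.mode is AnalysisMode.AUTOMATIC_ROI and self.assignment.roi_channel is None:
            raise ChannelAssignmentError("automatic-ROI mode requires a roi_channel")
        if self.mode is AnalysisMode.MANUAL_ROI_2CH and self.assignment.axon_channel_2 is None:
            raise ChannelAssignmentError("two-axon-channel mode requires axon_channel_2")
        if self.normalize and self.norm_roi_path is None:
            raise NormalizationError("normalization requires a reference ROI polygon file")

    @property
    def n_axon_channels(self) -> int:
        return 2 if self.mode is AnalysisMode.MANUAL_ROI_2CH else 1


@dataclass
class NormalizationRef:
    """Reference image and region whose mean intensity divides raw lengths."""

    entry: ImageEntry
    roi_polygon: np.ndarray
    mean_intensity: float

    def __post_init__(self) -> None:
        if self.mean_intensity <= 0:
            raise NormalizationError("normalization mean intensity must be > 0")


@dataclass
class ImageArtifacts:
    """Per-image products handed from processing to output writing."""

    entry: ImageEntry
    image: MultiChannelImage
    roi: RoiMask
    traces: dict[int, TraceResult]
    error: str | None = None


@dataclass
class BatchResult:
    rows: list[dict]
    params_used: dict
    parameter_image_id: int | None = None
    normalization: NormalizationRef | None = None
    output_files: list[Path] = field(default_factory=list)

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


# ---------------------------------------------------------------------------
# normalization

def select_normalization_image(
    entries: Sequence[ImageEntry],
    axon_plane_of: Callable[[ImageEntry], np.ndarray],
) -> ImageEntry:
    """The image with the highest axon-channel mean intensity; ties → lowest id."""
    if not entries:
        raise ValueError("need at least one entry")
    return min(entries, key=lambda e: (-float(axon_plane_of(e).mean()), e.numeric_id))


def compute_normalization(plane: np.ndarray, roi_polygon: np.ndarray) -> float:
    """Mean axon-channel intensity inside the reference polygon."""
    mask = rasterize_polygon(np.asarray(roi_polygon, dtype=float), plane.shape)
    if not mask.any():
        raise PolygonError("normalization polygon rasterizes to an empty region")
    mean = float(np.asarray(plane)[mask].mean())
    if mean <= 0:
        raise NormalizationError("normalization region has zero mean intensity")
    return mean


def normalize_length(raw: float, mean_intensity: float) -> float:
    """Normalized axon length: raw pixels divided by the reference mean intensity."""
    if mean_intensity <= 0:
        raise NormalizationError(f"mean intensity must be > 0, got {mean_intensity}")
    return raw / mean_intensity


# ---------------------------------------------------------------------------
# per-image processing

def _roi_for(entry: ImageEntry, planes: dict[str, np.ndarray], config: BatchConfig,
             shape: tuple[int, int]) -> RoiMask:
    mode = config.mode
    if mode is AnalysisMode.ENTIRE_IMAGE:
        return full_image_roi(shape)
    if mode is AnalysisMode.AUTOMATIC_ROI:
        return detect_roi(planes["roi_channel"], config.roi_params, source_mode=mode.value)
    try:
        polygon_path = config.manual_roi_paths[entry.numeric_id]
    except KeyError:
        raise PolygonError(f"no manual ROI polygon supplied for image {entry.numeric_id}")
    return load_manual_roi(polygon_path, shape, source_mode=mode.value)


def process_image(entry: ImageEntry, config: BatchConfig) -> ImageArtifacts:
    image = load_image(entry)
    planes = split_channels(image, config.assignment)
    roi = _roi_for(entry, planes, config, image.pixels.shape[:2])
    if roi.is_empty:
        logger.warning("image %d: empty ROI, reported with zero axon length", entry.numeric_id)
    traces = {1: trace_axons(planes["axon_channel_1"], roi, config.detection, detail=config.detail)}
    if config.n_axon_channels == 2:
        traces[2] = trace_axons(planes["axon_channel_2"], roi, config.detection,
                                detail=config.detail)
    return ImageArtifacts(entry=entry, image=image, roi=roi, traces=traces)


# ---------------------------------------------------------------------------
# batch run

def run_batch(folder: Path | str, config: BatchConfig, write: bool = True) -> BatchResult:
    """Process every image in an analysis folder with one frozen parameter set.

    Per-image failures are recorded in the summary row and the batch
    continues; two runs on identical inputs produce byte-identical outputs.
    """
    folder = Path(folder)
    entries = scan_analysis_folder(folder)
    params_used = {
        "mode": config.mode.value,
        "detection": dataclasses.asdict(config.detection),
        "roi_params": dataclasses.asdict(config.roi_params),
        "assignment": dataclasses.asdict(config.assignment),
        "normalize": config.normalize,
        "detail": config.detail,
    }
    logger.info("batch parameters frozen: %s", params_used)

    if write:
        (folder / TRACED_DIR).mkdir(exist_ok=True)  # fail on unwritable destination up front
        if config.detail:
            (folder / DETAIL_DIR).mkdir(exist_ok=True)

    plane_cache: dict[tuple[int, str], np.ndarray] = {}

    def plane_of(entry: ImageEntry, role: str) -> np.ndarray:
        key = (entry.numeric_id, role)
        if key not in plane_cache:
            plane_cache[key] = split_channels(load_image(entry), config.assignment)[role]
        return plane_cache[key]

    result = BatchResult(rows=[], params_used=params_used)

    if config.mode is AnalysisMode.AUTOMATIC_ROI:
        param_entry = select_parameter_image(entries, lambda e: plane_of(e, "roi_channel"))
        result.parameter_image_id = param_entry.numeric_id
        logger.info("parameter image (median ROI-channel intensity): %d", param_entry.numeric_id)

    if config.normalize:
        ref_entry = select_normalization_image(entries, lambda e: plane_of(e, "axon_channel_1"))
        polygon = read_polygon_file(config.norm_roi_path)
        mean = compute_normalization(plane_of(ref_entry, "axon_channel_1"), polygon)
        result.normalization = NormalizationRef(ref_entry, polygon, mean)
        logger.info("normalization reference: image %d, mean intensity %.3f",
                    ref_entry.numeric_id, mean)

    artifacts: list[ImageArtifacts] = []
    for entry in entries:
        row: dict = {"image_id": entry.numeric_id}
        try:
            art = process_image(entry, config)
        except Exception as exc:  # per-image failure: record and continue
            logger.error("image %d failed: %s", entry.numeric_id, exc)
            row.update({"roi_area_px": np.nan, "axon1_length_px": np.nan, "error": str(exc)})
            if config.normalize:
                row["axon1_normalized"] = np.nan
            result.rows.append(row)
            continue
        artifacts.append(art)
        row["roi_area_px"] = art.roi.area_px
        for ch, trace in sorted(art.traces.items()):
            row[f"axon{ch}_length_px"] = trace.total_length_px
            if config.normalize:
                norm = normalize_length(trace.total_length_px, result.normalization.mean_intensity)
                trace.normalized_length = norm
                row[f"axon{ch}_normalized"] = norm
        row["error"] = ""
        result.rows.append(row)

    if write:
        result.output_files = write_outputs(folder, config, artifacts, result)
    return result


# ---------------------------------------------------------------------------
# outputs

def _out_suffix(entry: ImageEntry) -> str:
    # overlays must be lossless; JPEG inputs get PNG outputs
    return ".tiff" if entry.format == "tiff" else ".png"


def _roi_outline(mask: np.ndarray) -> np.ndarray:
    return mask & ~ndi.binary_erosion(mask, border_value=True)


def _write_image(path: Path, pixels: np.ndarray) -> Path:
    iio.imwrite(path, np.asarray(pixels))
    return path


def write_outputs(
    folder: Path, config: BatchConfig, artifacts: list[ImageArtifacts], result: BatchResult
) -> list[Path]:
    """Write per-image products, detail files and the summary spreadsheet.

    Per image N (letters follow the a–e convention): Na = original RGB with
    the ROI outlined in white; Nb/Nc = cropped grayscale axon channel 1
    without/with yellow traces; Nd/Ne = the same for axon channel 2.  Images
    with an empty ROI get only Na.
    """
    written: list[Path] = []
    traced = folder / TRACED_DIR
    for art in artifacts:
        n = art.entry.numeric_id
        suffix = _out_suffix(art.entry)
        original = art.image.pixels.copy()
        original[_roi_outline(art.roi.mask)] = ROI_OUTLINE_COLOR
        written.append(_write_image(traced / f"{n}a{suffix}", original))
        letters = {1: ("b", "c"), 2: ("d", "e")}
        for ch, trace in sorted(art.traces.items()):
            if art.roi.is_empty:
                continue
            gray_letter, overlay_letter = letters[ch]
            written.append(_write_image(traced / f"{n}{gray_letter}{suffix}", trace.cropped_plane))
            overlay = render_overlay(trace.cropped_plane, trace.skeleton, color=TRACE_COLOR)
            written.append(_write_image(traced / f"{n}{overlay_letter}{suffix}", overlay))
        if config.detail:
            written.extend(_write_detail(folder, art))

    frame = result.frame
    csv_path = folder / f"{SUMMARY_STEM}.csv"
    frame.to_csv(csv_path, index=False)
    written.append(csv_path)
    xlsx_path = folder / f"{SUMMARY_STEM}.xlsx"
    params_frame = pd.DataFrame(
        [{"parameter": k, "value": repr(v)} for k, v in result.params_used.items()]
    )
    _write_xlsx(xlsx_path, {"results": frame, "parameters": params_frame})
    written.append(xlsx_path)
    return written


def _write_detail(folder: Path, art: ImageArtifacts) -> list[Path]:
    detail_dir = folder / DETAIL_DIR
    written: list[Path] = []
    n = art.entry.numeric_id
    for ch, trace in sorted(art.traces.items()):
        if trace.axons is None:
            continue
        tag = f"{n}" if ch == 1 else f"{n}_ch{ch}"
        frame = pd.DataFrame(
            [
                {
                    "component_id": a.component_id,
                    "length_px": a.length_px,
                    "color_r": a.color[0],
                    "color_g": a.color[1],
                    "color_b": a.color[2],
                }
                for a in trace.axons
            ],
            columns=["component_id", "length_px", "color_r", "color_g", "color_b"],
        )
        csv_path = detail_dir / f"{tag} tracing data details.csv"
        frame.to_csv(csv_path, index=False)
        written.append(csv_path)
        xlsx_path = detail_dir / f"{tag} tracing data details.xlsx"
        _write_xlsx(xlsx_path, {"details": frame})
        written.append(xlsx_path)
        if trace.skeleton.size:
            overlay = render_detail_overlay(trace.cropped_plane, trace.skeleton, trace.axons)
            png_path = detail_dir / f"{tag} tracing data details.png"
            written.append(_write_image(png_path, overlay))
    return written


def _write_xlsx(path: Path, sheets: dict[str, pd.DataFrame]) -> None:
    """Write an xlsx with pinned metadata and zip timestamps (byte-reproducible)."""
    with pd.ExcelWriter(path, engine="openpyxl") as writer:
        for name, frame in sheets.items():
            frame.to_excel(writer, sheet_name=name, index=False)
        writer.book.properties.created = _EPOCH
        writer.book.properties.modified = _EPOCH
    _pin_zip_timestamps(path)


def _pin_zip_timestamps(path: Path) -> None:
    with zipfile.ZipFile(path) as zf:
        items = [(name, zf.read(name)) for name in sorted(zf.namelist())]
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        for name, data in items:
            if name == "docProps/core.xml":
                # openpyxl stamps the save wall-clock into dcterms:modified
                data = re.sub(
                    rb"(<dcterms:modified[^>]*>)[^<]*(</dcterms:modified>)",
                    rb"\g<1>1980-01-01T00:00:00Z\g<2>",
                    data,
                )
            info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
            info.compress_type = zipfile.ZIP_DEFLATED
            info.external_attr = 0o600 << 16
            zf.writestr(info, data)
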