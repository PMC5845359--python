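"""Analysis-folder scanning and RGB channel handling.

An analysis folder holds nothing but image files whose filename stems are
positive integers without a leading zero (``3.tiff``, ``24.jpeg`` ...).  The
numeric id orders the batch and names every derived output.  Images are RGB;
each color plane is assigned a role (axon detection, ROI detection, or
neither) that holds for the whole batch.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import (
    ChannelAssignmentError,
    EmptyFolderError,
    FilenameError,
    FolderContentError,
    ImageFormatError,
)

#: recognised image suffixes → canonical format name
IMAGE_SUFFIXES = {
    ".tif": "tiff",
    ".tiff": "tiff",
    ".png": "png",
    ".jpg": "jpeg",
    ".jpeg": "jpeg",
}

#: output artifacts the batch engine itself writes into the analysis folder;
#: ignored on re-scan so an already-analyzed folder stays valid input.
RESERVED_STEMS = {"tracing data summary"}

CHANNEL_INDEX = {"r": 0, "g": 1, "b": 2}


@dataclass(frozen=True)
class ImageEntry:
    """One image file in an analysis folder."""

    numeric_id: int
    path: Path
    format: str

    def __post_init__(self) -> None:
        if self.numeric_id < 1:
            raise FilenameError(f"numeric id must be >= 1, got {self.numeric_id}")


@dataclass
class MultiChannelImage:
    """H×W×3 8-bit pixel array plus its source entry (None for in-memory fixtures)."""

    pixels: np.ndarray
    entry: ImageEntry | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ImageFormatError(f"expected H×W×3 pixels, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ImageFormatError("image must have at least one row and column")
        self.pixels = px.astype(np.uint8, copy=False)


@dataclass(frozen=True)
class ChannelAssignment:
    """Maps the r/g/b planes to axon- and ROI-detection roles.

    ``axon_channel_2`` is only used in the two-axon-channel mode;
    ``roi_channel`` only when the ROI is detected automatically.
    """

    axon_channel_1: str
    axon_channel_2: str | None = None
    roi_channel: str | None = None

    def __post_init__(self) -> None:
        roles = [("axon_channel_1", self.axon_channel_1)]
        if self.axon_channel_2 is not None:
            roles.append(("axon_channel_2", self.axon_channel_2))
        if self.roi_channel is not None:
            roles.append(("roi_channel", self.roi_channel))
        for name, ch in roles:
            if ch not in CHANNEL_INDEX:
                raise ChannelAssignmentError(f"{name} must be one of r/g/b, got {ch!r}")
        channels = [ch for _, ch in roles]
        if len(set(channels)) != len(channels):
            raise ChannelAssignmentError(f"channel roles must be pairwise distinct, got {channels}")


def _validate_stem(stem: str, path: Path) -> int:
    if not stem.isdigit():
        raise FilenameError(f"filename stem must be all digits: {path.name!r}")
    if stem.startswith("0"):
        raise FilenameError(f"filename cannot start with '0': {path.name!r}")
    return int(stem)


def scan_analysis_folder(path: Path | str) -> list[ImageEntry]:
    """Validate a folder and list its images sorted by ascending numeric id.

    Dotfiles, subdirectories (the tool's own ``traced images`` output folder
    lives inside the analysis folder) and the summary spreadsheet are
    ignored; any other non-image file is an error.
    """
    folder = Path(path)
    if not folder.is_dir():
        raise FolderContentError(f"not a directory: {folder}")
    entries: list[ImageEntry] = []
    seen: dict[int, Path] = {}
    for child in sorted(folder.iterdir()):
        if child.name.startswith(".") or child.is_dir():
            continue
        if child.stem.lower() in RESERVED_STEMS:
            continue
        suffix = child.suffix.lower()
        if suffix not in IMAGE_SUFFIXES:
            raise FolderContentError(f"non-image file in analysis folder: {child.name!r}")
        numeric_id = _validate_stem(child.stem, child)
        if numeric_id in seen:
            raise FilenameError(
                f"duplicate numeric id {numeric_id}: {seen[numeric_id].name!r} and {child.name!r}"
            )
        seen[numeric_id] = child
        entries.append(ImageEntry(numeric_id=numeric_id, path=child, format=IMAGE_SUFFIXES[suffix]))
    if not entries:
        raise EmptyFolderError(f"no image files in {folder}")
    return sorted(entries, key=lambda e: e.numeric_id)


def load_image(entry: ImageEntry) -> MultiChannelImage:
    """Decode an entry into an 8-bit H×W×3 image.

    Grayscale sources are replicated to three identical planes; an alpha
    channel is dropped; 16-bit sources are min–max rescaled to 0–255.
    """
    try:
        raw = iio.imread(entry.path)
    except Exception as exc:  # imageio raises a zoo of backend errors
        raise ImageFormatError(f"cannot decode {entry.path.name!r}: {exc}") from exc
    arr = np.asarray(raw)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise ImageFormatError(f"unsupported image shape {arr.shape} in {entry.path.name!r}")
    if arr.dtype != np.uint8:
        arr = arr.astype(np.float64)
        lo, hi = arr.min(), arr.max()
        if hi > lo:
            arr = (arr - lo) / (hi - lo) * 255.0
        else:
            arr = np.zeros_like(arr)
        arr = np.round(arr).astype(np.uint8)
    return MultiChannelImage(pixels=arr, entry=entry)


def split_channels(
    img: MultiChannelImage, assign: ChannelAssignment
) -> dict[str, np.ndarray]:
    """Return the grayscale plane for every assigned role, pixel values untouched."""
    planes: dict[str, np.ndarray] = {}
    for field in dataclasses.fields(assign):
        channel = getattr(assign, field.name)
        if channel is None:
            continue
        planes[field.name] = img.pixels[:, :, CHANNEL_INDEX[channel]].copy()
    return planes
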