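"""Synthetic fluorescence fixtures with analytic ground truth.

Real spinal-cord sections are replaced by generated images that reproduce
the features the pipeline must cope with: bright smooth curvilinear axons on
a noisy background, blob-like graft signal in a second channel, debris
specks, and near-zero tissue holes.  Every quantity the tracer estimates is
known analytically: per-axon arc length comes from dense polyline
integration of the generating curve (step < 0.1 px), the graft mask is the
set of stamped blobs, and the hole mask is the set of punched rectangles.

Axons are drawn as gentle sinusoid graphs y = f(x) with bounded slope, which
makes them non-self-intersecting; mutual disjointness is enforced by spaced
baselines plus an explicit overlap check with retries.  Bounded slope also
keeps the skeleton-pixel length measure close to true arc length, matching
how the tracer is meant to be read on real, mostly in-plane fibers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.morphology import dilation, disk

from .errors import FixtureError
from .image_io import ImageEntry, MultiChannelImage

#: dense sampling step (px along x) for arc-length integration
ARC_STEP = 0.05


@dataclass(frozen=True)
class FixtureSpec:
    """Everything that determines a synthetic image; ``seed`` fixes all randomness."""

    image_size: tuple[int, int] = (600, 256)
    n_axons: int = 20
    axon_width_px: int = 3
    axon_intensity: int = 200
    background_mean: float = 30.0
    background_sigma: float = 8.0
    #: ((row, col) center, half_width) per graft blob
    graft_blobs: tuple[tuple[tuple[int, int], int], ...] = ()
    #: (row0, col0, height, width) rectangles punched to zero
    hole_rects: tuple[tuple[int, int, int, int], ...] = ()
    debris_count: int = 0
    debris_size_range: tuple[int, int] = (2, 4)
    seed: int = 0
    x_margin: int = 28
    max_retries: int = 20


@dataclass
class FixtureTruth:
    """Ground truth for one generated image."""

    axon_lengths: list[float] = field(default_factory=list)
    graft_mask: np.ndarray | None = None
    hole_mask: np.ndarray | None = None

    @property
    def total_length(self) -> float:
        return float(sum(self.axon_lengths))


def _sample_curve(
    rng: np.random.Generator, h: int, w: int, baseline: float, x_margin: int
) -> tuple[np.ndarray, np.ndarray, float]:
    """One gentle sinusoid graph across the image; returns (xs, ys, arc length)."""
    x0, x1 = x_margin, w - 1 - x_margin
    span = x1 - x0
    a1, f1 = rng.uniform(3, 6), rng.uniform(1, 1.5)
    a2, f2 = rng.uniform(1, 2), rng.uniform(2, 3)
    p1, p2 = rng.uniform(0, 2 * np.pi, size=2)
    xs = np.arange(x0, x1 + 1e-9, ARC_STEP)
    t = (xs - x0) / span
    ys = baseline + a1 * np.sin(2 * np.pi * f1 * t + p1) + a2 * np.sin(2 * np.pi * f2 * t + p2)
    arc = float(np.hypot(np.diff(xs), np.diff(ys)).sum())
    return xs, ys, arc


def _stroke(xs: np.ndarray, ys: np.ndarray, shape: tuple[int, int], width_px: int) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    rr = np.clip(np.round(ys).astype(int), 0, shape[0] - 1)
    cc = np.clip(np.round(xs).astype(int), 0, shape[1] - 1)
    mask[rr, cc] = True
    radius = max(0, (width_px - 1) // 2)
    if radius:
        mask = dilation(mask, disk(radius))
    return mask


def generate_axon_image(spec: FixtureSpec) -> tuple[MultiChannelImage, FixtureTruth]:
    """Render an RGB fixture: axons in green, graft signal in red, blue empty.

    Curves that would touch an already-drawn axon (with a 2-px guard) are
    re-drawn up to ``spec.max_retries`` times, then an error is raised, so
    detail-mode component counts equal ``n_axons`` by construction.
    """
    h, w = spec.image_size
    rng = np.random.default_rng(spec.seed)
    truth = FixtureTruth()
    axon_mask = np.zeros((h, w), dtype=bool)
    occupied = np.zeros((h, w), dtype=bool)
    for i in range(spec.n_axons):
        baseline = (i + 1) * h / (spec.n_axons + 1)
        for attempt in range(spec.max_retries + 1):
            xs, ys, arc = _sample_curve(rng, h, w, baseline + rng.uniform(-2, 2), spec.x_margin)
            stroke = _stroke(xs, ys, (h, w), spec.axon_width_px)
            if not (stroke & occupied).any():
                break
            if attempt == spec.max_retries:
                raise FixtureError(f"could not place axon {i} without overlap")
        axon_mask |= stroke
        occupied |= dilation(stroke, disk(2))  # guard band keeps components disjoint
        truth.axon_lengths.append(arc)

    green = np.clip(rng.normal(spec.background_mean, spec.background_sigma, (h, w)), 0, 255)
    green[axon_mask] = spec.axon_intensity
    red, graft_mask = generate_graft_channel(replace(spec, seed=spec.seed + 1))
    truth.graft_mask = graft_mask

    pixels = np.zeros((h, w, 3), dtype=np.uint8)
    pixels[:, :, 0] = red
    pixels[:, :, 1] = np.round(green).astype(np.uint8)

    hole_mask = np.zeros((h, w), dtype=bool)
    for r0, c0, hh, ww in spec.hole_rects:
        hole_mask[r0 : r0 + hh, c0 : c0 + ww] = True
    if hole_mask.any():
        pixels = punch_holes(pixels, spec.hole_rects)
        # punched axon pixels no longer contribute detectable length
        truth.axon_lengths = _lengths_after_holes(truth.axon_lengths, axon_mask, hole_mask)
    truth.hole_mask = hole_mask
    return MultiChannelImage(pixels=pixels, entry=None), truth


def _lengths_after_holes(
    lengths: list[float], axon_mask: np.ndarray, hole_mask: np.ndarray
) -> list[float]:
    # fixtures used for length recovery keep holes clear of axons; if a hole
    # clips an axon the analytic length is no longer exact, so flag it
    if (axon_mask & hole_mask).any():
        raise FixtureError("hole rectangles must not intersect axon strokes")
    return lengths


def generate_graft_channel(spec: FixtureSpec) -> tuple[np.ndarray, np.ndarray]:
    """ROI-channel plane: bright blobs plus debris specks over dim noise.

    Returns the uint8 plane and the truth mask (blobs only, not debris).
    """
    h, w = spec.image_size
    rng = np.random.default_rng(spec.seed)
    plane = np.clip(rng.normal(spec.background_mean / 2, spec.background_sigma / 2, (h, w)), 0, 255)
    truth = np.zeros((h, w), dtype=bool)
    for (r, c), half_width in spec.graft_blobs:
        r0, r1 = max(0, r - half_width), min(h, r + half_width + 1)
        c0, c1 = max(0, c - half_width), min(w, c + half_width + 1)
        truth[r0:r1, c0:c1] = True
    plane[truth] = 220
    lo, hi = spec.debris_size_range
    for _ in range(spec.debris_count):
        size = int(rng.integers(lo, hi + 1))
        r = int(rng.integers(0, h - size))
        c = int(rng.integers(0, w - size))
        if truth[r : r + size, c : c + size].any():
            continue  # debris only outside the graft
        plane[r : r + size, c : c + size] = 220
    return np.round(plane).astype(np.uint8), truth


def punch_holes(
    image: np.ndarray, hole_rects: tuple[tuple[int, int, int, int], ...]
) -> np.ndarray:
    """Zero the listed (row0, col0, height, width) rectangles in every channel."""
    out = np.asarray(image).copy()
    for r0, c0, h, w in hole_rects:
        out[r0 : r0 + h, c0 : c0 + w] = 0
    return out


def write_fixture_folder(
    folder: Path | str,
    specs: dict[int, FixtureSpec],
    image_format: str = "tiff",
) -> dict[int, FixtureTruth]:
    """Write fixtures as a valid analysis folder (numeric filenames, images only)."""
    folder = Path(folder)
    folder.mkdir(parents=True, exist_ok=True)
    suffix = {"tiff": ".tiff", "png": ".png", "jpeg": ".jpeg"}[image_format]
    truths: dict[int, FixtureTruth] = {}
    for numeric_id, spec in sorted(specs.items()):
        img, truth = generate_axon_image(spec)
        path = folder / f"{numeric_id}{suffix}"
        iio.imwrite(path, img.pixels)
        img.entry = ImageEntry(numeric_id=numeric_id, path=path, format=image_format)
        truths[numeric_id] = truth
    return truths
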