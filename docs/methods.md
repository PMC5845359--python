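# Methods

## Pipeline model and assumptions

The package quantifies bright curvilinear structures (axons) inside a
region of interest of a fluorescence image. It assumes: (i) axons are
locally ridge-like — brighter than their immediate surroundings, a few
pixels wide, smooth at the derivative scale; (ii) the ROI signal (graft
label, nuclear stain) is blob-like and brighter than background, though
possibly fragmented and speckled with debris; (iii) images are 8-bit RGB
with one role per color channel, constant across a batch. Length is defined
as the pixel count of the one-pixel-wide topological skeleton of the
detected ridge set. This undercounts Euclidean length on diagonal runs by
up to √2 (~29% worst case, far less for mostly axis-aligned fibers); it is
kept because it is simple, monotone, and comparable across images analyzed
with identical settings — relative differences between experimental groups,
not absolute micrometres, are the quantity of interest.

## ROI detection

1. **Contrast stretch**: linear rescale saturating 0.35% of pixels at each
   tail. The saturation fraction mirrors the common automatic-contrast
   default of interactive image software; it only needs to defeat outlier
   pixels before thresholding.
2. **Binarization**: Otsu's method on the stretched plane. A constant plane
   has no ROI signal and yields an empty mask. The threshold rule is
   isolated in `preprocess_roi_channel` and trivially swappable.
3. **Particle removal / hole filling**: 8-connected foreground components
   with area < `min_particle_px` (default 100 px; exposed in config) are
   dropped; background regions 4-disconnected from the border are filled.
4. **Merge and prune**: Euclidean-distance dilation by `enlarge_px` (60)
   then erosion by `reduce_px` (90). "Within distance *d*" is inclusive
   (≤ *d*, pixel-center metric), which gives the exact closed-form bounds
   verified by the acceptance sweeps: gaps of up to 2·60 = 120 px merge;
   isolated fragments of half-width < 90 − 60 = 30 px vanish. The pair is
   evaluated in the unbounded plane (the array is padded by `enlarge_px`
   before the dilation), so an ROI spanning the whole frame is inset by
   30 px, not 90. Standalone erosion (`adjust_roi` with a negative value)
   treats the frame border as background, as padded binary erosion does.
5. **Adjustment**: optional ±255 px dilation/erosion, applied after the
   merge step. The ordering relative to the merge is not observable from
   any stated bound; applying it last keeps the printed 120/30 constants
   independent of the user adjustment.

The *parameter image* — the one a user would tune settings on — is the
image whose ROI-channel mean intensity is the batch median (lower median on
even counts; the lowest numeric id among exact ties).

## Axon tracing

1. **Crop**: tight bounding box of the ROI; outside-ROI pixels zeroed.
2. **Tissue holes**: 8-connected regions with intensity ≤ 5 (of 255) and
   area ≥ 500 px are replaced by the mean of the remaining pixels (rounded
   half up). Without this, the sharp rim of a void responds like a ridge
   and produces long false traces; with it, a hole contributes nothing (a
   regression test asserts both directions). The zeroed area outside the
   ROI participates as a "hole" too, which usefully suppresses edge
   responses at the ROI boundary. The defaults (5, 500) are conservative:
   real tissue is noisy well above 5, and genuine voids in slide-scanner
   images are far larger than 500 px.
3. **Ridge response**: second-order Gaussian-scaled derivative per axis
   (σ = `derivative_scale`, default 1.0 px — matched to few-pixel-wide
   fibers), sign-inverted, min–max normalized per image. The per-image
   normalization makes `sensitivity` a relative leniency: threshold
   = 1 − sensitivity. Its corollary is that a *zero-signal* image is
   normalized to its own noise; the default sensitivity must therefore sit
   below the noise ceiling (see calibration below).
4. **Combine / thin**: the per-axis detections are united (an intersection
   would erase purely horizontal or vertical fibers from one axis),
   restricted to the ROI, and thinned. `skimage.morphology.thin` leaves a
   2×2 block in rare configurations, so a deterministic simple-point pass
   deletes one removable corner per residual block; the final skeleton
   contains no 2×2 all-true square, and every pixel lies inside the ROI.
5. **Cleanup**: 8-connected skeleton components of size ≤ `cleanup_px` are
   removed (strictly "above the cleanup value" survives, so a component of
   exactly the cleanup size is dropped).
6. **Detail mode**: one record per component, colors as evenly spaced HSV
   hues in deterministic scan order; per-axon lengths always sum exactly to
   the total.

### Default detection parameters

`sensitivity = 0.30`, `cleanup_px = 30`, `derivative_scale = 1.0`. The
original workflow leaves these to interactive per-dataset tuning; the
headless analog here is the `preview` command plus a config file. The
shipped defaults were fixed once by previewing the reference fixtures at
the generator's default conditions: 0.30 recovers the analytic length of
the standard 20-curve fixture to within ~0.5% across seeds while leaving a
pure-noise image (background σ = 8) at zero traced length after cleanup.
Sensitivities ≥ 0.35 begin to pass background fluctuations whose thinned
webs exceed the cleanup size; ≤ 0.25 starts dropping hole-rim regression
signal and, at 0.20, fragments real fibers. As with the interactive
original, real datasets are expected to re-tune these on their parameter
image.

## Normalization

Raw length / mean intensity of a user-supplied polygon evaluated on the
axon channel of the *reference image* — the image with the highest
axon-channel mean (ties to lowest id). In two-channel mode both channels
are divided by the same reference mean, taken from axon channel 1, since a
single reference region is drawn. Normalized values are omitted when
normalization is off. The identity normalized · mean = raw holds to 1e-9.

## Batch behavior and outputs

Parameters are frozen before the first image; per-image failures (e.g. a
missing manual polygon) are recorded in that image's summary row and the
batch continues, so row count always equals image count. The pipeline
contains no randomness, and spreadsheet metadata (workbook timestamps, zip
entry dates) is pinned, so repeated runs are byte-identical. Overlay images
are always written losslessly (TIFF for TIFF input, PNG otherwise — JPEG
input included, to keep trace pixels exact). Outputs are written into the
analysis folder (as the original tool does); the folder scanner therefore
ignores subdirectories and the summary spreadsheet's reserved filename so
an analyzed folder remains valid input. Detail-mode per-image files are
prefixed with the image id to avoid name collisions within the shared
results folder. Manual ROIs are single polygons given as `x,y` CSV vertex
lists (0-based, origin top-left), rasterized boundary-inclusively — the
lossless headless stand-in for a drawn selection.

## Synthetic fixtures

`fixtures.generate_axon_image` renders: axons as gentle two-sinusoid graphs
y = f(x) spanning the frame width (slope bounded ≈ 0.47 so the
skeleton-pixel metric stays within a few percent of true arc length, as it
does for mostly in-plane fibers), stroked 3 px wide at intensity 200 over
N(30, 8²) background noise; graft blobs as bright squares at 220 with
seeded ≤ 4 px debris specks; holes as zeroed rectangles. Ground truth is
analytic: arc length by dense polyline integration (step 0.05 px < 0.1 px),
graft mask = stamped blobs, hole mask = punched rectangles. Curves are
disjoint by construction (spaced baselines + overlap retry with a 2-px
guard band), so detail-mode component counts are exact. The default
20-curve, 600×256 fixture carries ≈ 4,000 px of truth length.

What the fixtures do **not** emulate: optics (PSF blur, vignetting),
intensity variation along a fiber, axon crossings and branching, dense
fascicles, autofluorescent texture, and high-dynamic-range scenes where
bright and faint axons coexist (a documented accuracy limit of this class
of single-threshold detector — HDR acquisition is the upstream remedy).
Passing tests therefore demonstrate correctness of the algorithmic
machinery and its stated constants, not field accuracy on real tissue;
the latter rests on per-dataset parameter tuning and visual verification
of the written overlays.

## Numerical choices and edge cases

- Mean-fill rounding: round half up (⌊x + 0.5⌋).
- 16-bit inputs are min–max rescaled to 8-bit at load; grayscale replicated
  to three planes; alpha dropped.
- Normalized ridge response of a constant plane is defined as all-zero;
  `binarize_response` never fires on zero response, so sensitivity 1
  selects exactly the positive-response pixels.
- A fully dark crop (blank image, or everything qualifying as hole) traces
  to zero length rather than erroring; an empty ROI likewise yields a
  zero-length row with a warning, never a skipped image.
- Component connectivity: 8-connected foreground everywhere; 4-connected
  background for hole filling.
- Even-count medians take the lower middle; all intensity ties break to the
  lowest numeric id.

## Known limitations

Skeleton pixel count is not Euclidean length (diagonal bias above); crossing
fibers merge into one detail-mode component (continuity reconstruction is
out of scope); only single-polygon manual ROIs are supported; multi-page
TIFF and proprietary microscope formats are not read; the per-image
relative sensitivity means a signal-free image is thresholded against its
own noise — the cleanup size, not the threshold, is what keeps such images
at zero.

## Problem sizes used in the test suite

The acceptance-style checks run the full pipeline on desk-scale synthetic
inputs chosen to exercise every stated bound: 41 two-blob frames
(~460×900 px) for the 120-px gap sweep, 60 single-square frames (420×420)
for the 30-px pruning sweep, the 600×256 twenty-curve fixture for length
recovery, and three-image 512×512 batches for normalization and
byte-determinism.
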