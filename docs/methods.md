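# Methods

## The measurement problem

A single mesozooplankter (0.2–20 mm) swims freely in a transparent cuvette
filmed side-on against a dark background (dark-field illumination: the
animal is bright, the water dark). Each ~30-s clip yields hundreds of
frames; each usable frame yields one projected body length. The task is to
turn that noisy, biased collection into one accurate length in millimetres.

## Per-frame pipeline

Stages run in a fixed order (`zoobooth.pipeline.STAGE_ORDER`); instrumented
runs record the order and the tests assert it.

1. **Crop** to the cuvette's inner area. The crop rectangle is defined in
   raw-frame coordinates and also bounds the edge-distance criterion:
   objects near the cuvette wall are distorted by meniscus and wall effects
   and may be touching the wall rather than free-swimming.
2. **Undistort.** The short-focal-length lens introduces mild barrel
   distortion. We model it as a 5-coefficient Brown–Conrady camera (radial
   k1–k3, tangential p1–p2), read from four whitespace-delimited text files
   (`mtx.out`, `dist.out`, `newcameramtx.out`, `roi.out`) produced once per
   mounted set-up by an external checkerboard calibration. For each output
   pixel we normalise through the rectified intrinsic matrix, push forward
   through the distortion polynomial, re-project through the original
   intrinsics, and sample the raw frame bilinearly; out-of-frame samples
   read 0, which is safe on a dark background. With zero coefficients and
   equal matrices the map is the exact identity. Estimating the calibration
   itself is out of scope; a writer for the four files is provided so tests
   and fixtures need no external tool.
3. **Grayscale** by the Rec. 601 luminance weights (0.299, 0.587, 0.114),
   rounded to the nearest 8-bit level.
4. **Sharpness** = variance of the 3×3 Laplacian response
   (kernel `[[0,1,0],[1,−4,1],[0,1,0]]`, replicate-padded). The acceptance
   threshold is 1.8 for all taxa. The statistic is computed at frame level
   and reused as the object's sharpness by default; a config flag switches
   to the object bounding box, since either reading of "object sharpness" is
   defensible and the frame-level one is cheaper and stabler for a scene
   containing one object.
5. **Background subtraction** with a per-pixel sample store (KNN family):
   each pixel keeps N = 10 recent intensity samples; it is background iff
   ≥ 3 samples lie within a squared-intensity radius of 400 (ties count as
   matches, biasing toward background); one sample per pixel is replaced
   stochastically at rate 1/500 per frame from a seeded generator, so the
   model is fully deterministic given the seed and a stationary object is
   absorbed over a few multiples of 500 frames. During a 10-frame warmup the
   store is filled deterministically from the incoming frames and the
   output is forced to all-background. Shadow handling is omitted: a
   dark-field scene casts no shadows. These defaults mirror the de-facto
   defaults of the algorithm family; the warmup fill is our choice of a
   deterministic initialisation.
6. **Erode ×3, dilate ×3** with a 3×3 rectangle. Erosion removes drifting
   particles and thin appendages (a *Daphnia*'s tail spine and antennae
   would otherwise inflate the fitted major axis); dilation restores the
   main body to its original extent. Three iterations remove structures up
   to ~6 px across while bodies ≥ 20 px survive; counts are
   species-overridable in the run config because appendage-heavy taxa
   (e.g. *Polyphemus*) need a different budget. Outside-image pixels count
   as background for both operations.
7. **Contours → largest object.** 8-connected components, external
   boundaries only (holes ignored), deterministic top-left scan order.
   "Largest" means largest pixel count — the same area measure the filter
   thresholds use, so every decision is auditable from the output row.
8. **Ellipse fit** by stabilised direct least squares on the boundary
   polygon (marching-squares 0.5-level contour, i.e. sub-pixel positions
   halfway between foreground and background pixel centres). Major axis =
   length, minor = width, orientation in [0°, 180°). Boundaries with < 5
   points or degenerate (collinear) configurations reject the frame.
9. **Species filter**, five criteria in fixed order (area range, L/W ratio
   range, minimum brightness, minimum sharpness, minimum edge distance) so
   the reported first-failed criterion is deterministic. Brightness is the
   mean grayscale over the object's own pixels of the undistorted frame —
   the mask only locates the animal. Profiles for six taxa ship in
   `species.yaml` (the *Daphnia* row is the default when no species is
   chosen); new taxa are added by editing that file.
10. **Convert** accepted lengths to mm by a fixed scale factor estimated
    once per set-up (imaging a ruler is out of scope; the factor is a
    config value).

## The percentile estimator and its calibration

Free 3-D rotation means projected lengths undershoot the truth except when
the long axis lies in the image plane; rare overshoots come from
segmentation failures (unremoved appendages, merged particles). The
distribution is left-skewed with a hard ceiling near the true length, so the
per-video estimate is a high percentile, not a central tendency.

Calibration scans every integer percentile p ∈ [50, 100] and minimises
Σᵢ |manualᵢ − Q_p(lengthsᵢ)| over paired manual measurements; ties break
toward the lower percentile for determinism. Quantiles use linear
interpolation between order statistics (a nearest-rank mode exists for
sensitivity checks); with a few hundred frames per video a finer grid than
integers adds nothing. The calibrated value is stored per taxon in
`species.yaml` — 93 for *Daphnia* on the reference set-up. Reference
analyses of partly different data subsets report both 93 and 94 for
*D. magna*; we keep 93, the value in the canonical parameter table, and note
that the optimum is set-up-dependent: re-calibrate whenever the instrument,
optics or cuvette changes. Summaries with fewer than 10 supporting frames
are flagged low-support but still written.

The assessment utility reports Pearson r, the R² of a linear fit of
estimate on manual length, and the mean absolute and relative percentage
difference (mean |diff| / mean size × 100) in the <2 mm, 2–3 mm and >3 mm
size classes.

## Synthetic scenes

The generator renders what the filter criteria assume: one bright prolate
spheroid (semi-axes a ≥ b, orthographic projection) whose long-axis
direction random-walks on the unit sphere (step sd 8°/frame) and whose
centre swims with a persistent-velocity process (velocity memory 0.9,
acceleration sd 2.5 px/frame, rms speed ≈ 5.7 px/frame ≈ 0.6 body
lengths/s at the default scale) reflecting off the crop walls; plus
drifting particle specks, optional thin bright appendage along the major
axis, Gaussian optics blur (sd 0.8 px), Gaussian sensor noise (sd 2.5) and
optional forward lens distortion (the exact inverse of the undistortion
map, inverted by fixed-point iteration). Defaults: 1080×768 frames, 780
frames (30 s × 26 fps), body intensity 200 on background 10, 0.02 mm/px.
Output is lossless multi-page TIFF plus a truth CSV (per-frame tilt,
projected axes, centre, true length), so every run is bit-reproducible from
its seed.

What it does **not** emulate — and hence what passing tests do not show
about real animals: translucent or unevenly transparent bodies (the failure
mode for *Diaphanosoma*), perspective size change through the cuvette depth
(orthographic approximation), depth-dependent defocus (blur is a single
config value, not tied to position), non-ellipsoidal morphology, and
illumination flicker. Recovery numbers on synthetic cohorts are therefore a
validation of the algorithmic chain, not a field-accuracy claim.

## Validation experiments and problem sizes

`zoobooth.evaluation` contains the two end-to-end experiments the
acceptance script and tests run:

- **Length recovery**: 20 clips × 300 frames, true lengths uniform in
  0.8–4.0 mm at 0.02 mm/px, manual noise sd 0.02 mm; rendered on an
  840×600 frame with a 700×500 crop — the same mm scale with a smaller
  canvas, since a 4-mm body is only 200 px long and the geometry is
  otherwise immaterial. The species profile is the *Daphnia* structure with
  the pixel-area bounds widened to 200–40 000 px: the field table's
  1500-px minimum assumes adult-sized animals at the reference zoom and
  would reject every synthetic juvenile. Scored by mean relative error and
  Pearson r of calibrated estimates against truth.
- **Calibration recovery**: cohorts of 30 distributions × 300 samples drawn
  from a ceiling-at-truth skewed family, with the manual value defined as a
  known generative percentile (85/90/95); the scan must recover it exactly
  at zero noise and within ±2 at 0.02-mm noise, over 20 replicates.

## Numerical choices and degenerate inputs

- Quantile: linear order-statistic interpolation; p = 100 → maximum.
- Filter comparisons are inclusive at both ends (a value equal to a
  threshold passes).
- Empty mask → no detection; empty video → error; empty distribution →
  summary row with missing length and n_frames = 0.
- Background-model tie at the match radius counts as background.
- Undistortion inverts out-of-frame samples to 0 and rounds back to the
  input integer dtype.
- All stochastic components (background model updates, scene generation)
  take explicit seeds; batch processing is deterministic and per-video
  independent (results equal the concatenation of single-video runs).

## Known limitations

- Accuracy claims transfer to real footage only as far as the synthetic
  fidelity limits above allow; per-set-up percentile calibration against
  manual measurements remains mandatory.
- One animal per clip is assumed throughout; a second bright object of
  comparable size makes "largest object" ambiguous frame to frame.
- h264/MP4 decoding requires an imageio ffmpeg backend at run time; the
  native formats are multi-page TIFF and `.npy` stacks.
- The KNN background model is pixelwise-independent; absorption of a
  perfectly stationary animal has a long tail (a few pixels can take
  several decay horizons to flip).
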