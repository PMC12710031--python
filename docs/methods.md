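# Methods

`aircolor` implements per-frame ("in-flight") color correction for aerial
RGB crop imagery in which a 24-patch reference chart (ColorChecker
Classic) is visible in every frame — for example when a second platform
carries the chart beneath the camera for the whole mission. Because the
chart and the canopy are imaged under the same instantaneous illumination,
each frame can be corrected against the chart it contains, rather than
against a single fixed reference frame whose lighting may not represent
the rest of the flight.

## The correction model

Let `A` be the n x 3 matrix of observed patch RGB means (0-255 scale,
n <= 24 after exclusions) and `C` the corresponding reference sRGB values.
The correction is the bias-augmented linear model

    C = [A | 1] M,        M = argmin || [A|1] M - C ||_F

with `M` a 4 x 3 matrix whose fourth row absorbs per-channel offsets. `M`
is obtained by QR-based least squares; the closed-form normal-equations
solution `(AᵀA)⁻¹AᵀC` defines the same minimizer and is used as an
independent oracle in the tests, but is not the implementation, for the
usual conditioning reasons. The fitted `M` is applied to every pixel
(`[r g b 1] M`) and the result clipped to [0, 255]; the model operates on
stored (gamma-encoded) 8-bit values, with no linearization step, because
the dominant field distortions are well approximated as affine on the
stored values and a 3-term linear map on linear RGB would not absorb the
encoding anyway. Out-of-gamut corrected values are clipped; more elaborate
gamut mapping is out of scope.

Patches whose observed mean exceeds **250** on any channel are excluded
from the fit (auto-exposure over bright scenes saturates the most
reflective patches; saturated readings carry no photometric information).
The threshold is a strict inequality: a mean of exactly 250 is retained.
Fitting requires at least **6** included patches (4 unknowns per output
channel) and warns below **9**, the count at which correction accuracy is
reported to stabilize in prior work on chart-based correction.

## Chart model

The chart is the Classic 24-patch layout: 4 rows x 6 columns, row-major
indices 1-24, row 4 the neutral ramp from white (19) to black (24), with
patch 22 the 18 % gray used as the brightness reference. Reference colors
ship as packaged data using the widely published sRGB coordinates of the
pre-2014 chart edition; the packaged Lab values (D65, 2° observer) are
derived from those sRGB coordinates by the package's own conversion, so
the sRGB values are primary. (Manufacturer Lab specifications differ from
sRGB-derived values by ~1-2 dE00 per patch; if a use case needs the
manufacturer's colorimetry, a new chart variant can be added without code
changes.) Layout space is chart-relative — unit length = one patch side,
patch gap 0.15, margin 0.25, origin at the chart's top-left outer corner —
and every homography in the package maps layout space to image pixels.

## Chart detection

Detection is template matching: SIFT keypoints/descriptors on the
user-supplied template crop and the frame, nearest-neighbour matching
with a Lowe ratio test (0.75) and cross-check, then RANSAC homography
estimation (reprojection threshold 3 px, minimum 12 matches, minimum 10
inliers at >= 40 % inlier fraction). Frames without a chart fail these
gates and are reported as unsuccessful detections, not exceptions.

Keypoint matching alone leaves 2-3 px of corner error at the ~270 px
chart scale, so the homography is then *polished against the chart's own
structure*: the 96 patch-cell corners are projected through the estimate,
relocated to subpixel accuracy by a local corner fit, and the homography
refit on the relocated correspondences (two passes, displacements over
3 px rejected). On the synthetic suite this brings aggregate corner RMS
error to well under 1 px. The refinement honors the pixel-center
convention used throughout the package: pixel (i, j) has center
(j + 0.5, i + 0.5), and a pixel belongs to a polygon iff its center is
inside.

Patch colors are sampled from each patch cell shrunk about its center to
**80 %** of the patch area (side scale sqrt(0.8)), in the chart plane,
then projected — keeping boundary pixels and neighbours out of the mean.
Shrinking in the chart plane rather than in the image differs only at
second order under the near-nadir poses the generator produces, and
guarantees polygons never cross patch boundaries.

## Colorimetry

sRGB decoding, XYZ (D65) and CIELAB follow the standard definitions
(delegated to scikit-image). CIEDE2000 is implemented in-package with
parametric factors kL = kC = kH = 1; it reproduces the published 34-pair
worked-example dataset to four decimals (the dataset ships as packaged
data and covers the formula's discontinuities), and matches an
independent implementation to 1e-9 over a random Lab grid.

Per-frame brightness is the mean of the R, G, B channel means of the
18 % gray patch (patch 22), normalized to reference exposure settings
(ISO 100, 1/100 s, f/8) by

    L_std = L_raw · (ISO_ref / ISO_raw) · (t_ref / t_raw) · (N_raw / N_ref)²

The aperture factor is implemented exactly as written, with the raw
f-number in the numerator. Note that on physical grounds one would expect
the inverse ratio (image irradiance scales as 1/N², so normalizing *to* a
reference aperture should multiply by (N_ref/N_raw)² — equivalently the
formula above with the roles swapped); the printed convention is retained
deliberately, and only the identity and cancellation properties (which are
convention-independent) are relied on elsewhere in the package.

Cross-sensor consistency uses the mean intracluster distance: for each
patch, the Lab values measured by the different cameras form a cluster,
and the score is the mean Euclidean distance of members from the cluster
centroid; lower is tighter.

## Mask and overlap arithmetic

For mosaicking, the detected chart quadrilateral is expanded about its
center by 30 % per direction along the chart's long axis and 50 % per
direction along the short axis (so a 270 x 180 px chart yields a
432 x 360 px mask), sized to cover the chart's carrier platform. The
expansion is applied in the chart's own axes through the homography, so
rotated charts are masked correctly. Overlap sufficiency is
round-half-up pixel arithmetic: at 80 % forward/side overlap and
8192 x 5460 px frames, neighbouring frames share 4368 px forward and
6554 px sideways, far exceeding the mask extents, so masked content is
always recoverable from adjacent frames.

## Synthetic scenes

The generator produces fully ground-truthed frames: a soil-colored
background with leaf-like random ellipses (colors jittered around a green
leaf base color; no botanical realism claimed), and the chart rendered at
a known homography — uniform in-plane rotation, configurable scale
(default long axis 270 px in a 540 x 720 frame, emulating the flight
geometry), and mild perspective jitter (corner displacement up to ~3 % of
chart size, near-nadir). Radiometric distortion is per-channel affine:

    frame = clip(gain ⊙ (illumination · ideal) + offset + noise)

with gains drawn from [0.5, 1.0] (attenuation only, so distortion cannot
overexpose patches), offsets from [-10, 10], scalar illumination, and
additive Gaussian noise (default sigma 1.0 on the 8-bit scale, a knob
because real sensor noise is uncharacterized). Rendering is deterministic
given the truth record. The distortion benchmark redraws any frame whose
implied uncorrected mean patch dE00 falls below 5, so the benchmark
always contains meaningful distortion.

Flight series fix one sensor (constant gain/offset) and vary the
illumination multiplier per frame — constant, linear drift, or a seeded
multiplicative random walk — mimicking changing ambient light over a
mission. This is the scenario in which per-frame correction should beat
any single fixed-reference correction, and the package's comparison
reports exactly that: per-frame mean patch dE00 for the in-flight
strategy and for each chosen fixed reference.

What the generator does **not** emulate: BRDF and specular effects of
real leaves, canopy shadowing, motion blur, mixed pixels at chart edges,
JPEG artifacts, or spatially varying illumination within a frame. Passing
the synthetic suite therefore demonstrates correctness of the geometry,
algebra and pipeline plumbing under the stated distortion model — not
field-level accuracy claims.

## Evaluation analyses

* `delta_e_map` / `segment_by_threshold`: per-pixel dE00 against a
  reference Lab color; pixels with dE strictly below the threshold
  (default 10) are selected. Agreement with a labeled region is scored as
  |predicted AND truth| / |truth|.
* `plot_color_summary`: plot-mean RGB and Lab, plus the normalized (R+B)
  index, (R+B)/(R+G+B) computed on plot-mean channels. The index is a
  chromaticity normalization (invariant to uniform brightness scaling)
  and falls with chlorophyll absorption in the R and B bands; computing
  it on plot means (rather than per-pixel-then-averaging) was an open
  choice, made for robustness to dark-pixel noise.
* `camera_consistency_report`: per-camera chart error before/after each
  camera's own correction, and per-patch intracluster distances.
* `compare_fixed_vs_inflight`: strategy comparison described above; the
  fixed reference whose illumination sits at the series mean is expected
  to be the best fixed strategy, and the per-frame strategy to be at
  least as good as any fixed one.

## Problem sizes and numerical choices

The test suite and the acceptance script run entirely on generated
scenes: 50-frame distortion benchmarks for detection accuracy and
correction recovery, an 11-frame linear-drift series (35 % peak-to-peak)
for the strategy comparison, 20 rendered replicates for the patch-count
sensitivity curve, and a six-camera synthetic consistency study. Frames
are 540 x 720 px (760 x 1000 px when the chart is rendered above 1.4x
scale) — large enough for the ~270 px flight-scale chart geometry while
keeping the suites quick on a single CPU.

Ties and degenerate inputs: rank-deficient fits (collinear patch colors)
raise with a diagnostic rather than returning a garbage matrix; empty
sampling polygons and empty ground-truth regions raise naming the
offending patch/region; detection failures are result objects, never
exceptions, so batch runs continue past chart-free frames.

## Known limitations

* The detector assumes the template depicts the full chart (margin
  included); partial or heavily blurred templates are unsupported.
* One CCM per frame; no smoothing of CCMs across neighbouring frames and
  no spatially varying correction within a frame.
* Linear correction only — polynomial/nonlinear variants tend to overfit
  the 24 patches and distort colors outside the chart gamut.
* The synthetic leaf model is decorative for segmentation tests; it does
  not model canopy structure.
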