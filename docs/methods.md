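# Methods

## Problem and model

Intraoperative hyperspectral imaging with a push-broom spectrograph delivers
one-pixel-wide spectral lines (here 1 x 540 px with 100 bands over
500-1000 nm) instead of full images. When the laparoscope moves freely, those
lines sample an unknown curve across the tissue. This package reconstructs a
spatially coherent false-color panorama from the line stream by *borrowing
motion from the RGB video channel*: the camera motion estimated between RGB
frames (10 fps) is transferred onto the temporally corresponding lines
(70 fps) and the lines are composited incrementally onto a growing canvas.

Two assumptions underpin the geometry:

* **Pinhole camera over a planar scene.** All inter-view relations are 3 x 3
  homographies acting on homogeneous pixel coordinates (origin at the
  upper-left corner, x right, y down). Tissue curvature and parallax are
  outside the model.
* **Small inter-frame motion.** Linear interpolation of homographies between
  consecutive frames is accurate enough to place the ~7 lines captured per
  frame interval.

## Pipeline

1. **Preprocessing.** Frames are undistorted through a precomputed radial
   map (bilinear lookup) and contrast-normalized with CLAHE (clip limit 2.0
   on the conventional 256-bin scale, 8 x 8 tile grid). CLAHE runs on
   luminance; color channels are scaled proportionally. Lines pass through
   untouched. Both streams carry integer-millisecond timestamps; no
   cross-stream reordering or synchronization happens here.
2. **Local picking.** Up to 1000 ORB keypoints per frame; brute-force
   Hamming matching with Lowe's ratio 0.8 (strict inequality; with a
   single-candidate reference the test is skipped; duplicate claims on one
   reference keypoint resolve to the lowest distance); RANSAC homography
   (confidence 0.995, reprojection threshold 8 px, seeded). The estimate is
   gated: `no_motion` below 2 px maximum corner displacement (skipped, not
   an error), `low_inliers` below 40 inliers, `distorted` when the warped
   corner quadrilateral is non-convex, mirror-flipped, or changes area by
   more than 2x, `excessive_motion` beyond 25% of the frame width. Twenty
   consecutive invalid frames reset the panorama and database.

   The *reference* keypoint set advances only when a frame is processed: a
   slowly creeping camera therefore accumulates displacement across skipped
   frames until it crosses the motion threshold, instead of being skipped
   forever. The distortion check runs before the excessive-motion check, so
   a mirrored frame reports the shape defect rather than the large corner
   displacement it also causes.
3. **Global registration.** Frame keypoints are matched against a bounded
   database of panorama keypoints (coordinates in the coordinate system of
   the first frame of the sequence, 256-bit descriptors, unmatched-age
   counters). The 500 lowest-distance matches feed the same RANSAC + gates;
   motion/distortion gating uses the relative transform
   `inv(H_(i-1,P)) @ H_(i,P)`, since corner displacement of the cumulative
   frame-to-panorama homography would measure distance travelled since
   sequence start. Maintenance after each processed frame: the 50 strongest
   unmatched keypoints are added (warped by `H_(i,P)`), the 200
   lowest-distance inlier matches are refreshed in place (newer description
   wins), all inliers get age zero, outlier matches are deleted, everything
   else ages by one and entries older than 80 processed frames are evicted.
   On an implausible frame, every database entry matched into the rejected
   homography is deleted and nothing else changes.
4. **Line stitching.** Lines with `t_prev <= t + delta < t_cur` belong to
   the interval ending at the current frame (`delta` = 35 ms inter-stream
   delay by default). Per-line homographies come from the element-wise
   convex combination of the two frames' global homographies (normalized to
   bottom-right 1, weights k/n for k = 0..n-1), conjugated into slit-local
   coordinates by `inv(H_pos) inv(H_sens) H H_sens H_pos`. The adaptive line
   width is the largest absolute horizontal corner translation of the
   inter-frame motion divided by the line count, rounded up, floored at 1
   and capped at 8 px; duplicated columns trail the motion so the leading
   edge keeps its true position. Lines are warped with nearest-neighbor
   sampling and composited newest-wins. A pure-translation offset homography
   (integer shifts only) keeps canvas coordinates non-negative as the
   panorama grows left/up, and content more than 100 px beyond the current
   display window is cropped away, the offset absorbing the shift.
5. **Visualization.** The canvas is warped with the inverse of the latest
   view transform into the 960 x 540 camera view and alpha-blended
   (default 0.5) onto the RGB frame on occupied pixels only.

## Synthetic scanner

The generator emulates the dual-sensor acquisition at desk scale:

* **Scenes.** `usaf` — dark bar triplets at five scales on a lightly
  textured background, emulating a printed resolution chart; `texture` —
  multi-scale smoothed Gaussian noise with no large uniform regions,
  emulating a printed surgical image. Both deterministic in
  `(seed, kind, size)`. Default physical scale 85 mm per 960 px, the
  50 mm-working-distance value used for all mm conversions.
* **Trajectories.** Translation, rotation, scale, perspective and freehand
  (drifting heading plus rotation and zoom oscillations), all advancing
  along +x as a push-broom scan must. Poses are linearly interpolated in
  time; scan speeds are expressed in scene px per frame interval.
* **Streams.** Frames are projective views of the scene (optional barrel
  distortion and vignetting, off by default so accuracy tests have a clean
  geometric oracle). Each line is the scene content under the slit at its
  delay-corrected timestamp, expanded into 100 bands by a fixed smooth
  unit-mean spectral profile scaled by albedo — so grayscale false color
  (band mean) inverts the synthesis exactly and panorama pixels can be
  compared to scene albedo. Line timestamps lag ground truth by the
  configured delay; the pipeline's `+delta` correction re-synchronizes them.
  Gaussian pixel noise (intensity scale, default noise levels 0-0.01) is
  seeded.

What the generator does **not** emulate: parallax or any 3-D structure
(the planarity assumption is taken at face value), illumination flicker,
specular highlights, realistic tissue spectra (the spectral profile is an
artifact choice; real targets' spectra are unknown), motion blur, and
rolling-shutter effects. Passing tests therefore demonstrate the geometric
correctness of the registration/stitching machinery, not robustness to
real-tissue photometry.

## Evaluation protocol

`auto_ground_truth_error` replaces manual landmark annotation: landmarks are
sampled on stitched lines, mapped (a) through the simulator's exact geometry
and (b) through the pipeline's recorded per-line homographies, both into the
panorama frame fixed by the first RGB frame; the Euclidean distance between
the two is the registration error. Reports list raw distances plus median,
linear-interpolation quartiles and maximum, so any outlier convention can be
applied downstream. Pixel errors convert to millimeters by
cross-multiplication (`error_px * section_mm / width_px`).

Problem sizes used by the acceptance script and tests, chosen to exercise
the full pipeline at desk scale:

* translation protocol: 105 frames (10.5 s), ~735 lines, 1 px per frame
  interval, noise 0.003, 150 landmarks;
* freehand batch: ten seeded scans of 25 frames at 1-3 px per frame
  interval, noise 0.003, 100 landmarks each;
* visual fidelity: 30 frames at 6 px per frame interval, zero noise, zero
  inter-stream delay, compared pixel-wise against the ground-truth scene
  strip.

The visual-fidelity configuration is deliberately clean: at 6 px per
interval the per-line spacing stays below 1 px so the adaptive width is 1,
and zero delay aligns the line index fraction k/n with the line's true time
fraction. Under the default 35 ms delay the same scan measures a mean
absolute error around 3 intensity levels, which decomposes into two
inherent approximations of the method rather than registration error
(registration stays at ~0.2 px there): the interpolation weight k/n lags
the true time fraction by up to one line period, and duplicated
constant-width columns with newest-wins overwrite bias content by up to
half a line width against the scan direction — the documented cost of
piecewise-constant line duplication.

## Numerical choices and edge cases

* Homographies are renormalized to `H[2,2] = 1` before interpolation and
  comparison; the interpolation never attains the newer endpoint within an
  interval (it becomes weight 0 of the next), reproduced as specified.
* Matrix interpolation is element-wise on normalized matrices and is then
  conjugated per line; conjugation commutes with the convex combination up
  to normalization, so the order matches the definition exactly.
* Compositing uses nearest-neighbor sampling to preserve the
  piecewise-constant line model and strict newest-wins overwrite; canvas
  growth and forget-cropping use integer translations only, so offset
  bookkeeping is exact.
* The width formula covers spacing *within* an interval. The first interval
  after sequence start is truncated by the inter-stream delay (its lines
  with `t + delta` before the first frame do not exist), so its spacing can
  exceed the following interval's width and leave an isolated uncovered
  column near the scan start at high speeds; steady state is gap-free.
  Gap-freeness checks therefore start at the second interval.
* A line whose warped footprint lands more than 10 display diagonals away
  is skipped with a warning rather than growing the canvas unboundedly.
* ORB uses a 2-level pyramid by default (config `picking.n_scales`): planar
  scans at surgical working distances change scale slowly, so a shallow
  pyramid keeps per-frame cost low while covering the zoom range of the
  scan trajectories; deeper pyramids are a config switch away.
* The CLAHE clip limit is exposed on the conventional 256-bin scale and
  mapped internally to the normalized clip fraction (`clip/256`) of the
  underlying implementation.
* Degenerate inputs: estimation with fewer than 4 matches, collinear
  correspondences, or singular calibration matrices raise typed errors that
  the pipeline gates as invalid frames; a flat (textureless) frame yields an
  empty keypoint set, which follows the same path.

## Configuration

All thresholds are config-exposed (`PipelineConfig`, YAML-loadable):
`picking.max_keypoints` (1000), `picking.lowe_ratio` (0.8),
`picking.ransac_confidence` (0.995), `picking.ransac_threshold_px` (8.0),
`picking.min_inliers` (40), `picking.min_motion_px` (2),
`picking.max_motion_frac` (0.25), `picking.max_invalid` (20),
`registration.max_matches` (500), `registration.max_new` (50),
`registration.max_updates` (200), `registration.max_age` (80),
`stitching.delta_ms` (35), `stitching.width_cap` (8),
`stitching.fixed_width` (3, used when adaptive width is disabled),
`stitching.forget_margin_px` (100). The motion/distortion gate numbers are
package defaults; the inlier count, ratio, RANSAC parameters, database caps,
width cap, forget margin and delay follow the reference acquisition setup.

## Known limitations

* Drift is contained, not eliminated: database coordinates are refreshed
  from warped current detections, so very long sequences accumulate slow
  bias. No bundle adjustment or loop closure is performed.
* Seams between overlapping passes are not blended or exposure-compensated;
  newest-wins can leave visible intensity steps under vignetting.
* The inter-stream delay is treated as a constant; drift of the delay over
  a sequence would translate directly into along-track placement error.
* Homography interpolation is uniform in line index, not in time; with the
  default delay this contributes a sub-pixel along-track lag at moderate
  speeds (see the evaluation section).
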