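# hsistitch

Real-time freehand panorama stitching for line-scan hyperspectral imaging,
guided by an RGB video stream.

## The problem

Push-broom hyperspectral cameras used in minimally invasive surgery record a
full reflectance spectrum (100 bands, 500-1000 nm) along a single
one-pixel-wide line at a time. A motorized sweep yields a static hypercube,
but a freely moving laparoscope yields an unordered stream of lines sampled
along an unknown path. This package reconstructs a spatially coherent
false-color panorama from that stream *without any motor or tracker*: camera
motion is estimated from the accompanying RGB video (960 x 540 at 10 fps),
transferred onto the temporally corresponding hyperspectral lines (1 x 540
x 100 at 70 fps), and the lines are composited incrementally onto a growing,
globally registered canvas that can be overlaid on the live RGB view.

It is aimed at researchers in computational biophotonics and surgical
imaging who want a hardware-free, fully testable reference implementation:
a synthetic dual-sensor scanner renders both streams from a known planar
scene with ground-truth homographies per timestamp, so every stage — and the
whole pipeline — can be scored against exact truth.

## The method

All geometry is homographies on a planar scene. Per RGB frame `I_i`:

* **Local picking** — ORB keypoints (1000 strongest), brute-force Hamming
  matching with Lowe's ratio 0.8, RANSAC (confidence 0.995, threshold 8 px)
  for the frame-to-frame homography `H_(i,i-1): I_i -> I_(i-1)`, followed by
  plausibility gates (>= 40 inliers, motion neither < 2 px nor > 25% of the
  frame width, no degenerate warp). Twenty consecutive invalid frames reset
  the panorama.
* **Global registration** — the frame is registered directly to the
  panorama through a bounded keypoint database (coordinates + descriptors +
  age), giving `H_(i,P): I_i -> P` and containing drift. Database caps: 500
  matches used, 50 additions and 200 refreshes per frame, eviction after 80
  unmatched frames.
* **Line stitching** — the buffered lines with `t_(i-1) <= t_j + delta < t_i`
  (inter-stream delay `delta` ~ 35 ms) get per-line homographies by linear
  interpolation between `H_(i-1,P)` and `H_(i,P)`, conjugated into
  slit-local coordinates by the sensor calibration
  (`H' = H_pos^-1 H_sens^-1 H H_sens H_pos`), widened adaptively
  (`w = ceil(T / n)`, capped at 8 px) so consecutive lines tile without
  gaps, and composited newest-wins. An accumulated translation offset keeps
  canvas coordinates non-negative; a forget function crops content more
  than 100 px outside the display window.
* **Visualization** — the panorama is warped back into the camera view with
  the inverse of the latest stitching transform and alpha-blended onto the
  RGB frame.

## Worked example

```python
import hsistitch as hs

scene = hs.generate_scene(seed=3, kind="texture", width=2000, height=1200)
trajectory = hs.make_trajectory("freehand", n_frames=25,
                                speed_px_per_frame=2.0, start=(200, 300), seed=3)
streams = hs.simulate_scan(scene, trajectory, noise_sd=0.003, seed=3)
frames, lines = hs.ingest(streams)                     # undistort + CLAHE
result = hs.FreehandStitcher(streams.calibration).run(frames, lines)
report = hs.auto_ground_truth_error(result, streams.ground_truth,
                                    n_landmarks=150, seed=1)
print(report.median, report.q1, report.q3)
```

Output (`examples/04_evaluate_accuracy.py`):

```
landmarks: 150
median error: 0.221 px (IQR 0.128-0.394, max 0.914)
in millimeters at 85 mm / 960 px: median 0.0195 mm, 95th percentile 0.0554 mm
```

The median registration error is the Euclidean distance, over sampled
landmarks, between where the pipeline placed line content on the panorama
and where the simulator's ground truth says it belongs; 0.22 px means the
stitched hyperspectral data lands within a quarter of a camera pixel of its
true position, about 0.02 mm on the target at a 50 mm working distance
(85 mm of target across the 960 px frame width).

The other scripts in `examples/` show stream simulation, panorama stitching
with the per-frame verdict log, overlay rendering, and the
error-versus-speed sweep. A thin CLI covers the same stages from the shell:

```bash
hsistitch simulate --scene-kind texture --trajectory freehand --out scratch/scan
hsistitch stitch --input scratch/scan --out scratch/run
hsistitch render --input scratch/scan --alpha 0.5 --out scratch/overlays
hsistitch evaluate --run scratch/scan --out scratch/report.json
```

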