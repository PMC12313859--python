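"""Simulate a dual-sensor freehand scan of a synthetic planar scene.

Emulates the laparoscopic acquisition geometry: a 960x540 RGB video stream
at 10 fps and a one-pixel-wide, 100-band hyperspectral line stream at 70 fps
sweeping over the same planar target, with the HSI timestamps lagging the
RGB clock by 35 ms.
"""

import hsistitch as hs

scene = hs.generate_scene(seed=0, kind="texture", width=2000, height=1200)
trajectory = hs.make_trajectory("freehand", n_frames=30, speed_px_per_frame=2.0,
                                start=(200, 300), seed=0)
streams = hs.simulate_scan(scene, trajectory, rgb_fps=10, hsi_fps=70,
                           delay_ms=35.0, noise_sd=0.003, seed=0)

print(f"frames: {len(streams.frames)} (10 fps, 960x540x3)")
print(f"lines:  {len(streams.lines)} (70 fps, 1x540x100)")
print(f"first line timestamps (ms): "
      f"{[l.timestamp_ms for l in streams.lines[:8]]}")
n_gt = len(streams.ground_truth.line_to_scene)
print(f"ground truth: one scene-placement homography per line ({n_gt} total)")
# About 7 lines fall between consecutive RGB frames: the stitcher will
# assign each of them to exactly one inter-frame interval.
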