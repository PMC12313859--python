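"""Render the growing panorama as a semitransparent overlay on the RGB view.

The panorama lives in its own canvas coordinates; for display it is warped
with the inverse of the latest stitching transform into the current camera
view and alpha-blended onto the RGB frame on occupied pixels only.
"""

from pathlib import Path

import imageio.v3 as iio

import hsistitch as hs

scene = hs.generate_scene(seed=0, kind="usaf", width=2000, height=1200)
trajectory = hs.make_trajectory("translation", n_frames=15, speed_px_per_frame=4.0)
streams = hs.simulate_scan(scene, trajectory, seed=0)
frames, lines = hs.ingest(streams)

stitcher = hs.FreehandStitcher(streams.calibration)
result = stitcher.run(frames, lines)

overlay = hs.render_overlay(
    frames[-1], result.state, result.view_transform, alpha=0.5
)
Path("scratch").mkdir(exist_ok=True)
iio.imwrite("scratch/overlay.png", overlay.image)
changed = (overlay.image != frames[-1].image).any(axis=2).mean()
print(f"overlay written to scratch/overlay.png")
print(f"{changed:.1%} of the view is augmented with stitched HSI data")
print("alpha=0 would show the pure RGB frame; alpha=1 the pure panorama")
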