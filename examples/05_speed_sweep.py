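"""Registration error as a function of scanning speed.

One simulate + stitch + evaluate cycle per speed; faster scans move more
between consecutive lines, so interpolation and line-width errors grow
roughly linearly with speed until the plausibility gates start rejecting
frames altogether.
"""

import hsistitch as hs

scene = hs.generate_scene(seed=0, kind="texture", width=2000, height=1200)
sweep = hs.speed_sweep(scene, speeds=[2.0, 4.0, 8.0], n_frames=14, seed=0)

for row in sweep["rows"]:
    if row["failed"]:
        print(f"speed {row['speed']:>4} px/frame: reconstruction failed")
    else:
        print(f"speed {row['speed']:>4} px/frame: "
              f"mean error {row['mean_error']:.3f} px, "
              f"median {row['median_error']:.3f} px")
fit = sweep["linear_fit"]
print(f"linear fit: error ~ {fit['slope']:.4f} * speed + {fit['intercept']:.4f}")
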