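"""On-disk layout for simulated scans and stitch runs.

A scan directory holds::

    frames/000000.png ...   8-bit RGB frames
    lines.tiff              float32 line stack, (J, 540, 100)
    timestamps.json         {"frames_ms": [...], "lines_ms": [...]}
    calibration.yaml        the calibration bundle
    ground_truth.json       optional simulator ground truth
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .exceptions import IngestionError
from .preprocess import CalibrationBundle
from .synthetic_scanner import RawFrame, RawLine, ScanGroundTruth, ScanStreams


def save_scan(directory: str | Path, streams: ScanStreams) -> Path:
    out = Path(directory)
    (out / "frames").mkdir(parents=True, exist_ok=True)
    for frame in streams.frames:
        iio.imwrite(out / "frames" / f"{frame.index:06d}.png", frame.image)
    stack = np.stack([l.spectra for l in streams.lines]).astype(np.float32)
    tifffile.imwrite(out / "lines.tiff", stack)
    (out / "timestamps.json").write_text(
        json.dumps(
            {
                "frames_ms": [f.timestamp_ms for f in streams.frames],
                "lines_ms": [l.timestamp_ms for l in streams.lines],
            }
        )
    )
    streams.calibration.save(out / "calibration.yaml")
    if streams.ground_truth is not None:
        (out / "ground_truth.json").write_text(
            json.dumps(streams.ground_truth.to_dict())
        )
    return out


def load_scan(directory: str | Path) -> ScanStreams:
    src = Path(directory)
    ts_path = src / "timestamps.json"
    if not ts_path.exists():
        raise IngestionError(f"missing timestamp sidecar {ts_path}")
    stamps = json.loads(ts_path.read_text())
    calibration = (
        CalibrationBundle.load(src / "calibration.yaml")
        if (src / "calibration.yaml").exists()
        else CalibrationBundle()
    )
    frame_files = sorted(
        list((src / "frames").glob("*.png")) + list((src / "frames").glob("*.tiff"))
    )
    if len(frame_files) != len(stamps["frames_ms"]):
        raise IngestionError(
            f"{len(frame_files)} frame files vs {len(stamps['frames_ms'])} timestamps"
        )
    frames = [
        RawFrame(image=np.asarray(iio.imread(path)), timestamp_ms=int(t), index=i)
        for i, (path, t) in enumerate(zip(frame_files, stamps["frames_ms"]))
    ]
    stack = tifffile.imread(src / "lines.tiff")
    if stack.ndim != 3 or stack.shape[0] != len(stamps["lines_ms"]):
        raise IngestionError("line stack does not match its timestamps")
    lines = [
        RawLine(spectra=stack[j].astype(float), timestamp_ms=int(t), index=j)
        for j, t in enumerate(stamps["lines_ms"])
    ]
    gt = None
    if (src / "ground_truth.json").exists():
        gt = ScanGroundTruth.from_dict(
            json.loads((src / "ground_truth.json").read_text())
        )
    return ScanStreams(
        frames=frames, lines=lines, ground_truth=gt, calibration=calibration
    )


def save_run(directory: str | Path, result) -> Path:
    """Persist a stitch run: panorama, occupancy mask, homography log."""
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    canvas = np.clip(np.rint(result.state.canvas * 255.0), 0, 255).astype(np.uint8)
    if canvas.size == 0:
        canvas = np.zeros((1, 1, 3), dtype=np.uint8)
    iio.imwrite(out / "panorama.png", canvas)
    mask = (result.state.mask.astype(np.uint8) * 255) if result.state.mask.size else (
        np.zeros((1, 1), dtype=np.uint8)
    )
    iio.imwrite(out / "mask.png", mask)
    log = {
        "resets": result.resets,
        "offset": result.state.offset.tolist(),
        "view_transform": (
            result.view_transform.tolist() if result.view_transform is not None
            else None
        ),
        "frames": [
            {
                "index": r.index,
                "timestamp_ms": r.timestamp_ms,
                "verdict_local": r.verdict_local,
                "verdict_global": r.verdict_global,
                "n_inliers_local": r.n_inliers_local,
                "n_inliers_global": r.n_inliers_global,
                "H_global": r.H_global.tolist() if r.H_global is not None else None,
                "stitched_lines": r.stitched_lines,
                "line_width": r.line_width,
            }
            for r in result.frame_records
        ],
        "lines": [
            {
                "line_index": r.line_index,
                "timestamp_ms": r.timestamp_ms,
                "width": r.width,
                "H_line": r.H_line.tolist(),
                "H_final": r.H_final.tolist(),
            }
            for r in result.state.records
        ],
    }
    (out / "homographies.json").write_text(json.dumps(log))
    return out
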