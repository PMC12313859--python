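"""Registration accuracy metrics.

Accuracy is quantified as the Euclidean distance between corresponding
landmarks seen by the RGB stream (ground truth) and by the stitched HSI
panorama, summarized by the median and interquartile range, optionally
converted from pixels to millimeters through the known target width
(cross-multiplication: at a 50 mm working distance the 960 px frame spans
85 mm of the target).  On simulated scans the manual annotation step is
replaced by the simulator's exact ground-truth geometry.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import homography as hg
from .synthetic_scanner import ScanGroundTruth, Scene, make_trajectory, simulate_scan


@dataclass
class KeypointPair:
    """One annotated landmark on the RGB view and on the HSI panorama."""

    rgb_xy: tuple[float, float]
    pano_xy: tuple[float, float]
    frame_id: int = 0
    source: str = "manual"

    @property
    def distance(self) -> float:
        dx = self.pano_xy[0] - self.rgb_xy[0]
        dy = self.pano_xy[1] - self.rgb_xy[1]
        return float(np.hypot(dx, dy))


@dataclass
class ErrorReport:
    """Distance summary: median, linear-interpolation quartiles, maximum."""

    distances: np.ndarray
    median: float = field(init=False)
    q1: float = field(init=False)
    q3: float = field(init=False)
    max: float = field(init=False)

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        if d.size == 0:
            raise ValueError("error report requires at least one distance")
        self.distances = d
        self.q1, self.median, self.q3 = (
            float(v) for v in np.percentile(d, [25, 50, 75])
        )
        self.max = float(d.max())

    def percentile(self, p: float) -> float:
        return float(np.percentile(self.distances, p))

    def in_mm(self, image_width_px: float = 960.0, section_width_mm: float = 85.0):
        """The same report with all distances converted to millimeters."""
        return ErrorReport(
            distances=px_to_mm(self.distances, image_width_px, section_width_mm)
        )

    def to_dict(self) -> dict:
        return {
            "n": int(self.distances.size),
            "median": self.median,
            "q1": self.q1,
            "q3": self.q3,
            "max": self.max,
            "distances": self.distances.tolist(),
        }


def registration_error(pairs: list[KeypointPair]) -> ErrorReport:
    """Euclidean keypoint-pair error report (deterministic)."""
    if not pairs:
        raise ValueError("at least one keypoint pair is required")
    return ErrorReport(distances=np.array([p.distance for p in pairs]))


def load_pairs(path: str | Path) -> list[KeypointPair]:
    """Read annotation pairs from CSV: frame_id, x_rgb, y_rgb, x_pano, y_pano."""
    pairs = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            pairs.append(
                KeypointPair(
                    rgb_xy=(float(row["x_rgb"]), float(row["y_rgb"])),
                    pano_xy=(float(row["x_pano"]), float(row["y_pano"])),
                    frame_id=int(row.get("frame_id", 0)),
                    source="manual",
                )
            )
    return pairs


def px_to_mm(error_px, image_width_px: float, section_width_mm: float):
    """Cross-multiply a pixel error to millimeters on the target plane."""
    if image_width_px <= 0 or section_width_mm <= 0:
        raise ValueError("widths must be positive")
    err = np.asarray(error_px, dtype=float)
    if np.any(err < 0):
        raise ValueError("errors must be non-negative")
    out = err * section_width_mm / image_width_px
    return float(out) if np.isscalar(error_px) or out.ndim == 0 else out


def auto_ground_truth_error(
    result,
    gt: ScanGroundTruth,
    n_landmarks: int = 200,
    seed: int = 0,
    max_attempts: int = 50,
) -> ErrorReport:
    """Score a stitch run of a simulated scan against exact ground truth.

    Landmarks are sampled on stitched lines; each is mapped (a) through the
    simulator's true geometry and (b) through the pipeline's recorded
    per-line homographies, both into the panorama coordinate system fixed by
    the first frame.  The displacement between the two is the registration
    error.  Deterministic for a fixed seed.
    """
    records = result.state.records
    if not records:
        raise ValueError("stitch run produced no lines to evaluate")
    C = gt.calibration.line_to_frame
    scene_to_pano = np.linalg.inv(C) @ gt.scene_to_frame[0]
    rng = np.random.default_rng(seed)
    offset = result.state.offset
    mask = result.state.mask
    distances = []
    for _ in range(n_landmarks):
        for _attempt in range(max_attempts):
            rec = records[int(rng.integers(len(records)))]
            y = float(rng.uniform(10.0, 530.0))
            p = np.array([[0.0, y]])
            pos_pipe = hg.apply(rec.H_line, p)[0]
            canvas_xy = hg.apply(offset, pos_pipe[None, :])[0]
            cx, cy = int(round(canvas_xy[0])), int(round(canvas_xy[1]))
            if not (
                0 <= cy < mask.shape[0] and 0 <= cx < mask.shape[1] and mask[cy, cx]
            ):
                continue
            truth_map = scene_to_pano @ gt.line_to_scene[rec.line_index]
            pos_true = hg.apply(truth_map, p)[0]
            distances.append(float(np.linalg.norm(pos_pipe - pos_true)))
            break
        else:
            raise ValueError("could not place a landmark on occupied panorama")
    return ErrorReport(distances=np.array(distances))


def speed_sweep(
    scene: Scene,
    speeds: list[float],
    n_frames: int = 40,
    kind: str = "translation",
    seed: int = 0,
    noise_sd: float = 0.0,
    n_landmarks: int = 100,
    stitcher_factory=None,
) -> dict:
    """One simulate+stitch+evaluate cycle per scanning speed.

    Speeds are in scene px per RGB frame interval.  A speed where the
    pipeline stitches fewer than a quarter of the emitted lines is recorded
    as failed.  Returns rows of (speed, mean/median error) plus the linear
    regression of mean error on speed over the successful rows.
    """
    from .pipeline import FreehandStitcher
    from .preprocess import ingest

    rows = []
    for speed in speeds:
        traj = make_trajectory(kind, n_frames, speed, seed=seed)
        streams = simulate_scan(scene, traj, noise_sd=noise_sd, seed=seed)
        frames, lines = ingest(streams)
        stitcher = (
            stitcher_factory() if stitcher_factory else FreehandStitcher(
                streams.calibration
            )
        )
        res = stitcher.run(frames, lines)
        if len(res.state.records) < len(lines) // 4:
            rows.append({"speed": speed, "failed": True})
            continue
        report = auto_ground_truth_error(
            res, streams.ground_truth, n_landmarks=n_landmarks, seed=seed
        )
        rows.append(
            {
                "speed": speed,
                "failed": False,
                "mean_error": float(report.distances.mean()),
                "median_error": report.median,
            }
        )
    ok = [(r["speed"], r["mean_error"]) for r in rows if not r["failed"]]
    fit = None
    if len(ok) >= 2:
        xs, ys = zip(*ok)
        slope, intercept = np.polyfit(xs, ys, 1)
        fit = {"slope": float(slope), "intercept": float(intercept)}
    return {"rows": rows, "linear_fit": fit}
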