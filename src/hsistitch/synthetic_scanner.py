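"""Synthetic dual-sensor scanner: planar scenes, trajectories, both streams.

Real recordings of the laparoscopic dual-sensor system (an RGB video camera
at 10 fps plus a push-broom spectrograph emitting one-pixel-wide lines at
70 fps through the same optics) are not available at desk scale, so this
module emulates the device: it renders a planar test scene under a moving
camera, emits the RGB frame stream and the HSI line stream with realistic
asynchronous timestamps, and records per-timestamp ground-truth homographies
so every downstream stage can be scored against known motion.

The emulation mirrors the physical acquisition geometry:

* each RGB frame is a 960 x 540 projective view of the scene under the pose
  at its timestamp (optionally barrel-distorted and vignetted);
* each HSI line is the scene content under the slit (the center column of
  the RGB view, positioned by ``h_sens @ h_pos``) at the line's timestamp,
  expanded into a 100-band spectrum by a fixed smooth unit-mean spectral
  profile scaled by the scene albedo, so that the band mean recovers the
  gray albedo exactly;
* line timestamps lag the RGB clock by the configured inter-stream delay, so
  the pipeline's ``+delta`` correction re-synchronizes them.

Timestamps are integer milliseconds from scan start.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from skimage.transform import ProjectiveTransform, warp

from . import homography as hg
from .exceptions import ConfigurationError, SimulationError
from .preprocess import (
    CalibrationBundle,
    FRAME_HEIGHT,
    FRAME_WIDTH,
    LINE_HEIGHT,
    N_BANDS,
    WAVELENGTHS_NM,
)

SCENE_KINDS = ("usaf", "texture")
TRAJECTORY_KINDS = ("translation", "rotation", "scale", "perspective", "freehand")

#: Fixed smooth unit-mean spectral shape used to expand gray albedo into a
#: 100-band spectrum.  Unit mean makes grayscale false-coloring (band mean)
#: the exact inverse of the synthesis.
_raw = 0.7 + 0.6 * np.exp(-(((WAVELENGTHS_NM - 680.0) / 150.0) ** 2))
SPECTRAL_PROFILE = _raw / _raw.mean()
del _raw


# ---------------------------------------------------------------------------
# scenes


@dataclass
class Scene:
    """A planar test target: gray albedo in [0, 1] plus physical scale."""

    albedo: np.ndarray  # (H, W) float in [0, 1]
    mm_per_px: float
    kind: str
    seed: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.albedo.shape


def _texture_albedo(rng: np.random.Generator, height: int, width: int) -> np.ndarray:
    """Multi-scale smoothed noise: varying gradients, no large uniform areas."""
    acc = np.zeros((height, width))
    for sigma in (2, 4, 8, 16, 32):
        acc += sigma * gaussian_filter(rng.standard_normal((height, width)), sigma)
    lo, hi = np.percentile(acc, [0.5, 99.5])
    acc = np.clip((acc - lo) / (hi - lo), 0.0, 1.0)
    return 0.05 + 0.9 * acc


def _usaf_albedo(rng: np.random.Generator, height: int, width: int) -> np.ndarray:
    """High-contrast axis-aligned bar triplets at several scales.

    Emulates a resolution test chart: groups of three dark bars (horizontal
    and vertical orientation) at five bar widths, tiled over a light
    background with faint texture so feature detection works between groups.
    """
    img = 0.82 + 0.08 * gaussian_filter(rng.standard_normal((height, width)), 6)
    img = np.clip(img, 0.7, 0.95)
    bar_widths = (48, 32, 20, 12, 8)
    step = 260
    k = 0
    for y0 in range(40, height - 300, step):
        for x0 in range(40, width - 300, step):
            w = bar_widths[k % len(bar_widths)]
            k += 1
            jx = int(rng.integers(-30, 31))
            jy = int(rng.integers(-30, 31))
            x, y = x0 + jx, y0 + jy
            bar_len = 5 * w
            # horizontal triplet: three bars stacked vertically
            for m in range(3):
                yy = y + m * 2 * w
                img[yy : yy + w, x : x + bar_len] = 0.05
            # vertical triplet to the right of it
            xv = x + bar_len + 2 * w
            for m in range(3):
                xx = xv + m * 2 * w
                img[y : y + bar_len, xx : xx + w] = 0.05
    return img


def generate_scene(
    seed: int, kind: str, width: int, height: int, mm_per_px: float = 85.0 / 960.0
) -> Scene:
    """Render a deterministic planar test scene.

    ``mm_per_px`` defaults to the scale of a 50 mm working distance, where a
    960 px frame spans 85 mm of the target.
    """
    if kind not in SCENE_KINDS:
        raise ConfigurationError(f"unknown scene kind {kind!r}; expected {SCENE_KINDS}")
    if width < 512 or height < 512:
        raise ConfigurationError("scene must be at least 512 x 512")
    rng = np.random.default_rng(seed)
    if kind == "usaf":
        albedo = _usaf_albedo(rng, height, width)
    else:
        albedo = _texture_albedo(rng, height, width)
    return Scene(albedo=albedo, mm_per_px=mm_per_px, kind=kind, seed=seed)


# ---------------------------------------------------------------------------
# trajectories


@dataclass
class Trajectory:
    """Per-frame camera poses over a planar scene.

    ``poses`` is an ``(n, 6)`` array with columns ``tx, ty`` (scene px of the
    frame origin), ``rot_deg`` (in-plane rotation about the frame center),
    ``scale`` (zoom about the frame center), and ``gx, gy`` (perspective tilt
    coefficients).  Poses are linearly interpolable to any timestamp between
    frame times.
    """

    poses: np.ndarray
    kind: str
    speed_px_per_frame: float

    @property
    def n_frames(self) -> int:
        return self.poses.shape[0]


def pose_matrix(pose: np.ndarray) -> np.ndarray:
    """Frame -> scene homography for one pose row."""
    tx, ty, rot_deg, scale, gx, gy = (float(v) for v in pose)
    c, s = np.cos(np.deg2rad(rot_deg)), np.sin(np.deg2rad(rot_deg))
    center = np.array([FRAME_WIDTH / 2.0, FRAME_HEIGHT / 2.0])
    rs = np.array(
        [[scale * c, -scale * s, 0.0], [scale * s, scale * c, 0.0], [0.0, 0.0, 1.0]]
    )
    tilt = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [gx, gy, 1.0]])
    to_center = hg.translation(-center[0], -center[1])
    from_center = hg.translation(center[0], center[1])
    return hg.translation(tx, ty) @ from_center @ rs @ tilt @ to_center


def make_trajectory(
    kind: str,
    n_frames: int,
    speed_px_per_frame: float,
    start: tuple[float, float] = (100.0, 100.0),
    seed: int | None = None,
    rot_amplitude_deg: float = 8.0,
    scale_amplitude: float = 0.06,
    tilt_amplitude: float = 4e-5,
) -> Trajectory:
    """Construct one of the standard scan paths.

    All kinds advance along +x at ``speed_px_per_frame`` (a push-broom scan
    needs lateral motion to cover the scene); the named transform family is
    layered on top.  ``freehand`` combines translation with drifting heading,
    rotation and zoom oscillations, seeded for reproducibility.
    """
    if kind not in TRAJECTORY_KINDS:
        raise ConfigurationError(
            f"unknown trajectory kind {kind!r}; expected {TRAJECTORY_KINDS}"
        )
    i = np.arange(n_frames, dtype=float)
    phase = 2.0 * np.pi * i / max(n_frames, 2)
    tx = start[0] + speed_px_per_frame * i
    ty = np.full(n_frames, start[1])
    rot = np.zeros(n_frames)
    scale = np.ones(n_frames)
    gx = np.zeros(n_frames)
    gy = np.zeros(n_frames)
    if kind == "rotation":
        rot = rot_amplitude_deg * np.sin(phase)
    elif kind == "scale":
        scale = 1.0 + scale_amplitude * np.sin(phase)
    elif kind == "perspective":
        gx = tilt_amplitude * np.sin(phase)
        gy = tilt_amplitude * np.cos(phase)
    elif kind == "freehand":
        rng = np.random.default_rng(0 if seed is None else seed)
        phases = rng.uniform(0, 2 * np.pi, size=4)
        heading = 0.35 * np.sin(phase + phases[0])
        dx = speed_px_per_frame * np.cos(heading)
        dy = speed_px_per_frame * np.sin(heading)
        tx = start[0] + np.concatenate([[0.0], np.cumsum(dx[:-1])])
        ty = start[1] + np.concatenate([[0.0], np.cumsum(dy[:-1])])
        rot = 0.6 * rot_amplitude_deg * np.sin(phase * 2 + phases[1])
        scale = 1.0 + 0.6 * scale_amplitude * np.sin(phase * 1.5 + phases[2])
    poses = np.column_stack([tx, ty, rot, scale, gx, gy])
    return Trajectory(poses=poses, kind=kind, speed_px_per_frame=speed_px_per_frame)


class PoseInterpolator:
    """Linear pose interpolation over time, with end-segment extrapolation."""

    def __init__(self, frame_times_ms: np.ndarray, poses: np.ndarray) -> None:
        self.times = np.asarray(frame_times_ms, dtype=float)
        self.poses = np.asarray(poses, dtype=float)
        if len(self.times) != len(self.poses):
            raise ValueError("one pose per frame time required")

    def __call__(self, t_ms: float) -> np.ndarray:
        t = float(t_ms)
        times, poses = self.times, self.poses
        if len(times) == 1:
            return poses[0]
        k = int(np.clip(np.searchsorted(times, t, side="right") - 1, 0, len(times) - 2))
        u = (t - times[k]) / (times[k + 1] - times[k])
        return (1.0 - u) * poses[k] + u * poses[k + 1]

    def matrix(self, t_ms: float) -> np.ndarray:
        return pose_matrix(self(t_ms))


# ---------------------------------------------------------------------------
# scan simulation


@dataclass
class RawFrame:
    image: np.ndarray  # (540, 960, 3) uint8
    timestamp_ms: int
    index: int


@dataclass
class RawLine:
    spectra: np.ndarray  # (540, 100) float
    timestamp_ms: int
    index: int


@dataclass
class ScanGroundTruth:
    """True geometry of a simulated scan, keyed by timestamp."""

    frame_timestamps_ms: list[int]
    scene_to_frame: list[np.ndarray]  # per frame: 3x3, scene -> frame coords
    line_timestamps_ms: list[int]  # emitted (delayed) timestamps
    line_to_scene: list[np.ndarray]  # per line: 3x3, slit-local -> scene coords
    delta_ms: float
    mm_per_px: float
    calibration: CalibrationBundle
    poses: np.ndarray = field(default_factory=lambda: np.zeros((0, 6)))

    def to_dict(self) -> dict:
        return {
            "frame_timestamps_ms": list(map(int, self.frame_timestamps_ms)),
            "scene_to_frame": [H.tolist() for H in self.scene_to_frame],
            "line_timestamps_ms": list(map(int, self.line_timestamps_ms)),
            "line_to_scene": [H.tolist() for H in self.line_to_scene],
            "delta_ms": self.delta_ms,
            "mm_per_px": self.mm_per_px,
            "calibration": self.calibration.to_dict(),
            "poses": self.poses.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScanGroundTruth":
        return cls(
            frame_timestamps_ms=d["frame_timestamps_ms"],
            scene_to_frame=[np.array(H) for H in d["scene_to_frame"]],
            line_timestamps_ms=d["line_timestamps_ms"],
            line_to_scene=[np.array(H) for H in d["line_to_scene"]],
            delta_ms=d["delta_ms"],
            mm_per_px=d["mm_per_px"],
            calibration=CalibrationBundle.from_dict(d["calibration"]),
            poses=np.array(d.get("poses", [])),
        )


@dataclass
class ScanStreams:
    """In-memory result of a simulated scan: both streams plus ground truth."""

    frames: list[RawFrame]
    lines: list[RawLine]
    ground_truth: ScanGroundTruth
    calibration: CalibrationBundle
    scene: Scene | None = None


def _check_in_scene(points: np.ndarray, shape: tuple[int, int], t_ms: int, what: str):
    h, w = shape
    x, y = points[:, 0], points[:, 1]
    if np.any(x < 0) or np.any(y < 0) or np.any(x > w - 1) or np.any(y > h - 1):
        raise SimulationError(
            f"trajectory leaves the scene at t={t_ms} ms ({what} outside "
            f"{w}x{h} scene)"
        )


def _render_frame(
    scene: Scene,
    M: np.ndarray,
    calibration: CalibrationBundle,
    vignetting: float,
) -> np.ndarray:
    """Render the 960x540 gray view under frame->scene homography ``M``."""
    if calibration.has_distortion:
        def inverse_map(coords):
            ideal = calibration.undistort_points(coords)
            return hg.apply(M, ideal)

        gray = warp(
            scene.albedo,
            inverse_map=inverse_map,
            output_shape=(FRAME_HEIGHT, FRAME_WIDTH),
            order=1,
            mode="edge",
        )
    else:
        gray = warp(
            scene.albedo,
            inverse_map=ProjectiveTransform(matrix=M),
            output_shape=(FRAME_HEIGHT, FRAME_WIDTH),
            order=1,
            mode="edge",
        )
    if vignetting > 0:
        ys, xs = np.mgrid[0:FRAME_HEIGHT, 0:FRAME_WIDTH]
        r2 = ((xs - calibration.cx) / (FRAME_WIDTH / 2)) ** 2 + (
            (ys - calibration.cy) / (FRAME_HEIGHT / 2)
        ) ** 2
        gray = gray * (1.0 - vignetting * np.clip(r2, 0, 1))
    return gray


def simulate_scan(
    scene: Scene,
    trajectory: Trajectory,
    rgb_fps: float = 10.0,
    hsi_fps: float = 70.0,
    delay_ms: float = 35.0,
    calibration: CalibrationBundle | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    vignetting: float = 0.0,
) -> ScanStreams:
    """Emulate one scan of ``scene`` along ``trajectory``.

    Returns the RGB frame stream (10 fps by default), the HSI line stream
    (70 fps by default, timestamps lagging by ``delay_ms``), and the ground
    truth geometry.  Gaussian pixel noise of ``noise_sd`` (on the [0, 1]
    intensity scale) is added to both streams, seeded.
    """
    if rgb_fps > hsi_fps:
        raise ConfigurationError("rgb_fps must not exceed hsi_fps")
    if calibration is None:
        calibration = CalibrationBundle(delta_ms=delay_ms)
    rng = np.random.default_rng(seed)
    n_frames = trajectory.n_frames
    frame_times = np.array([round(i * 1000.0 / rgb_fps) for i in range(n_frames)])
    interp = PoseInterpolator(frame_times, trajectory.poses)
    line_to_frame = calibration.line_to_frame

    # RGB frames
    frames: list[RawFrame] = []
    scene_to_frame: list[np.ndarray] = []
    fcorners = hg.corners(FRAME_WIDTH - 1, FRAME_HEIGHT - 1)
    for i, t in enumerate(frame_times):
        M = interp.matrix(t)
        _check_in_scene(hg.apply(M, fcorners), scene.shape, int(t), "frame corners")
        gray = _render_frame(scene, M, calibration, vignetting)
        if noise_sd > 0:
            gray = gray + rng.normal(0.0, noise_sd, size=gray.shape)
        img8 = np.clip(np.rint(gray * 255.0), 0, 255).astype(np.uint8)
        frames.append(
            RawFrame(image=np.repeat(img8[:, :, None], 3, axis=2),
                     timestamp_ms=int(t), index=i)
        )
        scene_to_frame.append(np.linalg.inv(M))

    # HSI lines: the stream covers the nominal scan duration n_frames / rgb_fps
    # (including the last frame interval); poses past the last frame time are
    # linearly extrapolated.  Lines in the final interval are emitted but can
    # only be stitched if another frame arrives, mirroring the live pipeline.
    duration_ms = round(n_frames * 1000.0 / rgb_fps)
    lines: list[RawLine] = []
    line_times: list[int] = []
    line_to_scene: list[np.ndarray] = []
    rows = np.arange(LINE_HEIGHT, dtype=float)
    slit_local = np.column_stack([np.zeros(LINE_HEIGHT), rows])
    j = 0
    while True:
        t_emit = round(j * 1000.0 / hsi_fps)
        if t_emit >= duration_ms:
            break
        t_true = t_emit + delay_ms
        M = interp.matrix(t_true)
        placement = M @ line_to_frame  # slit-local -> scene
        pts = hg.apply(placement, slit_local)
        _check_in_scene(pts, scene.shape, int(t_emit), "slit line")
        albedo = map_coordinates(
            scene.albedo, [pts[:, 1], pts[:, 0]], order=1, mode="nearest"
        )
        spectra = albedo[:, None] * SPECTRAL_PROFILE[None, :]
        if noise_sd > 0:
            spectra = spectra + rng.normal(0.0, noise_sd, size=spectra.shape)
        spectra = np.clip(spectra, 0.0, None)
        lines.append(RawLine(spectra=spectra, timestamp_ms=int(t_emit), index=j))
        line_times.append(int(t_emit))
        line_to_scene.append(placement)
        j += 1

    gt = ScanGroundTruth(
        frame_timestamps_ms=[int(t) for t in frame_times],
        scene_to_frame=scene_to_frame,
        line_timestamps_ms=line_times,
        line_to_scene=line_to_scene,
        delta_ms=delay_ms,
        mm_per_px=scene.mm_per_px,
        calibration=calibration,
        poses=trajectory.poses,
    )
    return ScanStreams(
        frames=frames, lines=lines, ground_truth=gt, calibration=calibration,
        scene=scene,
    )
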