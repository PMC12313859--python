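"""Stream preprocessing: undistortion, CLAHE contrast normalization, timestamps.

The acquisition front-end of the pipeline turns the two raw sensor streams
into the pair of asynchronous, timestamped streams every later stage consumes:

* RGB frames, 960 x 540 x 3, 8-bit, undistorted and contrast-enhanced with
  contrast-limited adaptive histogram equalization (CLAHE, clip limit 2.0,
  8 x 8 tile grid);
* hyperspectral lines, 1 x 540 x 100 reflectance samples (500-1000 nm in
  5 nm steps), passed through untouched.

No temporal synchronization happens here: the two streams stay independent
and are only re-aligned (via the inter-stream delay ``delta_ms``) inside the
line-stitching stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import map_coordinates
from skimage.exposure import equalize_adapthist

from . import homography as hg
from .exceptions import CalibrationError, ConfigurationError, IngestionError

FRAME_WIDTH = 960
FRAME_HEIGHT = 540
LINE_HEIGHT = 540
N_BANDS = 100
#: Band-center wavelengths in nm (500-1000 nm, 5 nm spacing).
WAVELENGTHS_NM = np.arange(N_BANDS) * 5.0 + 500.0


@dataclass
class CalibrationBundle:
    """Static calibration shared by simulator and pipeline.

    ``h_sens`` aligns the HSI sensor plane with the RGB sensor plane;
    ``h_pos`` moves the one-pixel-wide slit line from the left image edge to
    its physical position at the center column of the RGB frame.  ``delta_ms``
    is the empirical delay of the HSI stream timestamps relative to the RGB
    stream.  Radial distortion follows the usual polynomial model
    ``r' = r * (1 + k1 r^2 + k2 r^4 + k3 r^6)`` on normalized coordinates.
    """

    k1: float = 0.0
    k2: float = 0.0
    k3: float = 0.0
    fx: float = 700.0
    fy: float = 700.0
    cx: float = FRAME_WIDTH / 2.0
    cy: float = FRAME_HEIGHT / 2.0
    h_sens: np.ndarray = field(default_factory=lambda: np.eye(3))
    h_pos: np.ndarray = field(
        default_factory=lambda: hg.translation(FRAME_WIDTH / 2.0, 0.0)
    )
    delta_ms: float = 35.0

    def __post_init__(self) -> None:
        self.h_sens = np.asarray(self.h_sens, dtype=float)
        self.h_pos = np.asarray(self.h_pos, dtype=float)
        if self.delta_ms < 0:
            raise CalibrationError("inter-stream delay delta_ms must be >= 0")
        for name, H in (("h_sens", self.h_sens), ("h_pos", self.h_pos)):
            if H.shape != (3, 3) or not hg.is_invertible(H):
                raise CalibrationError(f"{name} must be an invertible 3x3 matrix")

    @property
    def has_distortion(self) -> bool:
        return any(k != 0.0 for k in (self.k1, self.k2, self.k3))

    @property
    def line_to_frame(self) -> np.ndarray:
        """Compose slit-local coordinates into RGB-frame coordinates."""
        return self.h_sens @ self.h_pos

    # -- distortion model ----------------------------------------------------

    def distort_points(self, points: np.ndarray) -> np.ndarray:
        """Map ideal (undistorted) pixel coords to distorted pixel coords."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        xn = (pts[:, 0] - self.cx) / self.fx
        yn = (pts[:, 1] - self.cy) / self.fy
        r2 = xn * xn + yn * yn
        factor = 1.0 + r2 * (self.k1 + r2 * (self.k2 + r2 * self.k3))
        return np.column_stack(
            [self.cx + xn * factor * self.fx, self.cy + yn * factor * self.fy]
        )

    def undistort_points(self, points: np.ndarray, iters: int = 20) -> np.ndarray:
        """Invert :meth:`distort_points` by fixed-point iteration."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        xd = (pts[:, 0] - self.cx) / self.fx
        yd = (pts[:, 1] - self.cy) / self.fy
        x, y = xd.copy(), yd.copy()
        for _ in range(iters):
            r2 = x * x + y * y
            factor = 1.0 + r2 * (self.k1 + r2 * (self.k2 + r2 * self.k3))
            if np.any(factor <= 0) or not np.all(np.isfinite(factor)):
                raise CalibrationError("distortion model is not invertible here")
            x, y = xd / factor, yd / factor
        return np.column_stack([self.cx + x * self.fx, self.cy + y * self.fy])

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "distortion": {"k1": self.k1, "k2": self.k2, "k3": self.k3},
            "intrinsics": {"fx": self.fx, "fy": self.fy, "cx": self.cx, "cy": self.cy},
            "h_sens": self.h_sens.tolist(),
            "h_pos": self.h_pos.tolist(),
            "delta_ms": self.delta_ms,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationBundle":
        dist = d.get("distortion", {})
        intr = d.get("intrinsics", {})
        return cls(
            k1=dist.get("k1", 0.0),
            k2=dist.get("k2", 0.0),
            k3=dist.get("k3", 0.0),
            fx=intr.get("fx", 700.0),
            fy=intr.get("fy", 700.0),
            cx=intr.get("cx", FRAME_WIDTH / 2.0),
            cy=intr.get("cy", FRAME_HEIGHT / 2.0),
            h_sens=np.array(d.get("h_sens", np.eye(3).tolist())),
            h_pos=np.array(
                d.get("h_pos", hg.translation(FRAME_WIDTH / 2.0, 0.0).tolist())
            ),
            delta_ms=d.get("delta_ms", 35.0),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "CalibrationBundle":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class TimedFrame:
    """One preprocessed RGB frame with its arrival timestamp in ms."""

    image: np.ndarray  # (540, 960, 3) uint8
    timestamp_ms: int
    index: int

    def __post_init__(self) -> None:
        if self.image.shape[:2] != (FRAME_HEIGHT, FRAME_WIDTH):
            raise IngestionError(
                f"frame {self.index}: expected {FRAME_HEIGHT}x{FRAME_WIDTH}, "
                f"got {self.image.shape[:2]}"
            )


@dataclass
class HSILine:
    """One raw spectral line (1 x 540 x 100) with its timestamp in ms."""

    spectra: np.ndarray  # (540, 100) float reflectance
    timestamp_ms: int
    index: int

    def __post_init__(self) -> None:
        if self.spectra.shape != (LINE_HEIGHT, N_BANDS):
            raise IngestionError(
                f"line {self.index}: expected ({LINE_HEIGHT}, {N_BANDS}), "
                f"got {self.spectra.shape}"
            )


def build_undistortion_map(
    calibration: CalibrationBundle,
    width: int = FRAME_WIDTH,
    height: int = FRAME_HEIGHT,
) -> np.ndarray:
    """Per-pixel source coordinates for undistortion, shape ``(2, H, W)``.

    Entry ``[:, y, x]`` holds the ``(row, col)`` position in the *distorted*
    image whose (bilinearly interpolated) value becomes undistorted pixel
    ``(x, y)``.  The map is computed once; applying it is a pure lookup.
    """
    ys, xs = np.mgrid[0:height, 0:width]
    pts = np.column_stack([xs.ravel().astype(float), ys.ravel().astype(float)])
    src = calibration.distort_points(pts)
    if not np.all(np.isfinite(src)):
        raise CalibrationError("undistortion map contains non-finite coordinates")
    return np.stack(
        [src[:, 1].reshape(height, width), src[:, 0].reshape(height, width)]
    )


def undistort(image: np.ndarray, umap: np.ndarray) -> np.ndarray:
    """Apply a precomputed undistortion map with bilinear resampling."""
    if image.ndim == 2:
        return map_coordinates(image.astype(float), umap, order=1, mode="nearest")
    channels = [
        map_coordinates(image[..., c].astype(float), umap, order=1, mode="nearest")
        for c in range(image.shape[2])
    ]
    out = np.stack(channels, axis=-1)
    if image.dtype == np.uint8:
        out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return out


def apply_clahe(
    frame: np.ndarray, clip_limit: float = 2.0, tile_grid: int = 8
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on 8-bit frames.

    Operates on the luminance channel; color channels are scaled
    proportionally.  ``clip_limit`` uses the conventional video-pipeline
    scale where 2.0 means each 256-bin tile histogram is clipped at twice
    the uniform bin height (internally mapped to the normalized clip
    fraction ``clip_limit / 256`` of skimage).
    """
    if clip_limit <= 0:
        raise ConfigurationError("CLAHE clip limit must be positive")
    if tile_grid <= 0:
        raise ConfigurationError("CLAHE tile grid must be positive")
    img = np.asarray(frame)
    gray = img if img.ndim == 2 else img @ np.array([0.299, 0.587, 0.114])
    h, w = gray.shape
    kernel = (max(1, h // tile_grid), max(1, w // tile_grid))
    lum = gray.astype(float) / 255.0
    if np.ptp(lum) < 1.0 / 255.0:
        # flat image: equalization is a no-op up to quantization
        return img.copy()
    eq = equalize_adapthist(lum, kernel_size=kernel, clip_limit=clip_limit / 256.0)
    if img.ndim == 2:
        return np.clip(np.rint(eq * 255.0), 0, 255).astype(np.uint8)
    gain = (eq * 255.0) / np.maximum(gray, 1e-6)
    out = np.clip(np.rint(img * gain[..., None]), 0, 255).astype(np.uint8)
    return out


def _check_monotone(stamps: list[int], what: str) -> None:
    for k in range(1, len(stamps)):
        if stamps[k] <= stamps[k - 1]:
            raise IngestionError(
                f"{what} timestamp not strictly increasing at record {k}: "
                f"{stamps[k]} after {stamps[k - 1]}"
            )


def ingest(
    source,
    clip_limit: float = 2.0,
    tile_grid: int = 8,
) -> tuple[list[TimedFrame], list[HSILine]]:
    """Turn a raw scan (directory or in-memory simulator output) into streams.

    Frames are re-ordered by timestamp, undistorted and CLAHE-equalized;
    lines are re-ordered and passed through untouched.  Duplicate timestamps
    raise :class:`IngestionError` naming the offending record.
    """
    from .io import load_scan  # local import to avoid a cycle

    if isinstance(source, (str, Path)):
        source = load_scan(source)

    calibration: CalibrationBundle = source.calibration
    umap = None
    if calibration.has_distortion:
        umap = build_undistortion_map(calibration)

    order = np.argsort([f.timestamp_ms for f in source.frames], kind="stable")
    frames_raw = [source.frames[k] for k in order]
    _check_monotone([f.timestamp_ms for f in frames_raw], "frame")

    frames = []
    for i, raw in enumerate(frames_raw):
        img = raw.image
        if umap is not None:
            img = undistort(img, umap)
        img = apply_clahe(img, clip_limit=clip_limit, tile_grid=tile_grid)
        frames.append(TimedFrame(image=img, timestamp_ms=raw.timestamp_ms, index=i))

    order = np.argsort([l.timestamp_ms for l in source.lines], kind="stable")
    lines_raw = [source.lines[k] for k in order]
    _check_monotone([l.timestamp_ms for l in lines_raw], "line")
    lines = [
        HSILine(spectra=raw.spectra, timestamp_ms=raw.timestamp_ms, index=j)
        for j, raw in enumerate(lines_raw)
    ]
    return frames, lines
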