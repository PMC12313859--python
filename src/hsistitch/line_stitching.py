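"""Compositing hyperspectral lines into the growing false-color panorama.

Each processed RGB frame triggers one stitching step: the buffered HSI lines
whose delay-corrected timestamps fall between the previous and the current
frame are selected, false-colored, given per-line homographies by linear
interpolation between the two frames' global homographies (conjugated into
slit-local coordinates by the sensor calibration), optionally widened so
consecutive lines tile without gaps, and projectively warped onto the canvas
with newest-wins overwrite semantics.  A pure-translation offset homography
keeps canvas coordinates non-negative as the panorama grows left/up, and a
forget function crops content far outside the display window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import homography as hg
from .exceptions import CalibrationError, ConfigurationError
from .preprocess import HSILine, LINE_HEIGHT, N_BANDS


@dataclass
class StitchConfig:
    delta_ms: float = 35.0
    adaptive_width: bool = True
    fixed_width: int = 3  # used when adaptive widening is disabled
    width_cap: int = 8
    false_color_mode: str = "gray"
    #: band indices mapped to (R, G, B) in "band_rgb" mode (620/550/500 nm)
    rgb_bands: tuple[int, int, int] = (24, 10, 0)
    forget_margin_px: int = 100
    sanity_diagonal_factor: float = 10.0


@dataclass
class LineSet:
    """The HSI lines assigned to one inter-frame interval, in time order."""

    lines: list[HSILine]
    t_prev: int
    t_cur: int

    def __len__(self) -> int:
        return len(self.lines)


def select_lines(
    buffer: list[HSILine], t_prev: float, t_cur: float, delta: float
) -> tuple[LineSet, list[HSILine]]:
    """Membership test ``t_prev <= t + delta < t_cur`` on the line buffer.

    Returns the selected :class:`LineSet` and the remaining buffer.  Lines
    older than the interval (``t + delta < t_prev``) are dropped: they belong
    to intervals that will never be stitched.  Selection is half-open, so
    over a run every line joins exactly one interval.
    """
    if t_prev >= t_cur:
        raise ValueError("t_prev must be strictly before t_cur")
    selected, remaining = [], []
    for line in buffer:
        t = line.timestamp_ms + delta
        if t_prev <= t < t_cur:
            selected.append(line)
        elif t >= t_cur:
            remaining.append(line)
        # else: stale, dropped
    return LineSet(lines=selected, t_prev=int(t_prev), t_cur=int(t_cur)), remaining


def false_color(
    line: HSILine | np.ndarray,
    mode: str = "gray",
    rgb_bands: tuple[int, int, int] = (24, 10, 0),
) -> np.ndarray:
    """Map a 100-band reflectance line to a 540 x 3 color line in [0, 1].

    ``gray`` uses the band-mean reflectance on all three channels (the exact
    inverse of the simulator's spectral synthesis); ``band_rgb`` maps three
    configured bands to R, G and B.  The mapping is pluggable: any callable
    ``(540, 100) -> (540, 3)`` may be passed to the stitcher instead.
    """
    spectra = line.spectra if isinstance(line, HSILine) else np.asarray(line)
    if spectra.shape != (LINE_HEIGHT, N_BANDS):
        raise ConfigurationError(f"expected ({LINE_HEIGHT}, {N_BANDS}) spectra")
    if mode == "gray":
        g = spectra.mean(axis=1)
        return np.clip(np.repeat(g[:, None], 3, axis=1), 0.0, 1.0)
    if mode == "band_rgb":
        return np.clip(spectra[:, list(rgb_bands)], 0.0, 1.0)
    raise ConfigurationError(f"unknown false-color mode {mode!r}")


def interpolate_homographies(
    H_prev: np.ndarray, H_cur: np.ndarray, n: int
) -> list[np.ndarray]:
    """Element-wise convex combination of two normalized homographies.

    Returns ``H_k = (1 - k/n) H_prev + (k/n) H_cur`` for ``k = 0 .. n-1``,
    renormalized.  ``H_0`` equals ``H_prev`` exactly; ``H_cur`` is never
    attained within the interval (it becomes ``H_0`` of the next one).
    """
    if n < 1:
        raise ValueError("need at least one line in the interval")
    A, B = hg.normalize(H_prev), hg.normalize(H_cur)
    out = []
    for k in range(n):
        w = k / n
        out.append(hg.normalize((1.0 - w) * A + w * B))
    return out


def adjust_for_line(
    H: np.ndarray, H_sens: np.ndarray, H_pos: np.ndarray
) -> np.ndarray:
    """Conjugate an RGB-frame homography into slit-local line coordinates.

    ``H' = H_pos^-1 H_sens^-1 H H_sens H_pos``: convert slit-local
    coordinates to the RGB frame, apply the frame mapping, convert back.
    """
    for name, M in (("H_sens", H_sens), ("H_pos", H_pos)):
        if not hg.is_invertible(M):
            raise CalibrationError(f"{name} is singular")
    return (
        np.linalg.inv(H_pos) @ np.linalg.inv(H_sens) @ H @ H_sens @ H_pos
    )


def frame_delta(H_prev_global: np.ndarray, H_cur_global: np.ndarray) -> np.ndarray:
    """Inter-frame motion in line coordinates: ``inv(H'_(i-1,P)) @ H'_(i,P)``."""
    if not hg.is_invertible(H_prev_global):
        raise CalibrationError("previous global homography is singular")
    return np.linalg.inv(H_prev_global) @ H_cur_global


def adaptive_width(
    delta_H: np.ndarray,
    line_height: int = LINE_HEIGHT,
    n_lines: int = 1,
    cap: int = 8,
) -> int:
    """Line width (px) that covers the horizontal motion of one interval.

    The four corners of a 1 x ``line_height`` line are mapped through the
    inter-frame motion ``delta_H``; the largest absolute horizontal corner
    translation, divided by the number of lines in the interval and rounded
    up, is the ideal width, capped at ``cap`` and floored at 1.
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    c = np.array(
        [[0.0, 0.0], [1.0, 0.0], [0.0, line_height], [1.0, line_height]]
    )
    warped = hg.apply(delta_H, c)
    T = float(np.max(np.abs(warped[:, 0] - c[:, 0])))
    return int(min(max(np.ceil(T / n_lines), 1), cap))


def motion_sign(delta_H: np.ndarray, line_height: int = LINE_HEIGHT) -> int:
    """Sign of the mean horizontal corner translation (+1 when moving +x)."""
    c = np.array(
        [[0.0, 0.0], [1.0, 0.0], [0.0, line_height], [1.0, line_height]]
    )
    mean_dx = float(np.mean(hg.apply(delta_H, c)[:, 0] - c[:, 0]))
    return 1 if mean_dx >= 0 else -1


@dataclass
class StitchedLineRecord:
    """Log entry for one stitched line (used by evaluation/visualization)."""

    line_index: int
    timestamp_ms: int
    width: int
    H_line: np.ndarray  # H'_(k,P): slit-local -> panorama (pre-offset)
    H_final: np.ndarray  # H^T_j @ H'_(k,P) at stitch time


@dataclass
class PanoramaState:
    """The growing false-color canvas and its coordinate bookkeeping.

    ``offset`` is the accumulated pure-translation homography H^T mapping
    pre-offset panorama coordinates (fixed at sequence start) to current
    canvas pixel coordinates; it changes only when the canvas grows to the
    left/top or is cropped by the forget function.
    """

    canvas: np.ndarray = field(
        default_factory=lambda: np.zeros((0, 0, 3), dtype=np.float32)
    )
    mask: np.ndarray = field(default_factory=lambda: np.zeros((0, 0), dtype=bool))
    offset: np.ndarray = field(default_factory=lambda: np.eye(3))
    latest_final_H: np.ndarray | None = None
    records: list[StitchedLineRecord] = field(default_factory=list)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def occupied_count(self) -> int:
        return int(self.mask.sum())


def update_offset(
    state: PanoramaState, warped_extent: tuple[float, float, float, float]
) -> tuple[PanoramaState, np.ndarray]:
    """Grow the canvas to contain ``warped_extent`` (xmin, ymin, xmax, ymax).

    Negative minima shift the origin: the offset homography gains an integer
    translation and the canvas is padded on the left/top; growth to the
    right/bottom pads without changing the offset.
    """
    xmin, ymin, xmax, ymax = warped_extent
    pad_left = int(np.ceil(-xmin)) if xmin < 0 else 0
    pad_top = int(np.ceil(-ymin)) if ymin < 0 else 0
    h, w = state.mask.shape
    need_w = int(np.ceil(xmax + pad_left)) + 1
    need_h = int(np.ceil(ymax + pad_top)) + 1
    new_w = max(w + pad_left, need_w)
    new_h = max(h + pad_top, need_h)
    if (pad_left, pad_top) != (0, 0) or (new_h, new_w) != (h, w):
        canvas = np.zeros((new_h, new_w, 3), dtype=np.float32)
        mask = np.zeros((new_h, new_w), dtype=bool)
        if h and w:
            canvas[pad_top : pad_top + h, pad_left : pad_left + w] = state.canvas
            mask[pad_top : pad_top + h, pad_left : pad_left + w] = state.mask
        state.canvas, state.mask = canvas, mask
        if pad_left or pad_top:
            state.offset = hg.translation(pad_left, pad_top) @ state.offset
    return state, state.offset


def _composite_one(
    state: PanoramaState,
    color: np.ndarray,  # (540, 3)
    H_line: np.ndarray,  # slit-local -> panorama (pre-offset)
    width: int,
    sign: int,
    sanity_limit: float,
) -> np.ndarray | None:
    """Warp one widened line onto the canvas; returns its final transform.

    The line is duplicated ``width`` times along x; the duplicated columns
    trail the motion (local x in ``[-(width-1), 0]`` for +x motion) so the
    leading edge stays at its true position.  Nearest-neighbor sampling
    preserves the piecewise-constant line model and newest-wins overwrite.
    """
    if sign >= 0:
        x0, x1 = -(width - 1), 0
    else:
        x0, x1 = 0, width - 1
    local_corners = np.array(
        [
            [x0 - 0.5, -0.5],
            [x1 + 0.5, -0.5],
            [x0 - 0.5, LINE_HEIGHT - 0.5],
            [x1 + 0.5, LINE_HEIGHT - 0.5],
        ]
    )
    pre = hg.apply(state.offset @ H_line, local_corners)
    if not np.all(np.isfinite(pre)) or np.max(np.abs(pre)) > sanity_limit:
        return None
    extent = (pre[:, 0].min(), pre[:, 1].min(), pre[:, 0].max(), pre[:, 1].max())
    state, _ = update_offset(state, extent)
    H_final = state.offset @ H_line
    warped = hg.apply(H_final, local_corners)

    cx0 = int(np.floor(warped[:, 0].min()))
    cx1 = int(np.ceil(warped[:, 0].max()))
    cy0 = int(np.floor(warped[:, 1].min()))
    cy1 = int(np.ceil(warped[:, 1].max()))
    ch, cw = state.mask.shape
    cx0, cx1 = max(cx0, 0), min(cx1, cw - 1)
    cy0, cy1 = max(cy0, 0), min(cy1, ch - 1)
    if cx1 < cx0 or cy1 < cy0:
        return H_final
    ys, xs = np.mgrid[cy0 : cy1 + 1, cx0 : cx1 + 1]
    pts = np.column_stack([xs.ravel().astype(float), ys.ravel().astype(float)])
    inv = np.linalg.inv(H_final)
    local = hg.apply(inv, pts)
    lx, ly = local[:, 0], local[:, 1]
    inside = (
        (lx >= x0 - 0.5)
        & (lx < x1 + 0.5)
        & (ly >= -0.5)
        & (ly < LINE_HEIGHT - 0.5)
    )
    if not np.any(inside):
        return H_final
    rows = np.clip(np.rint(ly[inside]).astype(int), 0, LINE_HEIGHT - 1)
    cy = ys.ravel()[inside]
    cx = xs.ravel()[inside]
    state.canvas[cy, cx] = color[rows]
    state.mask[cy, cx] = True
    return H_final


def warp_and_composite(
    line_set: LineSet,
    colors: list[np.ndarray],
    per_line_H: list[np.ndarray],
    state: PanoramaState,
    width: int = 1,
    sign: int = 1,
    config: StitchConfig | None = None,
    display_diagonal: float = 1101.0,
) -> PanoramaState:
    """Composite the interval's widened lines onto the canvas, newest wins.

    ``per_line_H`` holds the conjugated per-line homographies H'_(k,P); the
    final transform of each line composes the current offset homography on
    top.  A line whose warped footprint exceeds ``sanity_diagonal_factor``
    display diagonals from the origin is skipped with a warning record.
    """
    cfg = config or StitchConfig()
    sanity = cfg.sanity_diagonal_factor * display_diagonal
    for line, color, H_line in zip(line_set.lines, colors, per_line_H):
        H_final = _composite_one(state, color, H_line, width, sign, sanity)
        if H_final is None:
            import warnings

            warnings.warn(
                f"line {line.index} mapped outside sanity bound; skipped",
                stacklevel=2,
            )
            continue
        state.latest_final_H = H_final
        state.records.append(
            StitchedLineRecord(
                line_index=line.index,
                timestamp_ms=line.timestamp_ms,
                width=width,
                H_line=H_line.copy(),
                H_final=H_final.copy(),
            )
        )
    return state


def crop_forget(
    state: PanoramaState,
    display_window: tuple[float, float, float, float],
    margin: int = 100,
) -> PanoramaState:
    """Crop canvas content farther than ``margin`` beyond the display window.

    ``display_window`` is (xmin, ymin, xmax, ymax) in canvas coordinates.
    The offset homography absorbs the removed left/top strip so retained
    content keeps its global placement; pixels within window + margin are
    untouched.
    """
    xmin, ymin, xmax, ymax = display_window
    h, w = state.mask.shape
    if h == 0 or w == 0:
        return state
    keep_x0 = max(int(np.floor(xmin - margin)), 0)
    keep_y0 = max(int(np.floor(ymin - margin)), 0)
    keep_x1 = min(int(np.ceil(xmax + margin)), w - 1)
    keep_y1 = min(int(np.ceil(ymax + margin)), h - 1)
    if keep_x1 < keep_x0 or keep_y1 < keep_y0:
        state.canvas = np.zeros((0, 0, 3), dtype=np.float32)
        state.mask = np.zeros((0, 0), dtype=bool)
        return state
    if (keep_x0, keep_y0) == (0, 0) and (keep_x1, keep_y1) == (w - 1, h - 1):
        return state
    state.canvas = state.canvas[keep_y0 : keep_y1 + 1, keep_x0 : keep_x1 + 1].copy()
    state.mask = state.mask[keep_y0 : keep_y1 + 1, keep_x0 : keep_x1 + 1].copy()
    if keep_x0 or keep_y0:
        state.offset = hg.translation(-keep_x0, -keep_y0) @ state.offset
        if state.latest_final_H is not None:
            state.latest_final_H = (
                hg.translation(-keep_x0, -keep_y0) @ state.latest_final_H
            )
    return state
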