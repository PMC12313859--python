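"""Overlay rendering: the panorama as an augmentation of the RGB view.

The stitched false-color panorama lives in its own canvas coordinate
system.  For display it is warped back into the current camera view with
the inverse of the latest stitching transform, cropped to the 960 x 540
monitor view and alpha-blended onto the RGB frame wherever stitched data
exists.  Pixels without panorama occupancy always show the RGB frame
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import ProjectiveTransform, warp

from . import homography as hg
from .exceptions import ConfigurationError
from .line_stitching import PanoramaState
from .preprocess import FRAME_HEIGHT, FRAME_WIDTH, TimedFrame

DISPLAY_MODES = ("rgb", "static_hsi", "freehand_hsi")


@dataclass
class OverlayFrame:
    image: np.ndarray  # (540, 960, 3) uint8
    alpha: float
    frame_index: int


def render_overlay(
    frame: TimedFrame,
    state: PanoramaState,
    view_transform: np.ndarray | None,
    alpha: float = 0.5,
) -> OverlayFrame:
    """Blend the panorama into the current camera view.

    ``view_transform`` maps frame coordinates to canvas coordinates (the
    inverse of the transform the panorama would need to reach the view); a
    singular or missing transform passes the RGB frame through.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ConfigurationError("alpha must be within [0, 1]")
    out = frame.image.copy()
    if (
        view_transform is None
        or state.mask.size == 0
        or not hg.is_invertible(view_transform)
    ):
        return OverlayFrame(image=out, alpha=alpha, frame_index=frame.index)
    tf = ProjectiveTransform(matrix=np.asarray(view_transform, dtype=float))
    pano = np.stack(
        [
            warp(
                state.canvas[..., c],
                inverse_map=tf,
                output_shape=(FRAME_HEIGHT, FRAME_WIDTH),
                order=0,
                mode="constant",
                cval=0.0,
            )
            for c in range(3)
        ],
        axis=-1,
    )
    occ = (
        warp(
            state.mask.astype(float),
            inverse_map=tf,
            output_shape=(FRAME_HEIGHT, FRAME_WIDTH),
            order=0,
            mode="constant",
            cval=0.0,
        )
        > 0.5
    )
    blended = alpha * pano * 255.0 + (1.0 - alpha) * out.astype(float)
    out[occ] = np.clip(np.rint(blended[occ]), 0, 255).astype(np.uint8)
    return OverlayFrame(image=out, alpha=alpha, frame_index=frame.index)


def select_mode(mode: str):
    """Return a renderer callable for one of the display modes.

    * ``rgb``: byte-identical frame pass-through;
    * ``static_hsi``: renders a supplied false-color snapshot unwarped;
    * ``freehand_hsi``: the stitching overlay (:func:`render_overlay`).
    """
    if mode == "rgb":
        def render(frame: TimedFrame, **_) -> OverlayFrame:
            return OverlayFrame(image=frame.image, alpha=0.0, frame_index=frame.index)

        return render
    if mode == "static_hsi":
        def render(frame: TimedFrame, snapshot: np.ndarray = None, **_) -> OverlayFrame:
            if snapshot is None:
                raise ConfigurationError("static_hsi mode requires a snapshot")
            img = np.clip(np.rint(np.asarray(snapshot, float) * 255.0), 0, 255)
            return OverlayFrame(
                image=img.astype(np.uint8), alpha=1.0, frame_index=frame.index
            )

        return render
    if mode == "freehand_hsi":
        return render_overlay
    raise ConfigurationError(
        f"unknown display mode {mode!r}; expected one of {DISPLAY_MODES}"
    )
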