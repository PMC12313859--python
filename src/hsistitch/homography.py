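"""Small helpers for 3x3 planar projective transforms.

Conventions used throughout the package: points are ``(x, y)`` with the
origin in the upper-left corner of the image, ``x`` pointing right along
columns and ``y`` down along rows.  A homography ``H`` acts on homogeneous
column vectors ``[x, y, 1]^T`` and is kept normalized so that ``H[2, 2] == 1``
wherever that entry is nonzero.
"""

from __future__ import annotations

import numpy as np

IDENTITY = np.eye(3)


def normalize(H: np.ndarray) -> np.ndarray:
    """Scale ``H`` so its bottom-right element is 1."""
    H = np.asarray(H, dtype=float)
    if H.shape != (3, 3):
        raise ValueError(f"homography must be 3x3, got {H.shape}")
    w = H[2, 2]
    if w == 0 or not np.isfinite(w):
        raise ValueError("homography cannot be normalized: H[2,2] is zero/non-finite")
    return H / w


def translation(tx: float, ty: float) -> np.ndarray:
    H = np.eye(3)
    H[0, 2] = tx
    H[1, 2] = ty
    return H


def is_translation(H: np.ndarray, atol: float = 1e-9) -> bool:
    return np.allclose(H, translation(H[0, 2], H[1, 2]), atol=atol)


def apply(H: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Map an ``(N, 2)`` array of (x, y) points through ``H``."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    ones = np.ones((pts.shape[0], 1))
    hom = np.hstack([pts, ones]) @ np.asarray(H, dtype=float).T
    w = hom[:, 2:3]
    if np.any(np.abs(w) < 1e-15):
        raise ValueError("point mapped to infinity (w ~ 0)")
    return hom[:, :2] / w


def corners(width: float, height: float) -> np.ndarray:
    """The four corners of a ``width x height`` region, origin upper-left."""
    return np.array(
        [[0.0, 0.0], [width, 0.0], [0.0, height], [width, height]], dtype=float
    )


def max_corner_displacement(H: np.ndarray, width: float, height: float) -> float:
    c = corners(width, height)
    return float(np.max(np.linalg.norm(apply(H, c) - c, axis=1)))


def is_invertible(H: np.ndarray, cond_limit: float = 1e12) -> bool:
    H = np.asarray(H, dtype=float)
    return bool(np.all(np.isfinite(H)) and np.linalg.cond(H) < cond_limit)
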