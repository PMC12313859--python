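"""Local keypoint picking: ORB features, ratio-test matching, gated RANSAC.

Every incoming RGB frame is reduced to its most salient binary-descriptor
keypoints.  Matching them against a reference set (the previous processed
frame, or the panorama database) yields point correspondences from which a
planar homography is estimated with RANSAC.  The estimate then passes a set
of plausibility gates — enough inliers, neither too little nor too much
motion, no degenerate frame distortion — before the frame is allowed to
drive stitching.  Twenty consecutive implausible frames reset the panorama.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.feature import ORB
from skimage.measure import ransac
from skimage.transform import ProjectiveTransform

from . import homography as hg
from .exceptions import EstimationError
from .preprocess import FRAME_HEIGHT, FRAME_WIDTH, TimedFrame



@dataclass
class KeypointSet:
    """Keypoints of one frame: (x, y) coords, 256-bit descriptors, responses.

    Coordinates use the image convention with origin at the upper-left
    corner.  Entries are ordered by decreasing detector response.
    """

    coords: np.ndarray  # (N, 2) float, (x, y)
    descriptors: np.ndarray  # (N, 256) bool
    responses: np.ndarray  # (N,) float

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def packed(self) -> np.ndarray:
        """Descriptors packed to four uint64 words for fast Hamming distances."""
        return (
            np.packbits(self.descriptors.astype(np.uint8), axis=1)
            .view(np.uint64)
            .reshape(len(self), 4)
        )


@dataclass
class MatchList:
    """Surviving descriptor matches between a current and a reference set."""

    current_idx: np.ndarray  # (M,) int indices into the current set
    reference_idx: np.ndarray  # (M,) int indices into the reference set
    distance: np.ndarray  # (M,) int Hamming distances

    def __len__(self) -> int:
        return self.current_idx.shape[0]

    @classmethod
    def empty(cls) -> "MatchList":
        z = np.zeros(0, dtype=int)
        return cls(z, z.copy(), z.copy())


@dataclass
class GateConfig:
    """Plausibility thresholds for homography gating (all config-exposed)."""

    min_inliers: int = 40
    min_motion_px: float = 2.0
    max_motion_frac: float = 0.25  # of frame width
    area_ratio_bounds: tuple[float, float] = (0.5, 2.0)
    max_invalid: int = 20


@dataclass
class GateVerdict:
    outcome: str  # ok | no_motion | low_inliers | excessive_motion | distorted

    @property
    def ok(self) -> bool:
        return self.outcome == "ok"

    @property
    def counts_as_invalid(self) -> bool:
        # low motion wastes resources but is not a registration failure
        return self.outcome not in ("ok", "no_motion")


def extract_keypoints(
    frame: TimedFrame | np.ndarray,
    max_keypoints: int = 1000,
    n_scales: int = 2,
) -> KeypointSet:
    """Detect up to ``max_keypoints`` ORB keypoints, strongest first.

    Deterministic for a given frame.  A uniform frame yields an empty set.
    """
    img = frame.image if isinstance(frame, TimedFrame) else frame
    if img.ndim == 3:
        img = img @ np.array([0.299, 0.587, 0.114])
    gray = img.astype(float)
    if gray.max() > 1.0:
        gray = gray / 255.0
    if np.ptp(gray) < 1e-6:
        return KeypointSet(
            coords=np.zeros((0, 2)),
            descriptors=np.zeros((0, 256), dtype=bool),
            responses=np.zeros(0),
        )
    orb = ORB(n_keypoints=max_keypoints, n_scales=n_scales, fast_threshold=0.05)
    try:
        orb.detect_and_extract(gray)
    except RuntimeError:  # skimage raises when no interest points are found
        return KeypointSet(
            coords=np.zeros((0, 2)),
            descriptors=np.zeros((0, 256), dtype=bool),
            responses=np.zeros(0),
        )
    coords = orb.keypoints[:, ::-1].astype(float)  # (row, col) -> (x, y)
    responses = orb.responses
    order = np.argsort(-responses, kind="stable")
    return KeypointSet(
        coords=coords[order],
        descriptors=orb.descriptors[order],
        responses=responses[order],
    )


def hamming_matrix(a: KeypointSet, b: KeypointSet) -> np.ndarray:
    """All-pairs Hamming distances between two descriptor sets, (|a|, |b|)."""
    xor = a.packed[:, None, :] ^ b.packed[None, :, :]
    return np.bitwise_count(xor).sum(axis=2, dtype=np.int64)


def match_descriptors(
    current: KeypointSet, reference: KeypointSet, ratio: float = 0.8
) -> MatchList:
    """Brute-force Hamming matching with Lowe's ratio test.

    A current keypoint keeps its nearest reference neighbor only when the
    best distance is strictly below ``ratio`` times the second-best (with a
    single-entry reference the test is skipped and the match kept).  When
    several current keypoints claim the same reference keypoint, only the
    lowest-distance pair survives.
    """
    if len(current) == 0 or len(reference) == 0:
        return MatchList.empty()
    dist = hamming_matrix(current, reference)
    best_ref = np.argmin(dist, axis=1)
    best = dist[np.arange(len(current)), best_ref]
    if len(reference) >= 2:
        masked = dist.copy()
        masked[np.arange(len(current)), best_ref] = np.iinfo(np.int64).max
        second = masked.min(axis=1)
        keep = best < ratio * second
    else:
        keep = np.ones(len(current), dtype=bool)
    cur_idx = np.flatnonzero(keep)
    ref_idx = best_ref[cur_idx]
    d = best[cur_idx]
    # resolve duplicate reference claims: keep the lowest-distance pair
    order = np.lexsort((d, ref_idx))
    cur_idx, ref_idx, d = cur_idx[order], ref_idx[order], d[order]
    first = np.ones(len(ref_idx), dtype=bool)
    first[1:] = ref_idx[1:] != ref_idx[:-1]
    return MatchList(
        current_idx=cur_idx[first], reference_idx=ref_idx[first], distance=d[first]
    )


def estimate_homography(
    matches: MatchList,
    current: KeypointSet,
    reference: KeypointSet,
    confidence: float = 0.995,
    reproj_threshold: float = 8.0,
    seed: int = 0,
    max_trials: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """RANSAC estimate of the homography mapping current -> reference coords.

    Returns ``(H, inlier_mask)``; inliers have reprojection error at most
    ``reproj_threshold`` pixels in the reference frame.  Raises
    :class:`EstimationError` on fewer than four matches or degenerate
    geometry, which the caller gates as ``low_inliers``.
    """
    if len(matches) < 4:
        raise EstimationError(f"need >= 4 matches, got {len(matches)}")
    src = current.coords[matches.current_idx]
    dst = reference.coords[matches.reference_idx]
    try:
        model, inliers = ransac(
            (src, dst),
            ProjectiveTransform,
            min_samples=4,
            residual_threshold=reproj_threshold,
            stop_probability=confidence,
            max_trials=max_trials,
            rng=seed,
        )
    except ValueError as exc:  # e.g. all samples degenerate
        raise EstimationError(str(exc)) from exc
    if model is None or inliers is None or not np.any(inliers):
        raise EstimationError("RANSAC found no consensus set")
    H = model.params
    if not np.all(np.isfinite(H)) or abs(H[2, 2]) < 1e-12:
        raise EstimationError("degenerate homography estimate")
    return hg.normalize(H), inliers


def _quad_convex_and_oriented(quad: np.ndarray) -> bool:
    """True when the corner quadrilateral is convex and not mirror-flipped.

    ``quad`` holds the warped corners in the order UL, UR, LL, LR; the test
    walks them as a polygon and requires all cross products to share the
    original (positive) orientation.
    """
    poly = quad[[0, 1, 3, 2]]  # UL, UR, LR, LL: polygon order
    crosses = []
    for k in range(4):
        a = poly[(k + 1) % 4] - poly[k]
        b = poly[(k + 2) % 4] - poly[(k + 1) % 4]
        crosses.append(a[0] * b[1] - a[1] * b[0])
    return all(c > 0 for c in crosses)


def gate_frame(
    H: np.ndarray | None,
    inlier_count: int,
    frame_size: tuple[int, int] = (FRAME_WIDTH, FRAME_HEIGHT),
    config: GateConfig | None = None,
) -> GateVerdict:
    """Plausibility checks for an estimated homography.

    Outcomes, checked in order: ``no_motion`` (max corner displacement below
    ``min_motion_px``; the frame is skipped but not counted invalid),
    ``low_inliers``, ``excessive_motion`` (displacement beyond
    ``max_motion_frac`` of the frame width), ``distorted`` (non-convex or
    mirror-flipped corner quadrilateral, or area ratio outside bounds),
    else ``ok``.  ``H is None`` (estimation failure) gates as low_inliers.
    """
    cfg = config or GateConfig()
    if H is None:
        return GateVerdict("low_inliers")
    w, h = frame_size
    c = hg.corners(w, h)
    try:
        warped = hg.apply(H, c)
    except ValueError:
        return GateVerdict("distorted")
    disp = float(np.max(np.linalg.norm(warped - c, axis=1)))
    if disp < cfg.min_motion_px:
        return GateVerdict("no_motion")
    if inlier_count < cfg.min_inliers:
        return GateVerdict("low_inliers")
    # distortion is checked before excessive motion: a mirrored or folded
    # frame also displaces its corners a lot, but the defect is the shape
    lo, hi = cfg.area_ratio_bounds
    if not _quad_convex_and_oriented(warped):
        return GateVerdict("distorted")
    if not (lo <= _quad_area(warped) / (w * h) <= hi):
        return GateVerdict("distorted")
    if disp > cfg.max_motion_frac * w:
        return GateVerdict("excessive_motion")
    return GateVerdict("ok")


def _quad_area(quad: np.ndarray) -> float:
    poly = quad[[0, 1, 3, 2]]
    x, y = poly[:, 0], poly[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


@dataclass
class ResetCounter:
    """Counts consecutive invalid frames; fires a reset at ``max_invalid``."""

    max_invalid: int = 20
    count: int = 0
    resets_fired: int = field(default=0)

    def update(self, verdict: GateVerdict) -> bool:
        """Record a verdict; returns True when a reset fires."""
        if verdict.ok:
            self.count = 0
            return False
        if not verdict.counts_as_invalid:
            return False
        self.count += 1
        if self.count >= self.max_invalid:
            self.count = 0
            self.resets_fired += 1
            return True
        return False
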