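"""Frame-to-panorama registration via a bounded keypoint database.

Registering each frame only against its predecessor accumulates drift.  The
pipeline therefore keeps a database of the strongest keypoints seen since
sequence start, stored in the global panorama coordinate system (fixed by
the upper-left corner of the first frame), and registers every new frame
directly against it.  The database is bounded: per processed frame at most
500 matches feed the homography, at most 50 new keypoints are added, at most
200 inlier entries are refreshed, and entries unmatched for more than 80
processed frames are evicted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import homography as hg
from .exceptions import EstimationError
from .picking import (
    GateConfig,
    GateVerdict,
    KeypointSet,
    MatchList,
    estimate_homography,
    gate_frame,
    match_descriptors,
)


@dataclass
class RegistrationConfig:
    max_matches: int = 500
    max_new: int = 50
    max_updates: int = 200
    max_age: int = 80


class KeypointDatabase:
    """Bounded store of panorama-frame keypoints with unmatched-age counters."""

    def __init__(self) -> None:
        self.coords = np.zeros((0, 2), dtype=float)  # panorama (x, y)
        self.descriptors = np.zeros((0, 256), dtype=bool)
        self.responses = np.zeros(0, dtype=float)
        self.ages = np.zeros(0, dtype=int)
        self.started = False

    def __len__(self) -> int:
        return self.coords.shape[0]

    def as_keypoint_set(self) -> KeypointSet:
        return KeypointSet(
            coords=self.coords, descriptors=self.descriptors, responses=self.responses
        )

    def bootstrap(self, kps: KeypointSet) -> None:
        """Seed the database from the first frame of a sequence (H = I)."""
        self.coords = kps.coords.copy()
        self.descriptors = kps.descriptors.copy()
        self.responses = kps.responses.copy()
        self.ages = np.zeros(len(kps), dtype=int)
        self.started = True

    def clear(self) -> None:
        self.__init__()

    # -- serialization for inspection ---------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "coords": self.coords.tolist(),
                "descriptors": np.packbits(
                    self.descriptors.astype(np.uint8), axis=1
                ).tolist() if len(self) else [],
                "responses": self.responses.tolist(),
                "ages": self.ages.tolist(),
                "started": self.started,
            }
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, payload: str | Path) -> "KeypointDatabase":
        if isinstance(payload, Path) or (
            isinstance(payload, str) and not payload.lstrip().startswith("{")
        ):
            payload = Path(payload).read_text()
        d = json.loads(payload)
        db = cls()
        n = len(d["coords"])
        db.coords = np.array(d["coords"], dtype=float).reshape(n, 2)
        packed = np.array(d["descriptors"], dtype=np.uint8).reshape(n, 32)
        db.descriptors = np.unpackbits(packed, axis=1).astype(bool)
        db.responses = np.array(d["responses"], dtype=float)
        db.ages = np.array(d["ages"], dtype=int)
        db.started = d["started"]
        return db


def global_match(
    current: KeypointSet,
    db: KeypointDatabase,
    max_matches: int = 500,
    ratio: float = 0.8,
) -> MatchList:
    """Match frame keypoints against the database, keep the best by distance.

    Only the ``max_matches`` lowest-Hamming-distance matches are forwarded to
    homography estimation.  An empty database on a non-first frame signals
    that a reset is required.
    """
    if not db.started or len(db) == 0:
        raise EstimationError("empty keypoint database: reset required")
    matches = match_descriptors(current, db.as_keypoint_set(), ratio=ratio)
    if len(matches) > max_matches:
        order = np.argsort(matches.distance, kind="stable")[:max_matches]
        order = np.sort(order)
        matches = MatchList(
            current_idx=matches.current_idx[order],
            reference_idx=matches.reference_idx[order],
            distance=matches.distance[order],
        )
    return matches


def estimate_global(
    matches: MatchList,
    current: KeypointSet,
    db: KeypointDatabase,
    h_prev_global: np.ndarray,
    gate_config: GateConfig | None = None,
    confidence: float = 0.995,
    reproj_threshold: float = 8.0,
    seed: int = 0,
) -> tuple[np.ndarray | None, np.ndarray | None, GateVerdict]:
    """Estimate the frame-to-panorama homography and gate its plausibility.

    The same RANSAC estimator and gates as local picking are used, but the
    motion/distortion checks run on the *relative* transform
    ``inv(H_(i-1,P)) @ H_(i,P)``: corner displacement of the cumulative
    panorama homography would measure distance since sequence start, not
    motion of this frame.
    """
    try:
        H, inliers = estimate_homography(
            matches,
            current,
            db.as_keypoint_set(),
            confidence=confidence,
            reproj_threshold=reproj_threshold,
            seed=seed,
        )
    except EstimationError:
        return None, None, GateVerdict("low_inliers")
    relative = np.linalg.inv(hg.normalize(h_prev_global)) @ H
    verdict = gate_frame(
        hg.normalize(relative), int(np.sum(inliers)), config=gate_config
    )
    return H, inliers, verdict


def maintain(
    db: KeypointDatabase,
    current: KeypointSet,
    matches: MatchList,
    inliers: np.ndarray | None,
    H: np.ndarray | None,
    verdict: GateVerdict,
    config: RegistrationConfig | None = None,
) -> KeypointDatabase:
    """Database maintenance after a frame (mutates and returns ``db``).

    For a plausible frame: unmatched current keypoints are added (the 50
    strongest, warped into panorama coordinates by ``H``); inlier matches are
    refreshed (the 200 lowest-distance get current coordinates/descriptors,
    all inliers get age zero); outlier matches are deleted; everything else
    ages by one and entries older than ``max_age`` are evicted.

    For an implausible frame only the deletion rule applies: every database
    entry matched into the implausible homography is discarded; no additions,
    updates or aging.
    """
    cfg = config or RegistrationConfig()
    delete = np.zeros(len(db), dtype=bool)

    if not verdict.ok:
        if len(matches):
            delete[matches.reference_idx] = True
        _apply_delete(db, delete)
        return db

    if H is None:
        raise ValueError("plausible frame requires a homography")
    inliers = np.asarray(inliers, dtype=bool)
    touched = np.zeros(len(db), dtype=bool)
    if len(matches):
        touched[matches.reference_idx] = True

    # (b) inlier matches: refresh the best max_updates, zero all inlier ages
    in_ref = matches.reference_idx[inliers]
    in_cur = matches.current_idx[inliers]
    in_dist = matches.distance[inliers]
    order = np.argsort(in_dist, kind="stable")
    refresh = order[: cfg.max_updates]
    warped = hg.apply(H, current.coords[in_cur[refresh]]) if len(refresh) else None
    if warped is not None:
        db.coords[in_ref[refresh]] = warped
        db.descriptors[in_ref[refresh]] = current.descriptors[in_cur[refresh]]
        db.responses[in_ref[refresh]] = current.responses[in_cur[refresh]]
    db.ages[in_ref] = 0

    # (c) matched-but-outlier entries are discarded
    delete[matches.reference_idx[~inliers]] = True

    # (d) unmatched entries age; stale entries are evicted
    db.ages[~touched] += 1
    delete |= db.ages > cfg.max_age

    # (a) the strongest unmatched current keypoints are added
    matched_cur = np.zeros(len(current), dtype=bool)
    if len(matches):
        matched_cur[matches.current_idx] = True
    new_idx = np.flatnonzero(~matched_cur)
    if len(new_idx):
        order = np.argsort(-current.responses[new_idx], kind="stable")
        new_idx = new_idx[order[: cfg.max_new]]
        new_coords = hg.apply(H, current.coords[new_idx])
        _apply_delete(db, delete)
        db.coords = np.vstack([db.coords, new_coords])
        db.descriptors = np.vstack([db.descriptors, current.descriptors[new_idx]])
        db.responses = np.concatenate([db.responses, current.responses[new_idx]])
        db.ages = np.concatenate([db.ages, np.zeros(len(new_idx), dtype=int)])
    else:
        _apply_delete(db, delete)
    return db


def _apply_delete(db: KeypointDatabase, delete: np.ndarray) -> None:
    if not np.any(delete):
        return
    keep = ~delete
    db.coords = db.coords[keep]
    db.descriptors = db.descriptors[keep]
    db.responses = db.responses[keep]
    db.ages = db.ages[keep]
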