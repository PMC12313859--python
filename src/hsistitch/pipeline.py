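"""End-to-end incremental stitching: streams in, panorama out.

The :class:`FreehandStitcher` consumes the two preprocessed streams in
arrival order.  HSI lines are buffered; each RGB frame runs local picking
(frame-to-reference homography + plausibility gates), global registration
against the keypoint database, and — when plausible — triggers stitching of
the lines captured since the previous processed frame.  Twenty consecutive
invalid frames reset the panorama and start a new sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import homography as hg
from .exceptions import EstimationError
from .global_registration import (
    KeypointDatabase,
    RegistrationConfig,
    estimate_global,
    global_match,
    maintain,
)
from .line_stitching import (
    PanoramaState,
    StitchConfig,
    adaptive_width,
    adjust_for_line,
    crop_forget,
    false_color,
    frame_delta,
    interpolate_homographies,
    motion_sign,
    select_lines,
    warp_and_composite,
)
from .picking import (
    GateConfig,
    GateVerdict,
    KeypointSet,
    ResetCounter,
    estimate_homography,
    extract_keypoints,
    gate_frame,
    match_descriptors,
)
from .preprocess import CalibrationBundle, FRAME_HEIGHT, FRAME_WIDTH, HSILine, TimedFrame


@dataclass
class PickingConfig:
    max_keypoints: int = 1000
    n_scales: int = 2
    lowe_ratio: float = 0.8
    ransac_confidence: float = 0.995
    ransac_threshold_px: float = 8.0
    min_inliers: int = 40
    min_motion_px: float = 2.0
    max_motion_frac: float = 0.25
    max_invalid: int = 20

    def gate(self) -> GateConfig:
        return GateConfig(
            min_inliers=self.min_inliers,
            min_motion_px=self.min_motion_px,
            max_motion_frac=self.max_motion_frac,
            max_invalid=self.max_invalid,
        )


@dataclass
class PipelineConfig:
    picking: PickingConfig = field(default_factory=PickingConfig)
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    stitching: StitchConfig = field(default_factory=StitchConfig)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for section, target in (
            ("picking", cfg.picking),
            ("registration", cfg.registration),
            ("stitching", cfg.stitching),
        ):
            for key, value in (d.get(section) or {}).items():
                if not hasattr(target, key):
                    raise KeyError(f"unknown config key {section}.{key}")
                setattr(target, key, value)
        cfg.seed = d.get("seed", 0)
        return cfg


@dataclass
class FrameRecord:
    """Per-frame processing log entry."""

    index: int
    timestamp_ms: int
    verdict_local: str
    verdict_global: str | None = None
    n_inliers_local: int = 0
    n_inliers_global: int = 0
    H_local: np.ndarray | None = None
    H_global: np.ndarray | None = None
    reset_fired: bool = False
    stitched_lines: int = 0
    line_width: int = 0


@dataclass
class StitchResult:
    state: PanoramaState
    frame_records: list[FrameRecord]
    database: KeypointDatabase
    resets: int
    config: PipelineConfig
    calibration: CalibrationBundle
    view_transform: np.ndarray | None  # frame -> canvas for the latest ok frame


class FreehandStitcher:
    """Incremental dual-stream stitcher (library entry point).

    Typical use::

        stitcher = FreehandStitcher(calibration)
        for frame in frames:          # lines fed as they arrive
            stitcher.process_line(...)
            stitcher.process_frame(frame)
        result = stitcher.result()

    or simply ``stitcher.run(frames, lines)``.
    """

    def __init__(
        self,
        calibration: CalibrationBundle | None = None,
        config: PipelineConfig | None = None,
    ) -> None:
        self.calibration = calibration or CalibrationBundle()
        self.config = config or PipelineConfig()
        if self.config.stitching.delta_ms is None:
            self.config.stitching.delta_ms = self.calibration.delta_ms
        self.counter = ResetCounter(max_invalid=self.config.picking.max_invalid)
        self.buffer: list[HSILine] = []
        self.frame_records: list[FrameRecord] = []
        self.resets = 0
        self._begin_sequence()

    # -- sequence state ------------------------------------------------------

    def _begin_sequence(self) -> None:
        self.state = PanoramaState()
        self.db = KeypointDatabase()
        self.ref_kps: KeypointSet | None = None
        self.H_global_prev = np.eye(3)  # raw H_(i-1,P), identity at start
        self.t_prev: int | None = None
        self.view_transform: np.ndarray | None = None

    def reset(self) -> None:
        """Discard the panorama and database; a new sequence begins."""
        self.resets += 1
        self._begin_sequence()

    # -- stream input --------------------------------------------------------

    def process_line(self, line: HSILine) -> None:
        self.buffer.append(line)

    def process_frame(self, frame: TimedFrame) -> FrameRecord:
        cfg = self.config
        pk = cfg.picking
        record = FrameRecord(
            index=frame.index, timestamp_ms=frame.timestamp_ms, verdict_local=""
        )
        kps = extract_keypoints(
            frame, max_keypoints=pk.max_keypoints, n_scales=pk.n_scales
        )

        if not self.db.started:
            # first frame of a sequence: bootstrap, H_(1,P) = identity
            self.db.bootstrap(kps)
            self.ref_kps = kps
            self.H_global_prev = np.eye(3)
            self.t_prev = frame.timestamp_ms
            record.verdict_local = "ok"
            record.verdict_global = "ok"
            record.H_global = np.eye(3)
            self._update_view(np.eye(3))
            self.frame_records.append(record)
            return record

        # ---- local picking: frame vs reference (last processed frame)
        H_local, inl_local = None, 0
        if self.ref_kps is not None and len(self.ref_kps) and len(kps):
            matches = match_descriptors(kps, self.ref_kps, ratio=pk.lowe_ratio)
            try:
                H_local, inliers = estimate_homography(
                    matches,
                    kps,
                    self.ref_kps,
                    confidence=pk.ransac_confidence,
                    reproj_threshold=pk.ransac_threshold_px,
                    seed=cfg.seed,
                )
                inl_local = int(np.sum(inliers))
            except EstimationError:
                H_local = None
        verdict_local = gate_frame(H_local, inl_local, config=pk.gate())
        record.verdict_local = verdict_local.outcome
        record.n_inliers_local = inl_local
        record.H_local = H_local

        if verdict_local.outcome == "no_motion":
            self.frame_records.append(record)
            return record
        if not verdict_local.ok:
            record.reset_fired = self.counter.update(verdict_local)
            if record.reset_fired:
                self.reset()
            self.frame_records.append(record)
            return record

        # ---- global registration against the database
        try:
            gmatches = global_match(
                kps, self.db, max_matches=cfg.registration.max_matches,
                ratio=pk.lowe_ratio,
            )
        except EstimationError:
            record.verdict_global = "low_inliers"
            record.reset_fired = self.counter.update(GateVerdict("low_inliers"))
            if record.reset_fired:
                self.reset()
            self.frame_records.append(record)
            return record
        H_ip, g_inliers, verdict_global = estimate_global(
            gmatches,
            kps,
            self.db,
            self.H_global_prev,
            gate_config=pk.gate(),
            confidence=pk.ransac_confidence,
            reproj_threshold=pk.ransac_threshold_px,
            seed=cfg.seed,
        )
        record.verdict_global = verdict_global.outcome
        record.n_inliers_global = int(np.sum(g_inliers)) if g_inliers is not None else 0
        record.H_global = H_ip

        if verdict_global.outcome == "no_motion":
            self.frame_records.append(record)
            return record
        if not verdict_global.ok:
            maintain(
                self.db, kps, gmatches, g_inliers, H_ip, verdict_global,
                config=cfg.registration,
            )
            record.reset_fired = self.counter.update(verdict_global)
            if record.reset_fired:
                self.reset()
            self.frame_records.append(record)
            return record

        # ---- plausible frame: stitch the interval, maintain, advance
        H_ip = hg.normalize(H_ip)
        n_stitched, width = self._stitch_interval(frame.timestamp_ms, H_ip)
        record.stitched_lines = n_stitched
        record.line_width = width
        maintain(
            self.db, kps, gmatches, g_inliers, H_ip, verdict_global,
            config=cfg.registration,
        )
        self.ref_kps = kps
        self.H_global_prev = H_ip
        self.t_prev = frame.timestamp_ms
        self.counter.update(verdict_global)
        self._update_view(H_ip)
        self._forget()
        self.frame_records.append(record)
        return record

    # -- helpers -------------------------------------------------------------

    def _stitch_interval(self, t_cur: int, H_ip: np.ndarray) -> tuple[int, int]:
        st = self.config.stitching
        cal = self.calibration
        line_set, self.buffer = select_lines(
            self.buffer, self.t_prev, t_cur, st.delta_ms
        )
        n = len(line_set)
        if n == 0:
            return 0, 0
        H_prev_adj = adjust_for_line(self.H_global_prev, cal.h_sens, cal.h_pos)
        H_cur_adj = adjust_for_line(H_ip, cal.h_sens, cal.h_pos)
        delta_H = frame_delta(H_prev_adj, H_cur_adj)
        if st.adaptive_width:
            width = adaptive_width(delta_H, n_lines=n, cap=st.width_cap)
        else:
            width = st.fixed_width
        sign = motion_sign(delta_H)
        raw = interpolate_homographies(self.H_global_prev, H_ip, n)
        per_line = [adjust_for_line(H, cal.h_sens, cal.h_pos) for H in raw]
        colors = [
            false_color(line, mode=st.false_color_mode, rgb_bands=st.rgb_bands)
            for line in line_set.lines
        ]
        warp_and_composite(
            line_set, colors, per_line, self.state, width=width, sign=sign,
            config=st,
        )
        return n, width

    def _update_view(self, H_ip: np.ndarray) -> None:
        cal = self.calibration
        H_adj = adjust_for_line(H_ip, cal.h_sens, cal.h_pos)
        self.view_transform = (
            self.state.offset @ H_adj @ np.linalg.inv(cal.line_to_frame)
        )

    def _forget(self) -> None:
        if self.view_transform is None or self.state.mask.size == 0:
            return
        c = hg.corners(FRAME_WIDTH, FRAME_HEIGHT)
        win = hg.apply(self.view_transform, c)
        window = (win[:, 0].min(), win[:, 1].min(), win[:, 0].max(), win[:, 1].max())
        before = self.state.offset.copy()
        crop_forget(self.state, window, margin=self.config.stitching.forget_margin_px)
        shift = self.state.offset @ np.linalg.inv(before)
        if not np.allclose(shift, np.eye(3)):
            self.view_transform = shift @ self.view_transform

    # -- driving -------------------------------------------------------------

    def run(
        self, frames: list[TimedFrame], lines: list[HSILine]
    ) -> StitchResult:
        """Process both streams in merged timestamp order."""
        events: list[tuple[int, int, object]] = []
        for f in frames:
            events.append((f.timestamp_ms, 1, f))
        for l in lines:
            events.append((l.timestamp_ms, 0, l))
        events.sort(key=lambda e: (e[0], e[1]))
        for _, tag, rec in events:
            if tag == 0:
                self.process_line(rec)
            else:
                self.process_frame(rec)
        return self.result()

    def result(self) -> StitchResult:
        return StitchResult(
            state=self.state,
            frame_records=self.frame_records,
            database=self.db,
            resets=self.resets,
            config=self.config,
            calibration=self.calibration,
            view_transform=self.view_transform,
        )
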