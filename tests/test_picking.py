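"""Keypoint extraction, matching, homography estimation and gating."""

import numpy as np
import pytest

import hsistitch as hs
from hsistitch import homography as hg
from hsistitch.exceptions import EstimationError
from hsistitch.picking import (
    GateConfig,
    GateVerdict,
    KeypointSet,
    ResetCounter,
    estimate_homography,
    extract_keypoints,
    gate_frame,
    hamming_matrix,
    match_descriptors,
)


def make_set(coords, descriptors, responses=None) -> KeypointSet:
    coords = np.asarray(coords, dtype=float)
    descriptors = np.asarray(descriptors, dtype=bool)
    if responses is None:
        responses = np.linspace(1.0, 0.5, len(coords))
    return KeypointSet(
        coords=coords, descriptors=descriptors, responses=np.asarray(responses)
    )


def descriptor_family(rng, n, flips=0, base=None):
    """Descriptors at a controlled Hamming distance from a base pattern."""
    if base is None:
        base = rng.random((n, 256)) > 0.5
    out = base.copy()
    for i in range(n):
        idx = rng.choice(256, size=flips, replace=False)
        out[i, idx] ^= True
    return base, out


class TestExtractKeypoints:
    def test_uniform_frame_yields_empty_set(self):
        img = np.full((540, 960, 3), 77, dtype=np.uint8)
        assert len(extract_keypoints(img)) == 0

    def test_deterministic_per_frame(self, short_streams):
        frame = short_streams[0][0]
        a = extract_keypoints(frame)
        b = extract_keypoints(frame)
        np.testing.assert_array_equal(a.coords, b.coords)
        np.testing.assert_array_equal(a.descriptors, b.descriptors)

    def test_usaf_frame_is_feature_rich(self, usaf_scene):
        crop = usaf_scene.albedo[100:640, 100:1060]
        img = (crop * 255).astype(np.uint8)
        kps = extract_keypoints(img)
        assert len(kps) >= 100

    def test_capped_at_max_keypoints_ordered_by_response(self, short_streams):
        frame = short_streams[0][0]
        kps = extract_keypoints(frame, max_keypoints=1000)
        assert len(kps) <= 1000
        assert np.all(np.diff(kps.responses) <= 1e-12)

    def test_coordinates_within_frame_bounds(self, short_streams):
        frame = short_streams[0][0]
        kps = extract_keypoints(frame)
        assert kps.coords[:, 0].min() >= 0 and kps.coords[:, 0].max() < 960
        assert kps.coords[:, 1].min() >= 0 and kps.coords[:, 1].max() < 540


class TestMatchDescriptors:
    def test_ratio_test_keeps_clear_winner(self, rng):
        # best distance 10, second 20, ratio 0.8: 10 < 16 -> kept
        base = rng.random((1, 256)) > 0.5
        d_best = base.copy()
        d_best[0, rng.choice(256, 10, replace=False)] ^= True
        d_second = base.copy()
        d_second[0, rng.choice(256, 20, replace=False)] ^= True
        cur = make_set([[0, 0]], base)
        ref = make_set([[0, 0], [5, 5]], np.vstack([d_best, d_second]))
        m = match_descriptors(cur, ref, ratio=0.8)
        assert len(m) == 1 and m.distance[0] == 10

    def test_ratio_test_boundary_is_strict(self, rng):
        # best 16, second 20: 16 < 0.8*20 is false -> rejected
        base = rng.random((1, 256)) > 0.5
        d_best = base.copy()
        d_best[0, rng.choice(256, 16, replace=False)] ^= True
        d_second = base.copy()
        d_second[0, rng.choice(256, 20, replace=False)] ^= True
        cur = make_set([[0, 0]], base)
        ref = make_set([[0, 0], [5, 5]], np.vstack([d_best, d_second]))
        assert len(match_descriptors(cur, ref, ratio=0.8)) == 0

    def test_identical_sets_self_match_at_distance_zero(self, rng):
        desc = rng.random((30, 256)) > 0.5
        coords = rng.uniform(0, 500, (30, 2))
        s = make_set(coords, desc)
        m = match_descriptors(s, s, ratio=0.8)
        assert len(m) == 30
        assert np.all(m.distance == 0)
        assert np.all(m.current_idx == m.reference_idx)

    def test_duplicate_reference_claims_resolved_by_distance(self, rng):
        ref_desc = rng.random((1, 256)) > 0.5
        near = ref_desc.copy()
        near[0, rng.choice(256, 4, replace=False)] ^= True
        far = ref_desc.copy()
        far[0, rng.choice(256, 12, replace=False)] ^= True
        cur = make_set([[0, 0], [9, 9]], np.vstack([near, far]))
        ref = make_set([[1, 1]], ref_desc)
        m = match_descriptors(cur, ref, ratio=0.8)  # single ref: ratio skipped
        assert len(m) == 1
        assert m.current_idx[0] == 0 and m.distance[0] == 4

    def test_hamming_matrix_agrees_with_bruteforce(self, rng):
        a = make_set(np.zeros((8, 2)), rng.random((8, 256)) > 0.5)
        b = make_set(np.zeros((11, 2)), rng.random((11, 256)) > 0.5)
        expected = (a.descriptors[:, None, :] != b.descriptors[None, :, :]).sum(2)
        np.testing.assert_array_equal(hamming_matrix(a, b), expected)


class TestEstimateHomography:
    def _translated_sets(self, rng, n, t, noise=0.0):
        src = rng.uniform(50, 500, (n, 2))
        dst = src + np.asarray(t) + noise * rng.standard_normal((n, 2))
        desc = rng.random((n, 256)) > 0.5
        cur = make_set(src, desc)
        ref = make_set(dst, desc)
        matches = match_descriptors(cur, ref, ratio=0.8)
        return cur, ref, matches

    def test_recovers_exact_translation(self, rng):
        cur, ref, m = self._translated_sets(rng, 50, (7.0, -3.0))
        H, inliers = estimate_homography(m, cur, ref, seed=0)
        np.testing.assert_allclose(H, hg.translation(7.0, -3.0), atol=1e-6)
        assert inliers.all()

    def test_robust_to_sixty_percent_outliers(self, rng):
        src = rng.uniform(50, 500, (100, 2))
        dst = src + np.array([5.0, 2.0])
        outliers = rng.choice(100, size=60, replace=False)
        dst[outliers] += rng.uniform(40, 200, (60, 2))
        desc = rng.random((100, 256)) > 0.5
        cur, ref = make_set(src, desc), make_set(dst, desc)
        m = match_descriptors(cur, ref, ratio=0.8)
        H, _ = estimate_homography(m, cur, ref, seed=0, reproj_threshold=3.0)
        probe = np.array([[100.0, 100.0], [400.0, 300.0]])
        np.testing.assert_allclose(
            hg.apply(H, probe), probe + np.array([5.0, 2.0]), atol=0.1
        )

    def test_too_few_matches_fail(self, rng):
        cur, ref, m = self._translated_sets(rng, 3, (1.0, 0.0))
        with pytest.raises(EstimationError):
            estimate_homography(m, cur, ref, seed=0)

    def test_collinear_points_degenerate(self, rng):
        n = 20
        src = np.column_stack([np.linspace(0, 500, n), np.full(n, 100.0)])
        dst = src + np.array([5.0, 0.0])
        desc = rng.random((n, 256)) > 0.5
        cur, ref = make_set(src, desc), make_set(dst, desc)
        m = match_descriptors(cur, ref, ratio=0.8)
        with pytest.raises(EstimationError):
            estimate_homography(m, cur, ref, seed=0)

    def test_seeded_estimation_is_reproducible(self, rng):
        cur, ref, m = self._translated_sets(rng, 80, (3.0, 1.0), noise=0.5)
        H1, _ = estimate_homography(m, cur, ref, seed=7)
        H2, _ = estimate_homography(m, cur, ref, seed=7)
        np.testing.assert_array_equal(H1, H2)


class TestGateFrame:
    def test_insufficient_inliers(self):
        verdict = gate_frame(hg.translation(10, 0), 39)
        assert verdict.outcome == "low_inliers"

    def test_forty_inliers_pass(self):
        assert gate_frame(hg.translation(10, 0), 40).outcome == "ok"

    def test_identity_is_no_motion(self):
        v = gate_frame(np.eye(3), 500)
        assert v.outcome == "no_motion"
        assert not v.counts_as_invalid

    def test_mirror_flip_is_distorted(self):
        mirror = np.diag([-1.0, 1.0, 1.0])
        mirror[0, 2] = 960.0  # flip about the vertical center line
        assert gate_frame(mirror, 500).outcome == "distorted"

    def test_excessive_motion(self):
        assert gate_frame(hg.translation(300, 0), 500).outcome == "excessive_motion"

    def test_area_collapse_is_distorted(self):
        H = np.diag([0.5, 0.5, 1.0])
        H[0, 2], H[1, 2] = 100.0, 60.0
        assert gate_frame(H, 500).outcome == "distorted"

    def test_estimation_failure_gates_low_inliers(self):
        assert gate_frame(None, 0).outcome == "low_inliers"

    def test_idempotent(self):
        H = hg.translation(12, 5)
        assert gate_frame(H, 100).outcome == gate_frame(H, 100).outcome


class TestResetCounter:
    def test_reset_fires_exactly_after_max_invalid(self):
        c = ResetCounter(max_invalid=20)
        fired = [c.update(GateVerdict("low_inliers")) for _ in range(20)]
        assert fired == [False] * 19 + [True]
        assert c.resets_fired == 1
        assert c.count == 0

    def test_ok_resets_the_counter(self):
        c = ResetCounter(max_invalid=20)
        for _ in range(19):
            c.update(GateVerdict("distorted"))
        c.update(GateVerdict("ok"))
        assert c.count == 0
        assert not c.update(GateVerdict("low_inliers"))

    def test_no_motion_does_not_count(self):
        c = ResetCounter(max_invalid=20)
        for _ in range(19):
            c.update(GateVerdict("low_inliers"))
        c.update(GateVerdict("no_motion"))
        assert c.count == 19
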