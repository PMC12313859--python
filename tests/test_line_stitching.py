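"""Line selection, homography algebra, widening, compositing, cropping."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import make_line
from hsistitch import homography as hg
from hsistitch.exceptions import ConfigurationError
from hsistitch.line_stitching import (
    LineSet,
    PanoramaState,
    adaptive_width,
    adjust_for_line,
    crop_forget,
    false_color,
    frame_delta,
    interpolate_homographies,
    motion_sign,
    select_lines,
    update_offset,
    warp_and_composite,
)


def random_homography(rng, scale=1.0):
    """A well-conditioned random projective transform near the identity."""
    H = np.eye(3)
    H[:2, :2] += 0.2 * scale * rng.standard_normal((2, 2))
    H[:2, 2] = 50.0 * scale * rng.standard_normal(2)
    H[2, :2] = 1e-4 * scale * rng.standard_normal(2)
    return H


class TestSelectLines:
    def test_half_open_boundary(self):
        buffer = [make_line(1000, index=0), make_line(1100, index=1)]
        selected, remaining = select_lines(buffer, 1000, 1100, delta=0.0)
        assert [l.index for l in selected.lines] == [0]
        assert [l.index for l in remaining] == [1]

    def test_enumerated_membership_with_delay(self):
        stamps = list(range(960, 1066, 15))  # 960, 975, ..., 1065
        buffer = [make_line(t, index=i) for i, t in enumerate(stamps)]
        selected, remaining = select_lines(buffer, 1000, 1100, delta=35.0)
        expected = [t for t in stamps if 1000 <= t + 35 < 1100]
        assert [l.timestamp_ms for l in selected.lines] == expected
        assert expected == [975, 990, 1005, 1020, 1035, 1050]
        # the stale 960 ms line is dropped, the 1065 ms line kept for later
        assert [l.timestamp_ms for l in remaining] == [1065]

    def test_nominal_rates_give_about_seven_lines_per_interval(self):
        frame_times = [round(i * 100.0) for i in range(21)]
        line_times = [round(j * 1000.0 / 70.0) for j in range(150)]
        buffer = [make_line(t, index=j) for j, t in enumerate(line_times)]
        counts = []
        for t0, t1 in zip(frame_times, frame_times[1:]):
            selected, buffer = select_lines(buffer, t0, t1, delta=35.0)
            counts.append(len(selected))
        assert abs(np.mean(counts) - 7.0) < 0.25

    @given(
        delta=st.integers(0, 50),
        offsets=st.lists(st.integers(0, 299), min_size=1, max_size=40),
    )
    def test_every_line_assigned_to_exactly_one_interval(self, delta, offsets):
        frame_times = [0, 100, 200, 300]
        buffer = [
            make_line(t, index=i) for i, t in enumerate(sorted(set(offsets)))
        ]
        n_input = len(buffer)
        seen = []
        for t0, t1 in zip(frame_times, frame_times[1:]):
            selected, buffer = select_lines(buffer, t0, t1, delta=delta)
            seen.extend(l.index for l in selected.lines)
        assert len(seen) == len(set(seen))
        assert len(seen) + len(buffer) <= n_input


class TestFalseColor:
    def test_zero_spectrum_is_black(self):
        out = false_color(make_line(0, value=0.0))
        assert np.all(out == 0.0)

    def test_constant_spectrum_gives_its_gray_level(self):
        out = false_color(make_line(0, value=0.37))
        np.testing.assert_allclose(out, 0.37)

    def test_brightness_is_monotone_in_band_mean(self, rng):
        a = rng.random((540, 100))
        b = a * 0.5
        line = make_line(0)
        ga = false_color(type(line)(spectra=a, timestamp_ms=0, index=0))
        gb = false_color(type(line)(spectra=b, timestamp_ms=0, index=1))
        assert np.all(ga[:, 0] > gb[:, 0])

    def test_band_rgb_mode_picks_configured_bands(self, rng):
        spectra = rng.random((540, 100))
        line = make_line(0)
        out = false_color(
            type(line)(spectra=spectra, timestamp_ms=0, index=0),
            mode="band_rgb", rgb_bands=(24, 10, 0),
        )
        np.testing.assert_allclose(out[:, 0], spectra[:, 24])
        np.testing.assert_allclose(out[:, 2], spectra[:, 0])

    def test_unknown_mode_rejected(self):
        with pytest.raises(ConfigurationError):
            false_color(make_line(0), mode="heatmap")


class TestInterpolateHomographies:
    def test_first_element_is_h_prev_exactly(self):
        A = hg.translation(3, 1)
        B = hg.translation(9, 5)
        out = interpolate_homographies(A, B, 4)
        np.testing.assert_array_equal(out[0], A)

    def test_equal_endpoints_give_constant_sequence(self, rng):
        H = random_homography(rng)
        for Hk in interpolate_homographies(H, H, 5):
            np.testing.assert_allclose(Hk, hg.normalize(H), atol=1e-12)

    def test_halfway_between_identity_and_translation(self):
        out = interpolate_homographies(np.eye(3), hg.translation(4, 0), 2)
        np.testing.assert_allclose(out[1], hg.translation(2, 0), atol=1e-12)

    def test_endpoint_never_attained(self):
        B = hg.translation(10, 0)
        out = interpolate_homographies(np.eye(3), B, 5)
        assert not np.allclose(out[-1], B)

    def test_zero_lines_rejected(self):
        with pytest.raises(ValueError):
            interpolate_homographies(np.eye(3), np.eye(3), 0)


class TestConjugation:
    def test_identity_calibration_is_transparent(self, rng):
        H = random_homography(rng)
        np.testing.assert_allclose(
            adjust_for_line(H, np.eye(3), np.eye(3)), H
        )

    def test_identity_homography_stays_identity(self, rng):
        H_sens = random_homography(rng, 0.3)
        H_pos = hg.translation(480, 0)
        np.testing.assert_allclose(
            adjust_for_line(np.eye(3), H_sens, H_pos), np.eye(3), atol=1e-12
        )

    def test_point_mapping_oracle(self, rng):
        """Conjugated matrix equals the sequential five-matrix chain."""
        for _ in range(200):
            H = random_homography(rng)
            H_sens = random_homography(rng, 0.3)
            H_pos = hg.translation(rng.uniform(0, 500), rng.uniform(0, 50))
            Hp = adjust_for_line(H, H_sens, H_pos)
            pts = rng.uniform(-20, 560, (25, 2))
            chain = hg.apply(
                np.linalg.inv(H_pos),
                hg.apply(
                    np.linalg.inv(H_sens),
                    hg.apply(H, hg.apply(H_sens, hg.apply(H_pos, pts))),
                ),
            )
            np.testing.assert_allclose(hg.apply(Hp, pts), chain, atol=1e-9)


class TestFrameDelta:
    def test_equal_inputs_give_identity(self, rng):
        H = random_homography(rng)
        np.testing.assert_allclose(frame_delta(H, H), np.eye(3), atol=1e-9)

    def test_identity_previous_passes_current_through(self):
        np.testing.assert_allclose(
            frame_delta(np.eye(3), hg.translation(5, 0)), hg.translation(5, 0)
        )

    def test_composition_reproduces_current(self, rng):
        for _ in range(50):
            A, B = random_homography(rng), random_homography(rng)
            delta = frame_delta(A, B)
            np.testing.assert_allclose(A @ delta, B, atol=1e-9)


class TestAdaptiveWidth:
    @pytest.mark.parametrize(
        "T,n,expected", [(21, 7, 3), (15, 7, 3), (100, 7, 8), (0, 7, 1), (7, 7, 1)]
    )
    def test_width_formula(self, T, n, expected):
        assert adaptive_width(hg.translation(T, 0), n_lines=n, cap=8) == expected

    def test_direction_sign(self):
        assert motion_sign(hg.translation(5, 0)) == 1
        assert motion_sign(hg.translation(-5, 0)) == -1


class TestOffsetAndCanvas:
    def test_negative_x_extent_shifts_origin(self):
        state = PanoramaState()
        state, offset = update_offset(state, (-5.0, 3.0, 20.0, 40.0))
        np.testing.assert_array_equal(offset, hg.translation(5, 0))

    def test_extent_inside_canvas_is_noop(self):
        state = PanoramaState()
        state, _ = update_offset(state, (0.0, 0.0, 30.0, 30.0))
        offset_before = state.offset.copy()
        shape_before = state.shape
        state, offset = update_offset(state, (2.0, 2.0, 10.0, 10.0))
        np.testing.assert_array_equal(offset, offset_before)
        assert state.shape == shape_before

    def test_both_axes_negative(self):
        state = PanoramaState()
        state, offset = update_offset(state, (-5.0, -7.0, 10.0, 10.0))
        np.testing.assert_array_equal(offset, hg.translation(5, 7))

    def test_existing_content_preserved_under_left_padding(self):
        state = PanoramaState()
        update_offset(state, (0.0, 0.0, 10.0, 539.0))
        state.canvas[5, 3] = 0.7
        state.mask[5, 3] = True
        update_offset(state, (-4.0, 0.0, 10.0, 539.0))
        assert state.mask[5, 7]
        assert state.canvas[5, 7, 0] == np.float32(0.7)


def stitch_single(state, color_value, tx, width=1, sign=1):
    line = make_line(0, value=color_value)
    color = false_color(line)
    ls = LineSet(lines=[line], t_prev=0, t_cur=100)
    return warp_and_composite(
        ls, [color], [hg.translation(tx, 0.0)], state, width=width, sign=sign
    )


class TestCompositing:
    def test_restitching_same_line_is_idempotent(self):
        s1 = stitch_single(PanoramaState(), 0.5, 10.0)
        s2 = stitch_single(stitch_single(PanoramaState(), 0.5, 10.0), 0.5, 10.0)
        np.testing.assert_array_equal(s1.canvas, s2.canvas)
        np.testing.assert_array_equal(s1.mask, s2.mask)

    def test_disjoint_lines_union_occupancy(self):
        one = stitch_single(PanoramaState(), 0.5, 5.0)
        n_one = one.occupied_count()
        both = stitch_single(one, 0.5, 25.0)
        assert both.occupied_count() == 2 * n_one

    def test_newest_wins_overwrite(self):
        state = stitch_single(PanoramaState(), 0.2, 10.0)
        state = stitch_single(state, 0.9, 10.0)
        occupied = state.canvas[state.mask]
        np.testing.assert_allclose(occupied, np.float32(0.9))

    def test_widened_line_covers_trailing_columns(self):
        state = stitch_single(PanoramaState(), 0.5, 10.0, width=3, sign=1)
        cols = np.flatnonzero(state.mask.any(axis=0))
        assert set(cols) == {8, 9, 10}

    def test_width_extends_forward_for_negative_motion(self):
        state = stitch_single(PanoramaState(), 0.5, 10.0, width=3, sign=-1)
        cols = np.flatnonzero(state.mask.any(axis=0))
        assert set(cols) == {10, 11, 12}

    def test_far_outside_line_skipped_with_warning(self):
        state = PanoramaState()
        with pytest.warns(UserWarning, match="sanity"):
            stitch_single(state, 0.5, 1e6)
        assert state.occupied_count() == 0


class TestCropForget:
    def _panorama_strip(self, x_from=2, x_to=400):
        state = PanoramaState()
        for k, tx in enumerate(range(x_from, x_to, 2)):
            stitch_single(state, 0.2 + 0.6 * (k % 3) / 3.0, float(tx), width=2)
        return state

    def test_content_beyond_margin_cropped(self):
        state = self._panorama_strip()
        window = (150.0, 0.0, 500.0, 539.0)
        crop_forget(state, window, margin=100)
        # columns 0..49 removed, offset absorbs the shift
        assert state.offset[0, 2] == -50.0
        assert state.mask.shape[1] <= 500 - 50 + 100 + 2

    def test_window_plus_margin_is_bit_identical(self):
        state = self._panorama_strip()
        window = (150.0, 0.0, 300.0, 539.0)
        before_canvas = state.canvas.copy()
        crop_forget(state, window, margin=100)
        # retained region: canvas x in [50, 400]; compare in global coords
        np.testing.assert_array_equal(
            state.canvas[:, : state.canvas.shape[1]],
            before_canvas[:, 50 : 50 + state.canvas.shape[1]],
        )

    def test_noop_when_within_margin(self):
        state = self._panorama_strip(2, 100)
        shape = state.shape
        crop_forget(state, (0.0, 0.0, 150.0, 539.0), margin=100)
        assert state.shape == shape

    def test_crop_then_stitch_matches_never_cropping(self):
        a = self._panorama_strip()
        crop_forget(a, (150.0, 0.0, 500.0, 539.0), margin=100)
        stitch_single(a, 0.8, 300.0)

        b = self._panorama_strip()
        stitch_single(b, 0.8, 300.0)
        # the line sits at global x = 300; locate it in each canvas
        acol = int(300 + a.offset[0, 2])
        bcol = int(300 + b.offset[0, 2])
        np.testing.assert_array_equal(a.canvas[:, acol], b.canvas[:, bcol])
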