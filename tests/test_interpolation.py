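"""Interpolator kernel: per-kind behavior, easing oracle, frame expansion."""

import warnings

import pytest
from hypothesis import given, settings, strategies as st

from graphmotion import (BezierControl, ConfigurationError, RangeError,
                         SceneState, UnsupportedChangeWarning, bezier_alpha,
                         capture_frame, crossfade_custom_graphics,
                         crossfade_value, frames_equal, interpolate_property,
                         lerp_color, lerp_number, lerp_object_position,
                         lerp_position, make_frames, reconcile_timeline,
                         visibility_opacity)
from graphmotion.frame_model import KeyFrame
from graphmotion.properties import KEYS, ObjectPosition


# ---------------------------------------------------------------------------
# Independent Bezier oracle: dense parameter sampling + numeric x-inversion
# ---------------------------------------------------------------------------

def bezier_oracle(t, p1, p2, samples=100_000):
    """y at curve-x=t by dense sampling of the parametric cubic."""
    best_y, best_err = None, None
    for i in range(samples + 1):
        s = i / samples
        u = 1.0 - s
        x = 3 * u * u * s * p1[0] + 3 * u * s * s * p2[0] + s ** 3
        err = abs(x - t)
        if best_err is None or err < best_err:
            best_err = err
            best_y = 3 * u * u * s * p1[1] + 3 * u * s * s * p2[1] + s ** 3
    return best_y


class TestScalarInterpolators:
    @pytest.mark.parametrize("v0,v1,t,expected", [
        (0, 10, 0.5, 5), (7, 7, 0.3, 7), (2, 5, 1.0, 5), (2, 5, 0.0, 2),
    ])
    def test_lerp_number(self, v0, v1, t, expected):
        assert lerp_number(v0, v1, t) == expected

    def test_t_outside_unit_interval_rejected(self):
        for bad in (-0.1, 1.1):
            with pytest.raises(RangeError):
                lerp_number(0, 1, bad)

    @pytest.mark.parametrize("c0,c1,t,expected", [
        ((0, 0, 0, 255), (255, 255, 255, 255), 0.5, (128, 128, 128, 255)),
        ((10, 20, 30, 255), (20, 40, 60, 255), 0.25, (13, 25, 38, 255)),
        ((5, 6, 7, 200), (99, 98, 97, 200), 0.0, (5, 6, 7, 200)),
        ((5, 6, 7, 200), (99, 98, 97, 200), 1.0, (99, 98, 97, 200)),
    ])
    def test_lerp_color_rgb_linear_round_half_up(self, c0, c1, t, expected):
        assert lerp_color(c0, c1, t) == expected

    @pytest.mark.parametrize("p0,p1,t,expected", [
        ((0, 0), (10, 20), 0.5, (5, 10)),
        ((0, 0), (10, 20), 1.0, (10, 20)),
        ((-5, 3), (5, 3), 0.2, (-3, 3)),
    ])
    def test_lerp_position(self, p0, p1, t, expected):
        assert lerp_position(p0, p1, t) == expected


class TestBezierAlpha:
    def test_constant_short_circuits(self):
        assert bezier_alpha(128, 128, 0.37) == 128

    def test_exact_endpoints(self):
        assert bezier_alpha(10, 240, 0.0) == 10
        assert bezier_alpha(10, 240, 1.0) == 240

    def test_agrees_with_dense_sampling_oracle_on_101_point_grid(self):
        ctrl = BezierControl((0.25, 0.1), (0.25, 1.0))
        for i in range(101):
            t = i / 100
            expected = round(0 + bezier_oracle(t, ctrl.p1, ctrl.p2) * 255)
            assert abs(bezier_alpha(0, 255, t, ctrl) - expected) <= 1, t

    def test_monotone_when_endpoints_ordered(self):
        vals = [bezier_alpha(0, 255, i / 50) for i in range(51)]
        assert vals == sorted(vals)

    def test_control_points_outside_unit_square_rejected(self):
        with pytest.raises(ConfigurationError):
            BezierControl((1.5, 0.0), (0.25, 1.0))


class TestCrossfade:
    def test_endpoints_fully_opaque(self):
        assert crossfade_value("a", "b", 0.0) == ("a", 1.0)
        assert crossfade_value("a", "b", 1.0) == ("b", 1.0)

    def test_switch_point_fully_faded_new_value(self):
        assert crossfade_value("ellipse", "rectangle", 0.5) == ("rectangle", 0.0)

    def test_linear_ramps(self):
        assert crossfade_value("ellipse", "rectangle", 0.25) == ("ellipse", 0.5)
        value, mult = crossfade_value("ellipse", "rectangle", 0.75)
        assert value == "rectangle" and mult == pytest.approx(0.5)

    def test_continuity_limits_at_switch(self):
        eps = 1e-9
        _, before = crossfade_value("a", "b", 0.5 - eps)
        _, after = crossfade_value("a", "b", 0.5 + eps)
        assert before == pytest.approx(0.0, abs=1e-8)
        assert after == pytest.approx(0.0, abs=1e-8)

    def test_identical_values_never_fade(self):
        assert crossfade_value("a", "a", 0.5) == ("a", 1.0)


class TestVisibility:
    @pytest.mark.parametrize("v0,v1,t,expected", [
        (True, False, 0.25, 0.75), (False, True, 1.0, 1.0),
        (False, False, 0.7, 0.0), (True, True, 0.7, 1.0),
        (False, True, 0.3, 0.3),
    ])
    def test_opacity_table(self, v0, v1, t, expected):
        assert visibility_opacity(v0, v1, t) == pytest.approx(expected)


class TestObjectPosition:
    def test_midpoint_offsets(self):
        op0 = ObjectPosition(offset_x=0.0, offset_y=0.0)
        op1 = ObjectPosition(offset_x=0.0, offset_y=10.0)
        out = lerp_object_position(op0, op1, 0.5)
        assert (out.offset_x, out.offset_y) == (0.0, 5.0)
        assert out.anchor == "center"

    def test_identity(self):
        op = ObjectPosition("north", "left", 3.0, 4.0)
        assert lerp_object_position(op, op, 0.4) == op

    def test_anchor_change_holds_then_snaps_with_warning(self):
        op0 = ObjectPosition(anchor="center")
        op1 = ObjectPosition(anchor="north")
        with pytest.warns(UnsupportedChangeWarning):
            assert lerp_object_position(op0, op1, 0.5) == op0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert lerp_object_position(op0, op1, 1.0) == op1


class TestCustomGraphics:
    def test_endpoints_show_single_image(self):
        out, size = crossfade_custom_graphics(("a", 10.0), ("b", 30.0), 0.0)
        assert out == "a" and size == 10.0
        out, size = crossfade_custom_graphics(("a", 10.0), ("b", 30.0), 1.0)
        assert out == "b" and size == 30.0

    def test_simultaneous_blend_midway(self):
        out, size = crossfade_custom_graphics(("a", 10.0), ("b", 30.0), 0.5)
        assert out == (("a", 0.5), ("b", 0.5))
        assert size == 20.0

    def test_empty_slot_fades_new_image_in(self):
        out, _ = crossfade_custom_graphics((None, 10.0), ("b", 10.0), 0.5)
        assert out == (("b", 0.5),)


class TestDispatch:
    def test_size_kind_linear(self):
        k = KEYS["edge"]["width"]
        assert interpolate_property(k, 2.0, 6.0, 0.5) == (4.0, None)

    def test_none_kind_holds_until_segment_end(self):
        k = KEYS["annotation"]["canvas"]
        assert interpolate_property(k, "background", "foreground", 0.5) \
            == ("background", None)
        assert interpolate_property(k, "background", "foreground", 0.99) \
            == ("background", None)
        assert interpolate_property(k, "background", "foreground", 1.0) \
            == ("foreground", None)

    def test_position_kind_linear(self):
        k = KEYS["node"]["x"]
        assert interpolate_property(k, 0.0, 100.0, 0.1) == (10.0, None)

    def test_transparency_kind_rounds_to_int(self):
        k = KEYS["node"]["transparency"]
        value, _ = interpolate_property(k, 0, 255, 0.5)
        assert value == 128  # 127.5 rounds half-up


# ---------------------------------------------------------------------------
# Frame expansion
# ---------------------------------------------------------------------------

def _keyframes(k):
    frames = []
    for i in range(k):
        scene = SceneState(nodes={"n": {"x": float(100 * i), "y": 0.0}})
        frames.append(capture_frame(scene, float(i), frame_id=f"kf{i}"))
    _, rec = reconcile_timeline(frames)
    return rec


class TestMakeFrames:
    def test_five_keyframes_at_30_yield_121(self):
        seq = make_frames(_keyframes(5), [30] * 4)
        assert len(seq) == 121

    def test_three_keyframes_at_10_yield_21(self):
        seq = make_frames(_keyframes(3), [10] * 2)
        assert len(seq) == 21

    def test_single_keyframe_degenerate(self):
        seq = make_frames(_keyframes(1), [])
        assert len(seq) == 1

    def test_bad_counts_rejected(self):
        with pytest.raises(RangeError):
            make_frames(_keyframes(3), [10])
        with pytest.raises(RangeError):
            make_frames(_keyframes(3), [10, 0])

    def test_unreconciled_frames_rejected(self):
        from graphmotion import ConsistencyError
        a = capture_frame(SceneState(nodes={"n": {}}), 0.0)
        b = capture_frame(SceneState(nodes={"m": {}}), 1.0)
        with pytest.raises(ConsistencyError):
            make_frames([a, b], [5])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(counts=st.lists(st.integers(min_value=1, max_value=60),
                           min_size=1, max_size=9))
    def test_count_law_over_random_segments(self, counts):
        seq = make_frames(_keyframes(len(counts) + 1), counts)
        assert len(seq) == sum(counts) + 1

    def test_endpoint_fidelity(self, toy_spec):
        from graphmotion import make_scenes
        frames = [capture_frame(s, float(i), frame_id=f"kf{i}")
                  for i, s in enumerate(make_scenes(toy_spec))]
        _, rec = reconcile_timeline(frames)
        n = 7
        seq = make_frames(rec, [n] * (len(rec) - 1))
        for j, kf in enumerate(rec[:-1]):
            rf = seq[j * n]
            assert rf.network_map == kf.network_map
            assert rf.node_map == kf.node_map
            assert rf.edge_map == kf.edge_map
            assert rf.annotation_map == kf.annotation_map
        last = seq[len(seq) - 1]
        assert last.node_map == rec[-1].node_map
        assert last.annotation_map == rec[-1].annotation_map

    def test_monotone_sizes_positions_transparencies(self):
        s0 = SceneState(nodes={"n": {"x": 0.0, "width": 10.0,
                                     "transparency": 0}})
        s1 = SceneState(nodes={"n": {"x": 50.0, "width": 60.0,
                                     "transparency": 250}})
        frames = [capture_frame(s0, 0.0), capture_frame(s1, 1.0)]
        _, rec = reconcile_timeline(frames)
        seq = make_frames(rec, [40])
        for name in ("x", "width", "transparency"):
            vals = [f.node_map["n"][name] for f in seq]
            assert vals == sorted(vals), name
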