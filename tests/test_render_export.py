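"""Raster determinism, resolution scaling, and movie export round trips."""

from pathlib import Path

import pytest
from PIL import Image

from graphmotion import (ConfigurationError, EncoderUnavailableError,
                         ExportSettings, RangeError, RenderSettings,
                         SceneState, capture_frame, count_gif_frames,
                         gif_frame_delay_cs, h264_available, render_frame,
                         write_frames, write_gif, write_mp4)
from graphmotion.errors import SceneIOError
from graphmotion.fixtures import FixtureSpec
from graphmotion.pipeline import compile_timeline
from graphmotion.timeline import Timeline, add_keyframe

SMALL = RenderSettings(base_width=120, base_height=90)


@pytest.fixture(scope="module")
def short_sequence():
    """A 2-keyframe color/position sweep expanded to 11 frames."""
    from graphmotion.fixtures import make_scenes
    spec = FixtureSpec(n_nodes=4, n_edges=3, seed=5, script_kind="color_sweep")
    s0, s1 = make_scenes(spec)
    s1.nodes["n0"]["x"] = s0.nodes["n0"]["x"] + 80.0
    tl = Timeline()
    tl = add_keyframe(tl, capture_frame(s0, 0.0, frame_id="a"))
    tl = add_keyframe(tl, capture_frame(s1, 1.0 / 3, frame_id="b"))
    return compile_timeline(tl).sequence  # 10 + 1 frames


class TestRenderFrame:
    def test_empty_scene_is_solid_background(self):
        scene = SceneState(network={"background_paint": (10, 20, 30, 255)})
        img = render_frame(capture_frame(scene, 0.0), SMALL)
        assert img.size == (120, 90)
        assert set(img.getdata()) == {(10, 20, 30, 255)}

    def test_resolution_300_triples_dimensions(self, tiny_frame):
        base = render_frame(tiny_frame, SMALL)
        big = render_frame(
            tiny_frame, RenderSettings(120, 90, resolution_pct=300))
        assert big.size == (3 * base.size[0], 3 * base.size[1])

    def test_fully_faded_node_invisible(self, tiny_scene):
        frame = capture_frame(tiny_scene, 0.0)
        from graphmotion.interpolation import frame_as_render_frame
        rf = frame_as_render_frame(frame)
        rf.object_opacity[("node", "a")] = 0.0
        rf.object_opacity[("edge", "e")] = 0.0  # would dangle without a
        with_hidden = render_frame(rf, SMALL)
        tiny_scene.nodes.pop("a")
        tiny_scene.edges.pop("e")
        without_node = render_frame(
            frame_as_render_frame(capture_frame(tiny_scene, 0.0)), SMALL)
        assert with_hidden.tobytes() == without_node.tobytes()

    def test_deterministic_across_runs_and_order(self, short_sequence):
        a = [render_frame(f, SMALL).tobytes() for f in short_sequence]
        b = [render_frame(f, SMALL).tobytes()
             for f in reversed(short_sequence)]
        assert a == list(reversed(b))

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ConfigurationError):
            RenderSettings(base_width=0, base_height=10)
        with pytest.raises(ConfigurationError):
            RenderSettings(resolution_pct=0)


class TestWriteFrames:
    def test_png_per_frame_with_padded_names(self, short_sequence, tmp_path):
        paths = write_frames(short_sequence, tmp_path / "out", SMALL)
        assert len(paths) == len(short_sequence)
        assert paths[0].name == "frame_000001.png"
        assert paths[-1].name == f"frame_{len(short_sequence):06d}.png"

    def test_empty_sequence_rejected(self, tmp_path):
        from graphmotion.interpolation import FrameSequence
        with pytest.raises(SceneIOError):
            write_frames(FrameSequence([]), tmp_path)

    def test_byte_identical_across_runs(self, short_sequence, tmp_path):
        p1 = write_frames(short_sequence, tmp_path / "r1", SMALL)
        p2 = write_frames(short_sequence, tmp_path / "r2", SMALL)
        for a, b in zip(p1, p2):
            assert a.read_bytes() == b.read_bytes()


class TestGif:
    @pytest.mark.parametrize("fps,delay", [(25, 4), (30, 3), (29.97, 3),
                                           (60, 2)])
    def test_frame_delay_centiseconds(self, fps, delay):
        assert gif_frame_delay_cs(fps) == delay

    def test_decoded_frame_count_and_delay(self, short_sequence, tmp_path):
        p = write_gif(short_sequence, tmp_path / "m.gif",
                      ExportSettings(format="gif", fps=25), SMALL)
        assert count_gif_frames(p) == len(short_sequence)
        with Image.open(p) as im:
            im.seek(1)
            assert im.info["duration"] == 40  # 4 cs

    def test_hold_segments_keep_every_frame(self, tiny_frame, tmp_path):
        """Identical consecutive frames must not be coalesced."""
        from graphmotion.frame_model import retime, scene_from_frame
        tl = Timeline()
        tl = add_keyframe(tl, tiny_frame)
        hold = capture_frame(scene_from_frame(tiny_frame), 0.1, frame_id="f1")
        tl = add_keyframe(tl, hold)
        seq = compile_timeline(tl).sequence  # 4 identical frames
        p = write_gif(seq, tmp_path / "hold.gif",
                      ExportSettings(format="gif", fps=30), SMALL)
        assert count_gif_frames(p) == len(seq) == 4

    def test_loop_flag_controls_netscape_extension(self, short_sequence, tmp_path):
        looped = write_gif(short_sequence, tmp_path / "loop.gif",
                           ExportSettings(format="gif", fps=30, loop=True),
                           SMALL)
        once = write_gif(short_sequence, tmp_path / "once.gif",
                         ExportSettings(format="gif", fps=30, loop=False),
                         SMALL)
        with Image.open(looped) as im:
            assert im.info.get("loop") == 0  # loop forever
        with Image.open(once) as im:
            assert "loop" not in im.info

    def test_offered_rates_only(self):
        with pytest.raises(RangeError):
            ExportSettings(format="gif", fps=24)


class TestMp4:
    def test_roundtrip_or_actionable_error(self, short_sequence, tmp_path):
        """With an ffmpeg backend the decode count matches; without one the
        error tells the user which backend to install."""
        if h264_available():
            from graphmotion import count_mp4_frames
            p = write_mp4(short_sequence, tmp_path / "m.mp4",
                          ExportSettings(format="mp4", fps=30), SMALL)
            assert count_mp4_frames(p) == len(short_sequence)
        else:
            with pytest.raises(EncoderUnavailableError,
                               match="imageio-ffmpeg|ffmpeg"):
                write_mp4(short_sequence, tmp_path / "m.mp4",
                          ExportSettings(format="mp4", fps=30), SMALL)
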