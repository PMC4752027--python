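"""Scene/storyboard/session formats and GraphML import."""

import json
import random

import networkx as nx
import pytest

from graphmotion import (SceneIOError, SessionVersionError, Timeline,
                         ValidationError, add_keyframe, capture_frame,
                         color_to_hex, frames_equal, hex_to_color,
                         import_graphml, load_session, load_storyboard,
                         read_scene, save_session, write_scene)
from graphmotion.scene_io import CIRCLE_LAYOUT_RADIUS


class TestColors:
    def test_hex_decoding(self):
        assert hex_to_color("#FF000080") == (255, 0, 0, 128)
        assert hex_to_color("#00ff00") == (0, 255, 0, 255)

    def test_bijection_on_random_sample_and_corners(self):
        rng = random.Random(0)
        corners = [(0, 0, 0, 0), (255, 255, 255, 255), (0, 0, 0, 255),
                   (255, 0, 0, 1)]
        sample = [tuple(rng.randrange(256) for _ in range(4))
                  for _ in range(500)]
        for c in corners + sample:
            assert hex_to_color(color_to_hex(c)) == c

    @pytest.mark.parametrize("bad", ["FF0000FF", "#F00", "#GG0000FF", 17])
    def test_malformed_rejected(self, bad):
        with pytest.raises(ValidationError):
            hex_to_color(bad)


class TestSceneFiles:
    def test_minimal_scene(self, tmp_path):
        p = tmp_path / "s.json"
        p.write_text(json.dumps({"nodes": {"n1": {"x": 1.0, "y": 2.0}}}))
        scene = read_scene(p)
        assert list(scene.nodes) == ["n1"]
        assert scene.nodes["n1"]["fill_color"] == (200, 200, 200, 255)

    def test_edge_to_unknown_node_named_in_error(self, tmp_path):
        p = tmp_path / "s.json"
        p.write_text(json.dumps({
            "nodes": {"n1": {}},
            "edges": {"bad_edge": {"source": "n1", "target": "nope"}}}))
        with pytest.raises(ValidationError, match="bad_edge"):
            read_scene(p)

    def test_unknown_property_rejected_with_pointer(self, tmp_path):
        p = tmp_path / "s.json"
        p.write_text(json.dumps({"nodes": {"n1": {"fill_colour": "#FF0000"}}}))
        with pytest.raises(ValidationError, match="/nodes/n1/fill_colour"):
            read_scene(p)

    def test_round_trip(self, tiny_scene, tmp_path):
        p = write_scene(tiny_scene, tmp_path / "s.json")
        again = read_scene(p)
        assert frames_equal(capture_frame(again, 0.0),
                            capture_frame(tiny_scene, 0.0))

    def test_missing_file(self, tmp_path):
        with pytest.raises(SceneIOError):
            read_scene(tmp_path / "absent.json")


class TestStoryboard:
    def test_times_must_be_non_decreasing(self, tmp_path):
        p = tmp_path / "sb.json"
        p.write_text(json.dumps({"scenes": [
            {"scene": "a.json", "time_s": 2.0},
            {"scene": "b.json", "time_s": 1.0}]}))
        with pytest.raises(ValidationError, match="non-decreasing"):
            load_storyboard(p)

    def test_empty_rejected(self, tmp_path):
        p = tmp_path / "sb.json"
        p.write_text(json.dumps({"scenes": []}))
        with pytest.raises(ValidationError):
            load_storyboard(p)


class TestSession:
    def _timeline(self, tiny_scene):
        tl = Timeline()
        for i in range(5):
            tiny_scene.nodes["a"]["x"] = float(i * 7)
            tl = add_keyframe(
                tl, capture_frame(tiny_scene, float(i), frame_id=f"kf{i}"))
        return tl

    def test_lossless_round_trip(self, tiny_scene, tmp_path):
        tl = self._timeline(tiny_scene)
        tl2 = load_session(save_session(tl, tmp_path / "sess.json"))
        assert len(tl2) == len(tl)
        for a, b in zip(tl.entries, tl2.entries):
            assert a.frame_id == b.frame_id and a.time_s == b.time_s
            assert frames_equal(a, b)

    def test_empty_timeline_round_trips(self, tmp_path):
        tl2 = load_session(save_session(Timeline(), tmp_path / "e.json"))
        assert len(tl2) == 0

    def test_future_version_rejected(self, tmp_path):
        p = tmp_path / "future.json"
        p.write_text(json.dumps({"version": 99, "frames": []}))
        with pytest.raises(SessionVersionError, match="99"):
            load_session(p)

    def test_corrupt_bundle(self, tmp_path):
        p = tmp_path / "c.json"
        p.write_text("{not json")
        with pytest.raises(SceneIOError):
            load_session(p)


class TestGraphML:
    def test_path_graph_topology(self, tmp_path):
        p = tmp_path / "g.graphml"
        nx.write_graphml(nx.path_graph(3), p)
        scene = import_graphml(p)
        assert len(scene.nodes) == 3
        assert len(scene.edges) == 2

    def test_missing_positions_fall_back_to_circle(self, tmp_path):
        p = tmp_path / "g.graphml"
        nx.write_graphml(nx.path_graph(4), p)
        s1, s2 = import_graphml(p), import_graphml(p)
        radii = {(s1.nodes[n]["x"] ** 2 + s1.nodes[n]["y"] ** 2) ** 0.5
                 for n in s1.nodes}
        assert all(abs(r - CIRCLE_LAYOUT_RADIUS) < 1e-9 for r in radii)
        assert all(s1.nodes[n] == s2.nodes[n] for n in s1.nodes)

    def test_positions_used_when_present(self, tmp_path):
        G = nx.Graph()
        G.add_node("v", x=12.5, y=-3.0)
        p = tmp_path / "g.graphml"
        nx.write_graphml(G, p)
        scene = import_graphml(p)
        assert scene.nodes["v"]["x"] == 12.5
        assert scene.nodes["v"]["y"] == -3.0

    def test_duplicate_node_id_rejected(self, tmp_path):
        p = tmp_path / "dupe.graphml"
        p.write_text(
            '<?xml version="1.0"?>'
            '<graphml xmlns="http://graphml.graphdrawing.org/xmlns">'
            '<graph edgedefault="undirected">'
            '<node id="a"/><node id="a"/></graph></graphml>')
        with pytest.raises(ValidationError, match="duplicate"):
            import_graphml(p)

    def test_malformed_xml(self, tmp_path):
        p = tmp_path / "bad.graphml"
        p.write_text("<graphml><unclosed>")
        with pytest.raises(SceneIOError):
            import_graphml(p)
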