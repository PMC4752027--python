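import pytest

from graphmotion import (AnnotationRecord, EdgeRecord, FixtureSpec,
                         SceneState, capture_frame)


@pytest.fixture
def tiny_scene() -> SceneState:
    """Two nodes, one edge, one annotation — minimal but category-complete."""
    return SceneState(
        network={"background_paint": (255, 255, 255, 255),
                 "scale_factor": 1.0},
        nodes={
            "a": {"x": -50.0, "y": 0.0, "fill_color": (255, 0, 0, 255),
                  "label": "A"},
            "b": {"x": 50.0, "y": 0.0, "fill_color": (0, 0, 255, 255),
                  "label": "B"},
        },
        edges={"e": EdgeRecord("a", "b", {"width": 2.0})},
        annotations={"note": AnnotationRecord(
            "text", {"x": -40.0, "y": -40.0, "text": "hello"})},
    )


@pytest.fixture
def tiny_frame(tiny_scene):
    return capture_frame(tiny_scene, time_s=0.0, frame_id="f0")


@pytest.fixture
def toy_spec() -> FixtureSpec:
    return FixtureSpec(n_nodes=5, n_edges=5, seed=11, script_kind="mixed")
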