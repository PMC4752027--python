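"""Seeded synthetic scenes, scripts, and storyboards.

The generator produces small styled networks and multi-scene "scripts"
whose pairwise differences exercise specific interpolator kinds — a color
sweep, a zoom-and-pan, a shape crossfade, a visibility toggle, an
annotation fade, a custom-graphics swap, and a 13-scene mixed script
shaped like a typical expression-overlay movie (full view, zoom onto a hub
node, label/shape restyle, degree-scaled sizes, annotations, three data
colorings with holds, then per-node charts fading in).  Everything derives
from one seeded PRNG stream, so a given (spec, seed) always produces
byte-identical files.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Union

from .errors import RangeError, ValidationError
from .frame_model import AnnotationRecord, EdgeRecord, SceneState
from .properties import ObjectPosition
from .scene_io import Storyboard, StoryboardEntry, save_storyboard, write_scene

SCRIPT_KINDS = ("color_sweep", "zoom_pan", "shape_crossfade",
                "visibility_toggle", "annotation_fade",
                "custom_graphics_swap", "mixed")

_PALETTE = [
    (31, 119, 180, 255), (255, 127, 14, 255), (44, 160, 44, 255),
    (214, 39, 40, 255), (148, 103, 189, 255), (140, 86, 75, 255),
    (227, 119, 194, 255), (127, 127, 127, 255), (188, 189, 34, 255),
    (23, 190, 207, 255),
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic fixture family."""

    n_nodes: int = 6
    n_edges: int = 7
    seed: int = 0
    script_kind: str = "mixed"

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise RangeError("n_nodes must be >= 1")
        max_edges = self.n_nodes * (self.n_nodes - 1) // 2
        if not 0 <= self.n_edges <= max_edges:
            raise RangeError(
                f"n_edges must lie in [0, {max_edges}] for {self.n_nodes} "
                f"nodes, got {self.n_edges}")
        if self.script_kind not in SCRIPT_KINDS:
            raise ValidationError(
                f"unknown script kind {self.script_kind!r}; "
                f"choose one of {SCRIPT_KINDS}")


def make_toy_network(spec: FixtureSpec) -> SceneState:
    """Deterministic random graph with a seeded circular layout."""
    rng = random.Random(spec.seed)
    scene = SceneState(network={"scale_factor": 1.0,
                                "center_x": 0.0, "center_y": 0.0})
    import math
    for i in range(spec.n_nodes):
        angle = 2.0 * math.pi * i / spec.n_nodes
        radius = 150.0 + rng.uniform(-20.0, 20.0)
        scene.nodes[f"n{i}"] = {
            "x": radius * math.cos(angle),
            "y": radius * math.sin(angle),
            "label": f"N{i}",
            "fill_color": _PALETTE[i % len(_PALETTE)],
        }
    pairs = [(a, b) for a in range(spec.n_nodes)
             for b in range(a + 1, spec.n_nodes)]
    for j, (a, b) in enumerate(sorted(rng.sample(pairs, spec.n_edges))):
        scene.edges[f"e{j}"] = EdgeRecord(f"n{a}", f"n{b}")
    return scene


def _set_all_nodes(scene: SceneState, **props) -> SceneState:
    for pmap in scene.nodes.values():
        pmap.update(props)
    return scene


def _gradient(value: float) -> tuple[int, int, int, int]:
    """Blue (low) to yellow (high) data coloring, value in [0, 1]."""
    from .interpolation import round_half_up
    r = round_half_up(255 * value)
    return (r, r, round_half_up(255 * (1.0 - value)), 255)


def _clone(scene: SceneState) -> SceneState:
    import copy
    return copy.deepcopy(scene)


def make_scenes(spec: FixtureSpec) -> list[SceneState]:
    """The scene list of the requested script, in storyboard order."""
    rng = random.Random(spec.seed + 1)
    base = make_toy_network(spec)
    kind = spec.script_kind

    if kind == "color_sweep":
        second = _clone(base)
        for i, pmap in enumerate(second.nodes.values()):
            pmap["fill_color"] = _PALETTE[(i + 3) % len(_PALETTE)]
        return [base, second]

    if kind == "zoom_pan":
        second = _clone(base)
        focus = base.nodes["n0"]
        second.network.update({"center_x": focus["x"], "center_y": focus["y"],
                               "scale_factor": 2.5})
        return [base, second]

    if kind == "shape_crossfade":
        second = _clone(base)
        _set_all_nodes(second, shape="rectangle")
        return [base, second]

    if kind == "visibility_toggle":
        second = _clone(base)
        victim = f"n{spec.n_nodes - 1}"
        del second.nodes[victim]
        second.edges = {eid: r for eid, r in second.edges.items()
                        if victim not in (r.source, r.target)}
        return [base, second]

    if kind == "annotation_fade":
        second = _clone(base)
        second.annotations["a_note"] = AnnotationRecord("text", {
            "x": -150.0, "y": -180.0, "text": "highlighted region",
            "font_size": 14.0, "canvas": "foreground"})
        second.annotations["a_box"] = AnnotationRecord("shape", {
            "x": -60.0, "y": -60.0, "width": 120.0, "height": 120.0,
            "color": (255, 255, 0, 255), "opacity": 120,
            "canvas": "background"})
        return [base, second]

    if kind == "custom_graphics_swap":
        first = _clone(base)
        _set_all_nodes(first, custom_graphics_1="chart:expr_a")
        second = _clone(first)
        _set_all_nodes(second, custom_graphics_1="chart:expr_b")
        return [first, second]

    # mixed: 13 scenes shaped like an expression-overlay movie
    scenes = [base]
    zoomed = _clone(base)  # 2: zoom onto the hub node
    hub = base.nodes["n0"]
    zoomed.network.update({"center_x": hub["x"], "center_y": hub["y"],
                           "scale_factor": 1.8})
    scenes.append(zoomed)

    restyled = _clone(zoomed)  # 3: common-name labels, circular shapes
    for i, pmap in enumerate(restyled.nodes.values()):
        pmap["label"] = f"GENE{i}"
        pmap["shape"] = "ellipse"
    scenes.append(restyled)

    sized = _clone(restyled)  # 4: node/label size scaled by degree
    degree = {nid: 0 for nid in sized.nodes}
    for rec in sized.edges.values():
        degree[rec.source] += 1
        degree[rec.target] += 1
    for nid, pmap in sized.nodes.items():
        pmap["width"] = pmap["height"] = 25.0 + 12.0 * degree[nid]
        pmap["label_size"] = 10.0 + 2.0 * degree[nid]
        pmap["transparency"] = 220
    scenes.append(sized)

    annotated = _clone(sized)  # 5: highlight annotations appear
    annotated.annotations["a_hub"] = AnnotationRecord("shape", {
        "x": hub["x"] - 40.0, "y": hub["y"] - 40.0, "width": 80.0,
        "height": 80.0, "shape": "ellipse", "color": (255, 255, 0, 255),
        "opacity": 100, "canvas": "background"})
    scenes.append(annotated)

    def colored(tag: str) -> SceneState:
        s = _clone(annotated)
        for pmap in s.nodes.values():
            pmap["fill_color"] = _gradient(rng.random())
        s.annotations["a_data"] = AnnotationRecord("text", {
            "x": -180.0, "y": 170.0, "text": f"expression: {tag}",
            "font_size": 13.0, "canvas": "foreground"})
        return s

    for tag in ("cond_1", "cond_2", "cond_3"):  # 6-11: data colorings + holds
        s = colored(tag)
        scenes.append(s)
        scenes.append(_clone(s))

    charted = _clone(scenes[-1])  # 12: per-node charts fade in, labels move
    for pmap in charted.nodes.values():
        pmap["custom_graphics_1"] = "chart:all_conditions"
        pmap["custom_graphics_size_1"] = pmap["width"] * 0.8
        pmap["label_position"] = ObjectPosition(offset_y=pmap["height"] / 2 + 10.0)
    scenes.append(charted)
    scenes.append(_clone(charted))  # 13: hold
    return scenes


def make_script(spec: FixtureSpec, out_dir: Union[str, Path]
                ) -> tuple[Path, list[Path]]:
    """Write the script's scene files and storyboard; returns their paths.

    Scene times advance one second per scene, so every segment expands to
    30 interpolated frames.  The seed is recorded in the file names.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = f"{spec.script_kind}_seed{spec.seed}"
    scene_paths = []
    entries = []
    for i, scene in enumerate(make_scenes(spec)):
        p = write_scene(scene, out / f"{stem}_scene{i:02d}.json")
        scene_paths.append(p)
        entries.append(StoryboardEntry(p.name, float(i)))
    sb = Storyboard(entries, defaults={"fps": 30, "resolution_pct": 100},
                    base_dir=out)
    sb_path = save_storyboard(sb, out / f"{stem}_storyboard.json")
    return sb_path, scene_paths
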