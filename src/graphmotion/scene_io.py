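"""File formats: scene JSON, storyboard JSON, session bundles, GraphML.

Scenes are single JSON documents with top-level ``network`` / ``nodes`` /
``edges`` / ``annotations`` maps; colors travel as ``#RRGGBBAA`` hex
strings (6-digit accepted on read, alpha = FF) and coordinates in model
units — the camera maps model units to pixels only at render time, so
resolution scaling never alters stored scenes.  A storyboard lists scene
files with timeline positions in seconds.  A session bundle embeds every
captured key frame with its full property maps so an animation reloads
losslessly.  Worked examples of all three formats live in docs/formats.md.
"""

from __future__ import annotations

import json
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Union

import networkx as nx

from . import timeline as tl_mod
from .errors import (SceneIOError, SessionVersionError, ValidationError)
from .frame_model import (AnnotationRecord, EdgeRecord, KeyFrame, SceneState,
                          capture_frame, normalize_scene)
from .properties import KEYS, Domain, ObjectPosition
from .timeline import Timeline

SESSION_VERSION = 1

#: Radius of the deterministic fallback circle layout for GraphML imports.
CIRCLE_LAYOUT_RADIUS = 200.0


# ---------------------------------------------------------------------------
# Color strings
# ---------------------------------------------------------------------------

def color_to_hex(color: tuple[int, int, int, int]) -> str:
    return "#{:02X}{:02X}{:02X}{:02X}".format(*color)


def hex_to_color(s: str) -> tuple[int, int, int, int]:
    if not isinstance(s, str) or not s.startswith("#") or len(s) not in (7, 9):
        raise ValidationError(
            f"colors must be '#RRGGBB' or '#RRGGBBAA' strings, got {s!r}")
    try:
        channels = [int(s[i:i + 2], 16) for i in range(1, len(s) - 1, 2)]
    except ValueError:
        raise ValidationError(f"invalid hex color {s!r}") from None
    if len(channels) == 3:
        channels.append(255)
    return tuple(channels)


# ---------------------------------------------------------------------------
# Property value (de)serialization
# ---------------------------------------------------------------------------

def _encode_value(domain: Domain, value: Any) -> Any:
    if domain is Domain.COLOR:
        return color_to_hex(value)
    if domain is Domain.OBJECT_POSITION:
        return {"anchor": value.anchor, "justification": value.justification,
                "offset_x": value.offset_x, "offset_y": value.offset_y}
    return value


def _decode_value(domain: Domain, value: Any, where: str) -> Any:
    if domain is Domain.COLOR:
        return hex_to_color(value)
    if domain is Domain.OBJECT_POSITION:
        if not isinstance(value, dict):
            raise ValidationError(
                f"{where}: object positions are JSON objects, got {value!r}")
        return ObjectPosition(
            anchor=value.get("anchor", "center"),
            justification=value.get("justification", "center"),
            offset_x=value.get("offset_x", 0.0),
            offset_y=value.get("offset_y", 0.0),
        )
    return value


def _decode_props(category: str, obj: dict, pointer: str,
                  skip: tuple = ()) -> dict:
    props = {}
    for name, raw in obj.items():
        if name in skip:
            continue
        if name not in KEYS[category]:
            raise ValidationError(
                f"unknown {category} property at {pointer}/{name}")
        props[name] = _decode_value(KEYS[category][name].domain, raw,
                                    f"{pointer}/{name}")
    return props


def _encode_props(category: str, props: dict) -> dict:
    return {name: _encode_value(KEYS[category][name].domain, v)
            for name, v in sorted(props.items())}


# ---------------------------------------------------------------------------
# Scene files
# ---------------------------------------------------------------------------

def _load_json(path: Union[str, Path]) -> Any:
    path = Path(path)
    if not path.exists():
        raise SceneIOError(f"file not found: {path}")
    try:
        with open(path, encoding="utf8") as fp:
            return json.load(fp)
    except json.JSONDecodeError as e:
        raise SceneIOError(f"invalid JSON in {path}: {e}") from e


def scene_from_dict(doc: Any, where: str = "scene") -> SceneState:
    if not isinstance(doc, dict):
        raise ValidationError(f"{where}: scene document must be a JSON object")
    unknown = set(doc) - {"network", "nodes", "edges", "annotations"}
    if unknown:
        raise ValidationError(
            f"{where}: unknown top-level keys {sorted(unknown)}")
    scene = SceneState()
    scene.network = _decode_props("network", doc.get("network", {}), "/network")
    for nid, obj in doc.get("nodes", {}).items():
        scene.nodes[nid] = _decode_props("node", obj, f"/nodes/{nid}")
    for eid, obj in doc.get("edges", {}).items():
        for req in ("source", "target"):
            if req not in obj:
                raise ValidationError(
                    f"edge {eid!r} at /edges/{eid} lacks its {req!r} node id")
        scene.edges[eid] = EdgeRecord(
            obj["source"], obj["target"],
            _decode_props("edge", obj, f"/edges/{eid}",
                          skip=("source", "target")))
    for aid, obj in doc.get("annotations", {}).items():
        if "type" not in obj:
            raise ValidationError(
                f"annotation {aid!r} at /annotations/{aid} lacks its "
                f"'type' (shape|text|image|arrow)")
        scene.annotations[aid] = AnnotationRecord(
            obj["type"],
            _decode_props("annotation", obj, f"/annotations/{aid}",
                          skip=("type",)))
    return normalize_scene(scene)


def read_scene(path: Union[str, Path]) -> SceneState:
    """Read and validate a scene file; missing properties get defaults."""
    return scene_from_dict(_load_json(path), where=str(path))


def scene_to_dict(scene: SceneState) -> dict:
    scene = normalize_scene(scene)
    doc: dict[str, Any] = {"network": _encode_props("network", scene.network)}
    doc["nodes"] = {nid: _encode_props("node", p)
                    for nid, p in sorted(scene.nodes.items())}
    doc["edges"] = {
        eid: {"source": r.source, "target": r.target,
              **_encode_props("edge", r.props)}
        for eid, r in sorted(scene.edges.items())}
    doc["annotations"] = {
        aid: {"type": r.kind, **_encode_props("annotation", r.props)}
        for aid, r in sorted(scene.annotations.items())}
    return doc


def write_scene(scene: SceneState, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.write_text(json.dumps(scene_to_dict(scene), indent=2, sort_keys=True)
                    + "\n", encoding="utf8")
    return path


# ---------------------------------------------------------------------------
# Storyboards
# ---------------------------------------------------------------------------

@dataclass
class StoryboardEntry:
    scene: str
    time_s: float


@dataclass
class Storyboard:
    """Ordered scene files with timeline positions plus export defaults."""

    entries: list[StoryboardEntry]
    defaults: dict[str, Any] = field(default_factory=dict)
    base_dir: Path = Path(".")


def load_storyboard(path: Union[str, Path]) -> Storyboard:
    path = Path(path)
    doc = _load_json(path)
    if not isinstance(doc, dict) or "scenes" not in doc:
        raise ValidationError(f"{path}: storyboard needs a 'scenes' list")
    raw = doc["scenes"]
    if not isinstance(raw, list) or not raw:
        raise ValidationError(f"{path}: 'scenes' must be a non-empty list")
    entries = []
    last_t = -math.inf
    for i, item in enumerate(raw):
        if "scene" not in item or "time_s" not in item:
            raise ValidationError(
                f"{path}: /scenes/{i} needs 'scene' and 'time_s'")
        t = item["time_s"]
        if not isinstance(t, (int, float)) or t < 0:
            raise ValidationError(
                f"{path}: /scenes/{i}/time_s must be a non-negative number")
        if t < last_t:
            raise ValidationError(
                f"{path}: scene times must be non-decreasing "
                f"(/scenes/{i} at {t} after {last_t})")
        last_t = t
        entries.append(StoryboardEntry(item["scene"], float(t)))
    return Storyboard(entries, doc.get("defaults", {}), base_dir=path.parent)


def save_storyboard(sb: Storyboard, path: Union[str, Path]) -> Path:
    path = Path(path)
    doc = {"scenes": [{"scene": e.scene, "time_s": e.time_s}
                      for e in sb.entries]}
    if sb.defaults:
        doc["defaults"] = sb.defaults
    path.write_text(json.dumps(doc, indent=2) + "\n", encoding="utf8")
    return path


def storyboard_timeline(sb: Storyboard) -> Timeline:
    """Capture every storyboard scene into a key frame on a timeline."""
    tl = Timeline()
    for entry in sb.entries:
        scene_path = sb.base_dir / entry.scene
        scene = read_scene(scene_path)
        frame = capture_frame(scene, time_s=entry.time_s,
                              frame_id=Path(entry.scene).stem)
        tl = tl_mod.add_keyframe(tl, frame)
    return tl


# ---------------------------------------------------------------------------
# Session bundles
# ---------------------------------------------------------------------------

def _frame_to_doc(f: KeyFrame) -> dict:
    return {
        "frame_id": f.frame_id,
        "time_s": f.time_s,
        "network": _encode_props("network", f.network_map),
        "nodes": {nid: _encode_props("node", p)
                  for nid, p in sorted(f.node_map.items())},
        "edges": {eid: {"source": r.source, "target": r.target,
                        **_encode_props("edge", r.props)}
                  for eid, r in sorted(f.edge_map.items())},
        "annotations": {aid: {"type": r.kind,
                              **_encode_props("annotation", r.props)}
                        for aid, r in sorted(f.annotation_map.items())},
    }


def _frame_from_doc(doc: dict, pointer: str) -> KeyFrame:
    return KeyFrame(
        frame_id=doc["frame_id"],
        time_s=doc["time_s"],
        network_map=_decode_props("network", doc.get("network", {}),
                                  f"{pointer}/network"),
        node_map={nid: _decode_props("node", p, f"{pointer}/nodes/{nid}")
                  for nid, p in doc.get("nodes", {}).items()},
        edge_map={eid: EdgeRecord(o["source"], o["target"],
                                  _decode_props("edge", o,
                                                f"{pointer}/edges/{eid}",
                                                skip=("source", "target")))
                  for eid, o in doc.get("edges", {}).items()},
        annotation_map={aid: AnnotationRecord(
            o["type"], _decode_props("annotation", o,
                                     f"{pointer}/annotations/{aid}",
                                     skip=("type",)))
            for aid, o in doc.get("annotations", {}).items()},
    )


def save_session(tl: Timeline, path: Union[str, Path]) -> Path:
    """Persist every key frame (full property maps) and its timeline time."""
    path = Path(path)
    doc = {
        "version": SESSION_VERSION,
        "fps_base": tl.fps_base,
        "frames": [_frame_to_doc(f) for f in tl.entries],
    }
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n",
                    encoding="utf8")
    return path


def load_session(path: Union[str, Path]) -> Timeline:
    """Load a session bundle; ``load(save(tl))`` equals ``tl`` exactly."""
    doc = _load_json(path)
    if not isinstance(doc, dict) or "version" not in doc:
        raise SceneIOError(f"{path}: not a session bundle (no version field)")
    if doc["version"] != SESSION_VERSION:
        raise SessionVersionError(
            f"{path}: session version {doc['version']!r} is not supported by "
            f"this build (supported: {SESSION_VERSION}); re-export the "
            f"session with a matching version")
    frames = tuple(_frame_from_doc(d, f"/frames/{i}")
                   for i, d in enumerate(doc.get("frames", [])))
    return Timeline(frames, doc.get("fps_base", tl_mod.FPS_BASE))


# ---------------------------------------------------------------------------
# GraphML import
# ---------------------------------------------------------------------------

def import_graphml(path: Union[str, Path],
                   style_defaults: Optional[dict] = None) -> SceneState:
    """Build a scene from GraphML topology.

    Node positions come from conventional ``x``/``y`` node attributes when
    present; otherwise nodes are placed on a circle of radius
    ``CIRCLE_LAYOUT_RADIUS`` in document order (deterministic across runs).
    ``style_defaults`` may carry ``network``/``node``/``edge`` property maps
    applied to every imported object.
    """
    path = Path(path)
    if not path.exists():
        raise SceneIOError(f"file not found: {path}")
    try:
        tree = ET.parse(path)
    except ET.ParseError as e:
        raise SceneIOError(f"malformed GraphML in {path}: {e}") from e
    ns = {"g": "http://graphml.graphdrawing.org/xmlns"}
    declared = [n.get("id") for n in tree.getroot().iter(
        "{http://graphml.graphdrawing.org/xmlns}node")]
    if len(declared) != len(set(declared)):
        dupes = sorted({d for d in declared if declared.count(d) > 1})
        raise ValidationError(f"{path}: duplicate node id(s) {dupes}")
    del ns

    try:
        graph = nx.read_graphml(path)
    except Exception as e:
        raise SceneIOError(f"cannot parse GraphML {path}: {e}") from e

    style_defaults = style_defaults or {}
    scene = SceneState(network=dict(style_defaults.get("network", {})))
    n = max(1, graph.number_of_nodes())
    for i, (nid, data) in enumerate(graph.nodes(data=True)):
        props = dict(style_defaults.get("node", {}))
        if "x" in data and "y" in data:
            props["x"], props["y"] = float(data["x"]), float(data["y"])
        else:
            angle = 2.0 * math.pi * i / n
            props["x"] = CIRCLE_LAYOUT_RADIUS * math.cos(angle)
            props["y"] = CIRCLE_LAYOUT_RADIUS * math.sin(angle)
        if "label" in data:
            props["label"] = str(data["label"])
        scene.nodes[str(nid)] = props
    for i, (u, v) in enumerate(graph.edges()):
        props = dict(style_defaults.get("edge", {}))
        scene.edges[f"{u}--{v}"] = EdgeRecord(str(u), str(v), props)
    return normalize_scene(scene)
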