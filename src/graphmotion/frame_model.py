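"""Scene model, key-frame capture/apply, and frame diffing.

A :class:`SceneState` holds one styled network state: a network-level
property map plus per-object maps for nodes, edges, and annotations.  A
:class:`KeyFrame` is a validated, *total* (every registered property
present) deep snapshot of a scene at one timeline position, the unit the
interpolator tween between.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Any, Iterator, Optional

from . import properties as props
from .errors import ConsistencyError, ValidationError
from .properties import KEYS, VisualPropertyKey


@dataclass
class EdgeRecord:
    """One edge: endpoints plus its visual-property map."""

    source: str
    target: str
    props: dict[str, Any] = field(default_factory=dict)


@dataclass
class AnnotationRecord:
    """One annotation: its class (shape|text|image|arrow) plus properties."""

    kind: str
    props: dict[str, Any] = field(default_factory=dict)


@dataclass
class SceneState:
    """One network state: four property maps keyed by object id.

    Node positions denote node centers in model coordinates; x grows
    rightward and y grows downward (raster convention).
    """

    network: dict[str, Any] = field(default_factory=dict)
    nodes: dict[str, dict[str, Any]] = field(default_factory=dict)
    edges: dict[str, EdgeRecord] = field(default_factory=dict)
    annotations: dict[str, AnnotationRecord] = field(default_factory=dict)


@dataclass
class KeyFrame:
    """A timeline snapshot: four total property maps plus a time in seconds."""

    frame_id: str
    time_s: Optional[float]
    network_map: dict[str, Any]
    node_map: dict[str, dict[str, Any]]
    edge_map: dict[str, EdgeRecord]
    annotation_map: dict[str, AnnotationRecord]
    thumbnail: Any = None

    def object_ids(self, category: str) -> set[str]:
        return set(
            {"node": self.node_map, "edge": self.edge_map,
             "annotation": self.annotation_map}[category]
        )


# ---------------------------------------------------------------------------
# Validation and normalization
# ---------------------------------------------------------------------------

def _check_props(category: str, obj_id: str, pmap: dict[str, Any]) -> None:
    for name, value in pmap.items():
        if name not in KEYS[category]:
            raise ValidationError(
                f"unknown {category} property {name!r} on object {obj_id!r}"
            )
        props.validate_value(KEYS[category][name], value,
                             where=f"{category} {obj_id!r}")


def validate_scene(scene: SceneState) -> None:
    """Enforce the scene invariants; raise ValidationError naming the culprit."""
    _check_props("network", "network", scene.network)
    for nid, pmap in scene.nodes.items():
        _check_props("node", nid, pmap)
    for eid, rec in scene.edges.items():
        for endpoint in (rec.source, rec.target):
            if endpoint not in scene.nodes:
                raise ValidationError(
                    f"edge {eid!r} references unknown node {endpoint!r}"
                )
        _check_props("edge", eid, rec.props)
    for aid, rec in scene.annotations.items():
        if rec.kind not in props.ANNOTATION_KINDS:
            raise ValidationError(
                f"annotation {aid!r} has unknown class {rec.kind!r} "
                f"(expected one of {props.ANNOTATION_KINDS})"
            )
        _check_props("annotation", aid, rec.props)


def _total_map(category: str, pmap: dict[str, Any]) -> dict[str, Any]:
    """Return ``pmap`` completed with documented defaults for every key."""
    out = {}
    for name in KEYS[category]:
        out[name] = pmap[name] if name in pmap else copy.deepcopy(
            props.default_of(category, name))
    return out


def normalize_scene(scene: SceneState) -> SceneState:
    """Validate and complete a scene so each object carries every key."""
    validate_scene(scene)
    return SceneState(
        network=_total_map("network", scene.network),
        nodes={nid: _total_map("node", p) for nid, p in scene.nodes.items()},
        edges={
            eid: EdgeRecord(r.source, r.target, _total_map("edge", r.props))
            for eid, r in scene.edges.items()
        },
        annotations={
            aid: AnnotationRecord(r.kind, _total_map("annotation", r.props))
            for aid, r in scene.annotations.items()
        },
    )


# ---------------------------------------------------------------------------
# Capture / apply
# ---------------------------------------------------------------------------

def capture_frame(scene: SceneState, time_s: Optional[float] = None,
                  frame_id: Optional[str] = None,
                  thumbnail: Any = None) -> KeyFrame:
    """Snapshot ``scene`` into a key frame.

    The returned maps are deep copies completed with defaults, so later
    mutation of the scene never alters the frame.  ``time_s`` may be left
    unset; the timeline assigns a default position on insertion.
    """
    if time_s is not None and (time_s != time_s or time_s < 0):
        raise ValidationError(f"time_s must be finite and >= 0, got {time_s}")
    snap = normalize_scene(copy.deepcopy(scene))
    if frame_id is None:
        frame_id = f"frame@{time_s if time_s is not None else 'unset'}"
    return KeyFrame(
        frame_id=frame_id,
        time_s=time_s,
        network_map=snap.network,
        node_map=snap.nodes,
        edge_map=snap.edges,
        annotation_map=snap.annotations,
        thumbnail=thumbnail,
    )


def scene_from_frame(frame: KeyFrame) -> SceneState:
    """Rebuild a scene holding exactly the frame's stored state."""
    return SceneState(
        network=copy.deepcopy(frame.network_map),
        nodes=copy.deepcopy(frame.node_map),
        edges=copy.deepcopy(frame.edge_map),
        annotations=copy.deepcopy(frame.annotation_map),
    )


def apply_frame(frame: KeyFrame, scene: SceneState, universe) -> SceneState:
    """Map a frame's stored properties onto ``scene``.

    Objects the frame knows get exactly the stored values; objects the frame
    lacks but the universe (union over all frames) contains are kept with
    their current style and hidden; objects missing from the scene are added
    back and styled from the stored information.
    """
    for cat in ("node", "edge", "annotation"):
        unknown = frame.object_ids(cat) - getattr(
            universe, f"{cat}_ids")
        if unknown:
            raise ConsistencyError(
                f"frame {frame.frame_id!r} references {cat} ids outside the "
                f"universe: {sorted(unknown)}"
            )
    current = normalize_scene(copy.deepcopy(scene))
    out = scene_from_frame(frame)

    def _hidden(pmap: dict[str, Any], category: str) -> dict[str, Any]:
        filled = _total_map(category, pmap)
        filled["visible"] = False
        return filled

    for nid in universe.node_ids - set(out.nodes):
        donor = current.nodes.get(nid, {})
        out.nodes[nid] = _hidden(donor, "node")
    for eid in universe.edge_ids - set(out.edges):
        src, tgt = universe.edge_endpoints[eid]
        donor = current.edges[eid].props if eid in current.edges else {}
        out.edges[eid] = EdgeRecord(src, tgt, _hidden(donor, "edge"))
    for aid in universe.annotation_ids - set(out.annotations):
        if aid in current.annotations:
            kind = current.annotations[aid].kind
            donor = current.annotations[aid].props
        else:
            kind = universe.annotation_kinds[aid]
            donor = {}
        out.annotations[aid] = AnnotationRecord(kind, _hidden(donor, "annotation"))
    return out


# ---------------------------------------------------------------------------
# Diffing
# ---------------------------------------------------------------------------

def _iter_maps(frame: KeyFrame) -> Iterator[tuple[str, str, dict[str, Any]]]:
    yield "network", "network", frame.network_map
    for nid, p in frame.node_map.items():
        yield "node", nid, p
    for eid, r in frame.edge_map.items():
        yield "edge", eid, r.props
    for aid, r in frame.annotation_map.items():
        yield "annotation", aid, r.props


def frame_diff(a: KeyFrame, b: KeyFrame) -> set[tuple[str, VisualPropertyKey]]:
    """Pairs ``(object_id, key)`` whose values differ between two frames.

    Keys carried by only one frame (an object added or removed) are all
    reported.  Membership is symmetric: ``frame_diff(a, b)`` and
    ``frame_diff(b, a)`` return the same set.
    """
    index_a = {(cat, oid): pmap for cat, oid, pmap in _iter_maps(a)}
    index_b = {(cat, oid): pmap for cat, oid, pmap in _iter_maps(b)}
    out: set[tuple[str, VisualPropertyKey]] = set()
    for (cat, oid) in index_a.keys() | index_b.keys():
        pa = index_a.get((cat, oid), {})
        pb = index_b.get((cat, oid), {})
        for name in pa.keys() | pb.keys():
            if name not in pa or name not in pb or pa[name] != pb[name]:
                out.add((oid, KEYS[cat][name]))
    return out


def frames_equal(a: KeyFrame, b: KeyFrame) -> bool:
    """Structural equality of the four property maps (times ignored)."""
    return (
        a.network_map == b.network_map
        and a.node_map == b.node_map
        and a.edge_map == b.edge_map
        and a.annotation_map == b.annotation_map
    )


def retime(frame: KeyFrame, time_s: float) -> KeyFrame:
    return replace(frame, time_s=time_s)
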