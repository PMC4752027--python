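"""Object-universe reconciliation across key frames.

Different key frames of one animation may contain different objects (nodes
appear, annotations are added, ...).  Interpolation needs every frame to
speak about the same object set, so we build the *union universe* of all
ids across the timeline and complete each frame against it: an object a
frame lacks is carried hidden (``visible=False``), styled from the nearest
frame (by time distance) that does contain it so a later fade-in starts
from a sensible geometry.  This mirrors keeping deleted objects in the root
network of a network collection.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .errors import ConflictError, ConsistencyError
from .frame_model import (AnnotationRecord, EdgeRecord, KeyFrame, _total_map)


@dataclass
class ObjectUniverse:
    """Union of object ids over a set of contributing frames."""

    node_ids: set[str] = field(default_factory=set)
    edge_ids: set[str] = field(default_factory=set)
    annotation_ids: set[str] = field(default_factory=set)
    edge_endpoints: dict[str, tuple[str, str]] = field(default_factory=dict)
    annotation_kinds: dict[str, str] = field(default_factory=dict)


def union_topology(frames: Sequence[KeyFrame]) -> ObjectUniverse:
    """Exact set union of object ids over ``frames``.

    The same edge id must keep the same endpoints everywhere (and the same
    annotation id the same class), otherwise the frames cannot belong to one
    network collection and a :class:`ConflictError` is raised.
    """
    if not frames:
        raise ConsistencyError("union_topology needs at least one frame")
    uni = ObjectUniverse()
    for f in frames:
        uni.node_ids |= set(f.node_map)
        for eid, rec in f.edge_map.items():
            ends = (rec.source, rec.target)
            if eid in uni.edge_endpoints and uni.edge_endpoints[eid] != ends:
                raise ConflictError(
                    f"edge {eid!r} has endpoints {uni.edge_endpoints[eid]} in "
                    f"one frame and {ends} in frame {f.frame_id!r}"
                )
            uni.edge_endpoints[eid] = ends
            uni.edge_ids.add(eid)
        for aid, rec in f.annotation_map.items():
            if aid in uni.annotation_kinds and uni.annotation_kinds[aid] != rec.kind:
                raise ConflictError(
                    f"annotation {aid!r} is a {uni.annotation_kinds[aid]!r} in "
                    f"one frame and a {rec.kind!r} in frame {f.frame_id!r}"
                )
            uni.annotation_kinds[aid] = rec.kind
            uni.annotation_ids.add(aid)
    missing = {e for s, t in uni.edge_endpoints.values()
               for e in (s, t)} - uni.node_ids
    if missing:
        raise ConsistencyError(
            f"edge endpoints {sorted(missing)} are not in the node universe"
        )
    return uni


def _nearest_donor(frames: Sequence[KeyFrame], time_s: Optional[float],
                   contains) -> Optional[KeyFrame]:
    """Frame nearest in |Δtime| satisfying ``contains``; ties -> earlier."""
    best = None
    best_key = None
    for f in frames:
        if not contains(f):
            continue
        if time_s is None or f.time_s is None:
            dist = 0.0
        else:
            dist = abs(f.time_s - time_s)
        key = (dist, f.time_s if f.time_s is not None else 0.0)
        if best_key is None or key < best_key:
            best, best_key = f, key
    return best


def reconcile_frame(frame: KeyFrame, universe: ObjectUniverse,
                    donors: Sequence[KeyFrame] = ()) -> KeyFrame:
    """Complete ``frame`` so it covers every universe object.

    Objects already present are untouched.  Absent objects are inserted with
    ``visible=False`` and their remaining style copied from the nearest-in-time
    donor frame containing them (ties resolve to the earlier frame); with no
    donor they fall back to documented defaults.  Edges whose endpoint is
    hidden in the completed frame are forced hidden as well, so no dangling
    edge is ever rendered.
    """
    for cat, ids in (("node", universe.node_ids),
                     ("edge", universe.edge_ids),
                     ("annotation", universe.annotation_ids)):
        extra = frame.object_ids(cat) - ids
        if extra:
            raise ConsistencyError(
                f"frame {frame.frame_id!r} contains {cat} ids outside the "
                f"universe: {sorted(extra)}"
            )

    out = KeyFrame(
        frame_id=frame.frame_id,
        time_s=frame.time_s,
        network_map=copy.deepcopy(frame.network_map),
        node_map=copy.deepcopy(frame.node_map),
        edge_map=copy.deepcopy(frame.edge_map),
        annotation_map=copy.deepcopy(frame.annotation_map),
        thumbnail=frame.thumbnail,
    )

    def _hidden_props(category: str, donor_props) -> dict:
        filled = _total_map(category, copy.deepcopy(donor_props))
        filled["visible"] = False
        return filled

    for nid in sorted(universe.node_ids - set(out.node_map)):
        donor = _nearest_donor(donors, frame.time_s,
                               lambda f: nid in f.node_map)
        out.node_map[nid] = _hidden_props(
            "node", donor.node_map[nid] if donor else {})
    for eid in sorted(universe.edge_ids - set(out.edge_map)):
        donor = _nearest_donor(donors, frame.time_s,
                               lambda f: eid in f.edge_map)
        src, tgt = universe.edge_endpoints[eid]
        out.edge_map[eid] = EdgeRecord(
            src, tgt,
            _hidden_props("edge", donor.edge_map[eid].props if donor else {}))
    for aid in sorted(universe.annotation_ids - set(out.annotation_map)):
        donor = _nearest_donor(donors, frame.time_s,
                               lambda f: aid in f.annotation_map)
        if donor is not None:
            kind, dprops = donor.annotation_map[aid].kind, donor.annotation_map[aid].props
        else:
            kind, dprops = universe.annotation_kinds[aid], {}
        out.annotation_map[aid] = AnnotationRecord(
            kind, _hidden_props("annotation", dprops))

    # an edge with a hidden endpoint would dangle -- hide it too
    for eid, rec in out.edge_map.items():
        if not (out.node_map[rec.source].get("visible", True)
                and out.node_map[rec.target].get("visible", True)):
            rec.props["visible"] = False
    return out


def reconcile_timeline(frames: Sequence[KeyFrame]
                       ) -> tuple[ObjectUniverse, list[KeyFrame]]:
    """Build the union universe and complete every frame against it."""
    universe = union_topology(frames)
    return universe, [reconcile_frame(f, universe, donors=frames)
                      for f in frames]
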