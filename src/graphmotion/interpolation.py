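"""Tweening kernel: per-kind interpolators and frame expansion.

Given two consecutive key frames and a local parameter ``t`` in [0, 1],
every visual property is advanced by the interpolator its kind prescribes:
numbers and positions linearly, colors per RGB channel with the alpha
channel eased on a cubic Bezier, categorical values by a two-phase
crossfade (old value fades out on [0, 0.5], new value fades in on
[0.5, 1]), visibility changes by a linear opacity ramp, and per-node custom
graphics by a simultaneous alpha blend of both images.

:func:`make_frames` expands a reconciled key-frame list into the full
interpolated sequence.  A segment with ``n`` interpolations contributes the
frames at ``t = i/n`` for ``i = 0..n-1`` (its start key frame included, the
end key frame owned by the following segment) and the final key frame is
appended once, so ``k`` key frames at a constant ``n`` yield
``(k - 1) * n + 1`` frames — five key frames at 30 make 121.
"""

from __future__ import annotations

import copy
import math
import warnings
from dataclasses import dataclass, field
from typing import Any, Optional, Sequence

from .errors import (ConfigurationError, ConsistencyError, RangeError,
                     UnsupportedChangeWarning, ValidationError)
from .frame_model import EdgeRecord, AnnotationRecord, KeyFrame
from .properties import (Domain, InterpolationKind, ObjectPosition,
                         VisualPropertyKey, interpolator_for, validate_value)

__all__ = [
    "BezierControl", "DEFAULT_EASING", "FrameSequence", "RenderFrame",
    "bezier_alpha", "crossfade_custom_graphics", "crossfade_value",
    "interpolate_property", "interpolator_for", "lerp_color", "lerp_number",
    "lerp_object_position", "lerp_position", "make_frames",
    "visibility_opacity",
]


def round_half_up(x: float) -> int:
    """Round with ties away from zero-point-five upward (2.5 -> 3)."""
    return math.floor(x + 0.5)


# ---------------------------------------------------------------------------
# Bezier easing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BezierControl:
    """Inner control points of a unit cubic Bezier easing curve.

    Endpoints are fixed at (0,0) and (1,1); both control points must lie in
    the unit square, which guarantees the curve's x is monotone in the
    parameter so it can be inverted.
    """

    p1: tuple[float, float] = (0.25, 0.1)
    p2: tuple[float, float] = (0.25, 1.0)

    def __post_init__(self) -> None:
        for (cx, cy) in (self.p1, self.p2):
            if not (0.0 <= cx <= 1.0 and 0.0 <= cy <= 1.0):
                raise ConfigurationError(
                    "Bezier control points must lie in [0,1]^2 so the easing "
                    f"curve is monotone in x; got {self.p1}, {self.p2}"
                )

    def ease(self, t: float) -> float:
        """y-value of the curve at curve-x = ``t`` (inverted numerically)."""
        if t <= 0.0:
            return 0.0
        if t >= 1.0:
            return 1.0
        x1, y1 = self.p1
        x2, y2 = self.p2

        def bx(s: float) -> float:
            u = 1.0 - s
            return 3 * u * u * s * x1 + 3 * u * s * s * x2 + s ** 3

        lo, hi = 0.0, 1.0
        for _ in range(60):  # bisection to well below the 1e-6 contract
            mid = 0.5 * (lo + hi)
            if bx(mid) < t:
                lo = mid
            else:
                hi = mid
        s = 0.5 * (lo + hi)
        u = 1.0 - s
        return 3 * u * u * s * y1 + 3 * u * s * s * y2 + s ** 3


#: Standard ease-in-out used for alpha fades unless overridden.
DEFAULT_EASING = BezierControl()


# ---------------------------------------------------------------------------
# Scalar interpolators
# ---------------------------------------------------------------------------

def _check_t(t: float) -> None:
    if not 0.0 <= t <= 1.0:
        raise RangeError(f"interpolation parameter t must lie in [0,1], got {t}")


def lerp_number(v0: float, v1: float, t: float) -> float:
    """Linear interpolation with exact endpoints at t=0 and t=1."""
    _check_t(t)
    if not (math.isfinite(v0) and math.isfinite(v1)):
        raise ValidationError(f"lerp_number needs finite values, got {v0}, {v1}")
    if t == 0.0:
        return v0
    if t == 1.0:
        return v1
    return v0 + t * (v1 - v0)


def bezier_alpha(a0: int, a1: int, t: float,
                 ctrl: BezierControl = DEFAULT_EASING) -> int:
    """Eased alpha blend: a0 + ease(t)·(a1−a0), rounded half-up.

    Equal endpoints short-circuit (no easing applied to a constant).
    """
    _check_t(t)
    for a in (a0, a1):
        if not (isinstance(a, int) and 0 <= a <= 255):
            raise ValidationError(f"alpha channels are integers 0-255, got {a}")
    if a0 == a1:
        return a0
    if t == 0.0:
        return a0
    if t == 1.0:
        return a1
    v = a0 + ctrl.ease(t) * (a1 - a0)
    return min(255, max(0, round_half_up(v)))


def lerp_color(c0: tuple, c1: tuple, t: float,
               ctrl: BezierControl = DEFAULT_EASING) -> tuple:
    """Per-channel linear RGB blend; alpha eased via :func:`bezier_alpha`.

    Channels are rounded half-up back to integers.
    """
    _check_t(t)
    for c in (c0, c1):
        if (len(c) != 4 or not all(isinstance(ch, int) and 0 <= ch <= 255
                                   for ch in c)):
            raise ValidationError(f"colors are 4-tuples of integers 0-255, got {c}")
    if t == 0.0:
        return tuple(c0)
    if t == 1.0:
        return tuple(c1)
    rgb = tuple(round_half_up(c0[i] + t * (c1[i] - c0[i])) for i in range(3))
    return rgb + (bezier_alpha(c0[3], c1[3], t, ctrl),)


def lerp_position(p0: tuple, p1: tuple, t: float) -> tuple:
    """Component-wise linear interpolation of a coordinate tuple."""
    _check_t(t)
    if len(p0) != len(p1):
        raise ValidationError("positions must have equal dimension")
    return tuple(lerp_number(a, b, t) for a, b in zip(p0, p1))


def lerp_object_position(op0: ObjectPosition, op1: ObjectPosition,
                         t: float) -> ObjectPosition:
    """Blend anchored offsets; anchor/justification changes are unsupported.

    When anchor or justification differ the value holds at ``op0`` and snaps
    to ``op1`` at t=1, with an :class:`UnsupportedChangeWarning`.
    """
    _check_t(t)
    if (op0.anchor, op0.justification) != (op1.anchor, op1.justification):
        if op0 != op1:
            warnings.warn(
                "object-position anchor/justification changes are not "
                f"interpolated (got {op0.anchor}/{op0.justification} -> "
                f"{op1.anchor}/{op1.justification}); snapping at segment end",
                UnsupportedChangeWarning, stacklevel=2)
        return op1 if t == 1.0 else op0
    return ObjectPosition(
        anchor=op0.anchor,
        justification=op0.justification,
        offset_x=lerp_number(op0.offset_x, op1.offset_x, t),
        offset_y=lerp_number(op0.offset_y, op1.offset_y, t),
    )


def crossfade_value(v0: Any, v1: Any, t: float) -> tuple[Any, float]:
    """Two-phase categorical crossfade.

    Returns ``(value, opacity_multiplier)``: the old value fading out on
    [0, 0.5) (multiplier 1−2t), the new value fading in on [0.5, 1]
    (multiplier 2t−1).  The new value owns the t=0.5 frame, at multiplier 0.
    """
    _check_t(t)
    if v0 == v1:
        return v0, 1.0
    if t < 0.5:
        return v0, 1.0 - 2.0 * t
    return v1, 2.0 * t - 1.0


def visibility_opacity(vis0: bool, vis1: bool, t: float) -> float:
    """Opacity ramp for an appearing/disappearing object."""
    _check_t(t)
    if vis0 and vis1:
        return 1.0
    if not vis0 and not vis1:
        return 0.0
    return 1.0 - t if vis0 else t


def crossfade_custom_graphics(g0: tuple[Optional[str], float],
                              g1: tuple[Optional[str], float],
                              t: float) -> tuple[Any, float]:
    """Simultaneous alpha blend of two custom graphics in one slot.

    ``g0``/``g1`` are ``(image_ref, size)``.  Unlike the categorical
    crossfade, both images are drawn at once — g0 at weight 1−t over g1 at
    weight t — so an image-to-image transition never passes through a blank
    midpoint; the size is interpolated linearly.  Returns
    ``(composite_or_ref, size)`` where the composite is a tuple of
    ``(ref, weight)`` layers.
    """
    _check_t(t)
    (r0, s0), (r1, s1) = g0, g1
    size = lerp_number(s0, s1, t)
    return _blend_refs(r0, r1, t), size


def _blend_refs(r0: Optional[str], r1: Optional[str], t: float) -> Any:
    if r0 == r1:
        return r0
    layers = tuple((r, w) for r, w in ((r0, 1.0 - t), (r1, t))
                   if r is not None and w > 0.0)
    if len(layers) == 1 and layers[0][1] == 1.0:
        return layers[0][0]
    if not layers:
        return None
    return layers


def interpolate_property(key: VisualPropertyKey, v0: Any, v1: Any, t: float,
                         ctrl: BezierControl = DEFAULT_EASING
                         ) -> tuple[Any, Optional[float]]:
    """Advance one property; returns ``(value, opacity_multiplier_or_None)``.

    The multiplier is produced only by the Crossfade and Visible kinds and
    applies to the rendered opacity of the property's visual element.
    """
    _check_t(t)
    kind = interpolator_for(key)
    validate_value(key, v0)
    validate_value(key, v1)
    if kind is InterpolationKind.COLOR:
        return lerp_color(v0, v1, t, ctrl), None
    if kind is InterpolationKind.SIZE:
        return lerp_number(v0, v1, t), None
    if kind is InterpolationKind.TRANSPARENCY:
        if v0 == v1 or t == 0.0:
            return v0, None
        if t == 1.0:
            return v1, None
        return min(255, max(0, round_half_up(v0 + t * (v1 - v0)))), None
    if kind is InterpolationKind.POSITION:
        return lerp_number(v0, v1, t), None
    if kind is InterpolationKind.OBJECT_POSITION:
        return lerp_object_position(v0, v1, t), None
    if kind is InterpolationKind.CROSSFADE:
        return crossfade_value(v0, v1, t)
    if kind is InterpolationKind.VISIBLE:
        return (v0 if t < 1.0 else v1), visibility_opacity(v0, v1, t)
    if kind is InterpolationKind.CUSTOM_GRAPHICS_CROSSFADE:
        return _blend_refs(v0, v1, t), None
    # InterpolationKind.NONE: not interpolated; snap at the segment end
    return (copy.deepcopy(v0) if t < 1.0 else copy.deepcopy(v1)), None


# ---------------------------------------------------------------------------
# Frame expansion
# ---------------------------------------------------------------------------

#: Which rendered element a crossfading property fades (per category).
CROSSFADE_ELEMENT = {
    ("node", "shape"): "body",
    ("node", "label"): "label",
    ("node", "font_face"): "label",
    ("edge", "label"): "label",
    ("edge", "font_face"): "label",
    ("edge", "line_type"): "body",
    ("annotation", "shape"): "body",
    ("annotation", "text"): "label",
    ("annotation", "font_style"): "label",
    ("annotation", "font_family"): "label",
    ("annotation", "image_url"): "body",
    ("annotation", "arrow_source_anchor"): "body",
    ("annotation", "arrow_target_anchor"): "body",
    ("annotation", "arrow_source_type"): "body",
    ("annotation", "arrow_target_type"): "body",
}


@dataclass
class RenderFrame:
    """One fully interpolated frame, ready for rasterization.

    Carries the same four property maps as a key frame plus the opacity
    multipliers produced by the Visible and Crossfade interpolators:
    ``object_opacity[(category, id)]`` scales a whole object,
    ``element_opacity[(category, id, element)]`` scales one rendered element
    ("body" or "label").  Multipliers compose multiplicatively with the
    object's own transparency properties at render time.
    """

    network_map: dict[str, Any]
    node_map: dict[str, dict[str, Any]]
    edge_map: dict[str, EdgeRecord]
    annotation_map: dict[str, AnnotationRecord]
    object_opacity: dict[tuple[str, str], float] = field(default_factory=dict)
    element_opacity: dict[tuple[str, str, str], float] = field(default_factory=dict)
    segment_index: int = 0
    local_t: float = 0.0

    def opacity_of(self, category: str, obj_id: str,
                   element: str = "body") -> float:
        return (self.object_opacity.get((category, obj_id), 1.0)
                * self.element_opacity.get((category, obj_id, element), 1.0))


@dataclass
class FrameSequence:
    """Ordered interpolated frames with per-frame segment provenance."""

    frames: list[RenderFrame]

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i):
        return self.frames[i]


def frame_as_render_frame(kf: KeyFrame, segment_index: int = 0,
                          local_t: float = 0.0) -> RenderFrame:
    """Wrap a key frame for rendering; hidden objects get opacity 0."""
    rf = RenderFrame(
        network_map=copy.deepcopy(kf.network_map),
        node_map=copy.deepcopy(kf.node_map),
        edge_map=copy.deepcopy(kf.edge_map),
        annotation_map=copy.deepcopy(kf.annotation_map),
        segment_index=segment_index,
        local_t=local_t,
    )
    for cat, items in (("node", kf.node_map),
                       ("edge", {e: r.props for e, r in kf.edge_map.items()}),
                       ("annotation",
                        {a: r.props for a, r in kf.annotation_map.items()})):
        for oid, pmap in items.items():
            if not pmap.get("visible", True):
                rf.object_opacity[(cat, oid)] = 0.0
    return rf


def _require_reconciled(frames: Sequence[KeyFrame]) -> None:
    first = frames[0]
    for f in frames[1:]:
        for cat in ("node", "edge", "annotation"):
            if f.object_ids(cat) != first.object_ids(cat):
                raise ConsistencyError(
                    f"frames {first.frame_id!r} and {f.frame_id!r} have "
                    f"different {cat} sets; reconcile the timeline first"
                )


def _tween_maps(a: KeyFrame, b: KeyFrame, t: float, ctrl: BezierControl,
                seg: int) -> RenderFrame:
    from .properties import KEYS

    rf = RenderFrame({}, {}, {}, {}, segment_index=seg, local_t=t)

    def tween_pmap(category: str, oid: str, pa: dict, pb: dict) -> dict:
        out = {}
        for name, key in KEYS[category].items():
            value, mult = interpolate_property(key, pa[name], pb[name], t, ctrl)
            out[name] = value
            if mult is None:
                continue
            kind = interpolator_for(key)
            if kind is InterpolationKind.VISIBLE:
                rf.object_opacity[(category, oid)] = mult
            else:
                el = CROSSFADE_ELEMENT.get((category, name), "body")
                ek = (category, oid, el)
                rf.element_opacity[ek] = rf.element_opacity.get(ek, 1.0) * mult
        return out

    rf.network_map = tween_pmap("network", "network", a.network_map, b.network_map)
    for nid, pa in a.node_map.items():
        rf.node_map[nid] = tween_pmap("node", nid, pa, b.node_map[nid])
    for eid, ra in a.edge_map.items():
        rf.edge_map[eid] = EdgeRecord(
            ra.source, ra.target,
            tween_pmap("edge", eid, ra.props, b.edge_map[eid].props))
    for aid, ra in a.annotation_map.items():
        rf.annotation_map[aid] = AnnotationRecord(
            ra.kind,
            tween_pmap("annotation", aid, ra.props, b.annotation_map[aid].props))
    # normalize multipliers of 1.0 away so endpoint frames compare cleanly
    rf.element_opacity = {k: v for k, v in rf.element_opacity.items() if v != 1.0}
    rf.object_opacity = {k: v for k, v in rf.object_opacity.items() if v != 1.0}
    return rf


def make_frames(keyframes: Sequence[KeyFrame], counts: Sequence[int],
                ctrl: BezierControl = DEFAULT_EASING) -> FrameSequence:
    """Expand reconciled key frames into the full interpolated sequence.

    ``counts[j]`` is the number of interpolations for segment ``j`` (between
    key frames ``j`` and ``j+1``).  The sequence holds ``sum(counts) + 1``
    frames; with a constant count ``n`` that is ``(k - 1) * n + 1``.
    """
    if not keyframes:
        raise ConsistencyError("make_frames needs at least one key frame")
    if len(counts) != len(keyframes) - 1:
        raise RangeError(
            f"expected {len(keyframes) - 1} segment counts, got {len(counts)}")
    if any(n < 1 for n in counts):
        raise RangeError(f"segment counts must be >= 1, got {list(counts)}")
    _require_reconciled(keyframes)

    if len(keyframes) == 1:
        return FrameSequence([frame_as_render_frame(keyframes[0])])

    frames: list[RenderFrame] = []
    for j, n in enumerate(counts):
        a, b = keyframes[j], keyframes[j + 1]
        for i in range(n):
            frames.append(_tween_maps(a, b, i / n, ctrl, seg=j))
    final = frame_as_render_frame(keyframes[-1], segment_index=len(counts) - 1,
                                  local_t=1.0)
    frames.append(final)
    return FrameSequence(frames)
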